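"""Synthetic colony images, descriptor tables and qPCR Ct panels.

The generators emulate the statistical structure the downstream analysis
assumes, so that every stage of the pipeline can be exercised and validated
without external data:

* two phenotype classes ("good" vs "bad") that differ in cell packing
  (gap fraction), cell elongation and colony-edge regularity;
* cell lines that differ in baseline colony size and growth dynamics over
  24-120 h of culture;
* Ct panels with planted per-(gene, group) fold changes against a stable
  reference gene, measured in technical triplicates over biological repeats.

All generators are pure functions of their arguments including the seed:
the same call yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .image import ImageMeta, LabeledColonyImage
from .morphometry import COLONY_PARAMETERS, RECORD_COLUMNS


class SizingError(ValueError):
    """Raised when a colony cannot fit the requested raster."""


# --------------------------------------------------------------------------
# specifications
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhenotypeSpec:
    """Target morphology of one phenotype class.

    gap_fraction is the target ratio of free intercellular space to colony
    footprint area; cell_elongation the target major/minor axis ratio of
    cells; boundary_irregularity controls how wavy/spiky the colony edge is
    (0 = smooth).  Cell diameters are in micrometres; healthy colonies are
    built from close-packed small cells of roughly 10-16 um.
    """

    label: str
    gap_fraction: float
    cell_elongation: float
    boundary_irregularity: float
    cell_diameter_mean: float = 13.0
    cell_diameter_sd: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.gap_fraction < 1.0:
            raise ValueError("gap_fraction must lie in [0, 1)")
        if self.cell_elongation < 1.0:
            raise ValueError("cell_elongation must be >= 1")
        if self.boundary_irregularity < 0.0:
            raise ValueError("boundary_irregularity must be >= 0")
        if self.cell_diameter_mean <= 0 or self.cell_diameter_sd < 0:
            raise ValueError("cell diameter parameters must be positive")


#: tightly packed, regular colony of small round-ish cells
GOOD_PHENOTYPE = PhenotypeSpec(
    label="good", gap_fraction=0.05, cell_elongation=1.3,
    boundary_irregularity=0.03, cell_diameter_mean=12.0, cell_diameter_sd=1.2,
)

#: loosely packed colony with elongated cells and a spiky edge
BAD_PHENOTYPE = PhenotypeSpec(
    label="bad", gap_fraction=0.16, cell_elongation=2.0,
    boundary_irregularity=0.10, cell_diameter_mean=14.0, cell_diameter_sd=2.0,
)


@dataclass(frozen=True)
class LineSpec:
    """Growth behaviour of one cell line.

    ``base_area`` is the mean colony area (um^2) at 24 h post-plating and
    ``growth_rate`` an exponential rate per hour; the implied area curve is
    non-decreasing in time.  ``shape_factor_trend`` offsets the expected
    colony shape factor in the three analysis time bins (24, 48, 72-120 h).
    """

    name: str
    base_area: float = 3.0e4
    growth_rate: float = 0.018
    shape_factor_trend: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.base_area <= 0:
            raise ValueError("base_area must be positive")
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be non-negative for monotone growth")

    def colony_area_at(self, time_h: float) -> float:
        """Mean colony area (um^2) at ``time_h`` hours post-plating."""
        return self.base_area * math.exp(self.growth_rate * (time_h - 24.0))


#: three synthetic lines: one larger, faster-growing ES-like line and two
#: smaller iPS-like lines, mirroring the size ordering seen in culture
DEFAULT_LINES = (
    LineSpec("ES1", base_area=3.2e4, growth_rate=0.020,
             shape_factor_trend=(0.00, 0.05, 0.00)),
    LineSpec("iPS1", base_area=2.2e4, growth_rate=0.015,
             shape_factor_trend=(0.00, 0.00, 0.00)),
    LineSpec("iPS2", base_area=1.9e4, growth_rate=0.018,
             shape_factor_trend=(0.00, 0.02, 0.05)),
)

VALID_TIMES = (24.0, 48.0, 72.0, 96.0, 120.0)


# --------------------------------------------------------------------------
# colony image generation
# --------------------------------------------------------------------------

def _radial_profile(rng: np.random.Generator, pheno: PhenotypeSpec,
                    n_theta: int = 2048) -> np.ndarray:
    """Unit-mean-square radial boundary profile rho(theta)."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    rho = np.ones(n_theta)
    for m in range(2, 7):
        amp = rng.normal(0.0, pheno.boundary_irregularity / m)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        rho += amp * np.cos(m * theta + phase)
    if pheno.boundary_irregularity > 0.05:
        # spiky protrusions on the colony edge
        n_spikes = rng.integers(3, 7)
        centers = rng.uniform(0.0, 2.0 * np.pi, n_spikes)
        width = 0.08
        for c in centers:
            delta = np.angle(np.exp(1j * (theta - c)))
            rho += 3.0 * pheno.boundary_irregularity * np.exp(
                -0.5 * (delta / width) ** 2)
    rho = np.maximum(rho, 0.2)
    rho /= np.sqrt(np.mean(rho ** 2))  # preserve the target area
    return rho


def _place_centers(rng: np.random.Generator, footprint: np.ndarray,
                   n_cells: int, min_dist: float) -> np.ndarray:
    """Dart-throwing (Poisson-disk style) placement of cell centers.

    Uses a uniform bucket grid so each candidate only checks nearby accepted
    darts; candidates violating the minimum spacing are rejected."""
    fg = np.argwhere(footprint)
    max_attempts = 60 * n_cells
    idx = rng.integers(0, len(fg), size=max_attempts)
    jitter = rng.uniform(-0.5, 0.5, size=(max_attempts, 2))
    pts = fg[idx] + jitter
    d2min = min_dist ** 2
    buckets: dict[tuple[int, int], list[int]] = {}
    accepted: list[np.ndarray] = []
    inv = 1.0 / max(min_dist, 1.0)
    for p in pts:
        if len(accepted) >= n_cells:
            break
        bi, bj = int(p[0] * inv), int(p[1] * inv)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for k in buckets.get((bi + di, bj + dj), ()):
                    q = accepted[k]
                    if (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 < d2min:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            buckets.setdefault((bi, bj), []).append(len(accepted))
            accepted.append(p)
    return np.asarray(accepted)


def _merge_fragments(labels: np.ndarray) -> np.ndarray:
    """Make every label 4-connected by merging stray fragments into the
    neighbouring label they touch the most (or background if isolated)."""
    struct = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)
    objects = ndimage.find_objects(labels)
    for lab, slc in enumerate(objects, start=1):
        if slc is None:
            continue
        grown = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, labels.shape[i]))
            for i, s in enumerate(slc)
        )
        view = labels[grown]
        mask = view == lab
        comp, n = ndimage.label(mask, structure=struct)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(mask, comp, np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        for frag in range(1, n + 1):
            if frag == keep:
                continue
            frag_mask = comp == frag
            ring = ndimage.binary_dilation(frag_mask, structure=struct) & ~frag_mask
            neighbours = view[ring]
            neighbours = neighbours[(neighbours != lab) & (neighbours > 0)]
            if neighbours.size:
                counts = np.bincount(neighbours)
                view[frag_mask] = int(np.argmax(counts))
            else:
                view[frag_mask] = 0
    return labels


def _carve_gaps(labels: np.ndarray, gap_target_px: int) -> np.ndarray:
    """Remove exactly ``gap_target_px`` pixels, eroding each cell from its
    boundary inward proportionally to its size (largest-remainder split)."""
    if gap_target_px <= 0:
        return labels
    sizes = np.bincount(labels.ravel())
    cells = np.nonzero(sizes[1:])[0] + 1
    cell_sizes = sizes[cells].astype(float)
    total = cell_sizes.sum()
    raw = gap_target_px * cell_sizes / total
    quota = np.floor(raw).astype(int)
    remainder = gap_target_px - quota.sum()
    order = np.argsort(-(raw - quota), kind="stable")
    quota[order[:remainder]] += 1
    # never erase a cell completely
    cap = cell_sizes.astype(int) - 1
    overflow = int(np.maximum(quota - cap, 0).sum())
    quota = np.minimum(quota, cap)
    if overflow:
        spare = cap - quota
        for i in np.argsort(-spare, kind="stable"):
            take = min(overflow, spare[i])
            quota[i] += take
            overflow -= take
            if overflow == 0:
                break
    objects = ndimage.find_objects(labels)
    for lab, q in zip(cells, quota):
        if q <= 0:
            continue
        slc = objects[lab - 1]
        crop = labels[slc] == lab
        dist = ndimage.distance_transform_edt(np.pad(crop, 1))[1:-1, 1:-1]
        rr, cc = np.nonzero(crop)
        order = np.lexsort((cc, rr, dist[rr, cc]))
        remove = order[:q]
        view = labels[slc]
        view[rr[remove], cc[remove]] = 0
    return labels


def generate_colony_image(
    line: LineSpec,
    pheno: PhenotypeSpec,
    time_h: float,
    seed: int,
    pixel_size: float = 1.0,
    shape: tuple[int, int] | None = None,
    passage: int = 20,
    clonality: str = "clonal",
) -> LabeledColonyImage:
    """Rasterize one synthetic colony as a labeled image.

    The colony footprint is a radially perturbed disk whose area follows the
    line's growth curve; cells are seeded by dart throwing, grown into an
    anisotropic (elongation-aware) Voronoi tessellation of the footprint and
    then eroded from their boundaries until the free intercellular space
    matches ``pheno.gap_fraction`` to within pixel rounding.  With
    ``gap_fraction=0`` the tessellation is space-filling and the measured
    intercellular space is zero.
    """
    if not (min(VALID_TIMES) <= time_h <= max(VALID_TIMES)):
        raise ValueError(f"time_h must lie within {min(VALID_TIMES)}-{max(VALID_TIMES)} h")
    rng = np.random.default_rng(seed)

    area_px = line.colony_area_at(time_h) / pixel_size ** 2
    r0 = math.sqrt(area_px / math.pi)
    rho = _radial_profile(rng, pheno)
    extent = int(math.ceil(2.0 * r0 * rho.max() + 8.0))
    if shape is None:
        side = max(512, extent)
        shape = (side, side)
    if min(shape) < extent:
        raise SizingError(
            f"colony needs a {extent} px raster; got shape {shape}"
        )

    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dy, dx = yy - cy, xx - cx
    rr = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx) % (2.0 * np.pi)
    t_idx = (theta / (2.0 * np.pi) * len(rho)).astype(int) % len(rho)
    footprint = rr <= r0 * rho[t_idx]

    fp_px = int(footprint.sum())
    d_px = pheno.cell_diameter_mean / pixel_size
    mean_cell_area = math.pi * (d_px / 2.0) ** 2
    n_cells = max(1, round(fp_px * (1.0 - pheno.gap_fraction) / mean_cell_area))
    centers = _place_centers(rng, footprint, n_cells, min_dist=0.8 * d_px)
    n_cells = len(centers)

    # per-cell orientation, elongation and size weight; the bad phenotype
    # carries a tail of strongly elongated outlier cells
    phi = rng.uniform(0.0, np.pi, n_cells)
    elong = np.maximum(1.0, rng.normal(pheno.cell_elongation,
                                       0.1 * pheno.cell_elongation, n_cells))
    if pheno.label == "bad" and n_cells >= 10:
        outliers = rng.choice(n_cells, size=max(1, n_cells // 10), replace=False)
        elong[outliers] *= 2.0
    size_w = np.maximum(
        0.4, rng.normal(1.0, pheno.cell_diameter_sd / pheno.cell_diameter_mean,
                        n_cells))

    pix = np.argwhere(footprint).astype(float)
    k = min(n_cells, 8)
    _, neigh = cKDTree(centers).query(pix, k=k)
    neigh = neigh.reshape(len(pix), k)
    dy = pix[:, 0, None] - centers[:, 0][neigh]
    dx = pix[:, 1, None] - centers[:, 1][neigh]
    ux = np.cos(phi)[neigh]
    uy = np.sin(phi)[neigh]
    along = dy * uy + dx * ux
    across = dy * ux - dx * uy
    e = elong[neigh]
    metric = (along * along / e + across * across * e) / size_w[neigh] ** 2
    choice = neigh[np.arange(len(pix)), metric.argmin(axis=1)]

    labels = np.zeros(shape, dtype=np.int32)
    labels[footprint] = choice + 1
    labels = _merge_fragments(labels)
    labels = _carve_gaps(labels, round(pheno.gap_fraction * fp_px))
    # boundary erosion can pinch a narrow cell in two: restore 4-connectivity
    labels = _merge_fragments(labels)

    # relabel contiguously (fragments merging may have emptied some labels)
    present = np.unique(labels)
    present = present[present > 0]
    remap = np.zeros(labels.max() + 1, dtype=np.int32)
    remap[present] = np.arange(1, present.size + 1)
    labels = remap[labels]

    meta = ImageMeta(line=line.name, passage=passage, time_h=float(time_h),
                     phenotype=pheno.label, clonality=clonality)
    return LabeledColonyImage(labels, footprint, pixel_size, meta, truth=pheno)


# --------------------------------------------------------------------------
# descriptor tables
# --------------------------------------------------------------------------

def _check_cov(cov: np.ndarray, p: int) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (p, p):
        raise ValueError(f"covariance must be {p}x{p}")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    evals = np.linalg.eigvalsh(cov)
    if evals.min() < -1e-8 * max(evals.max(), 1.0):
        raise ValueError("covariance must be positive semi-definite")
    return cov


def generate_feature_table(
    group_means: Mapping[tuple[str, str], Mapping[str, float]],
    group_cov: np.ndarray | Mapping[tuple[str, str], np.ndarray],
    n_per_group: int,
    seed: int,
    unit: str = "colony",
    times: Sequence[float] = (24.0, 48.0),
    passages: Sequence[int] = (13, 24, 45),
) -> pd.DataFrame:
    """Draw a synthetic descriptor table with planted group structure.

    ``group_means`` maps (line, phenotype) to the mean vector of the
    descriptors; ``group_cov`` is one shared covariance or one per group.
    Each record additionally carries a growth time, passage and an
    independent clonality label (clonality has no morphological effect; it
    only matters for expression analyses).  Shape-factor draws are clipped
    to (0, 1] and all descriptors to positive values.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    keys = list(group_means)
    params = list(group_means[keys[0]])
    p = len(params)
    rng = np.random.default_rng(seed)
    frames = []
    for key in keys:
        line, phenotype = key
        mean = np.asarray([group_means[key][q] for q in params], dtype=float)
        cov = group_cov[key] if isinstance(group_cov, Mapping) else group_cov
        if isinstance(cov, pd.DataFrame):
            cov = cov.loc[params, params].to_numpy()  # align to mean order
        cov = _check_cov(cov, p)
        draws = rng.multivariate_normal(mean, cov, size=n_per_group,
                                        method="svd")
        df = pd.DataFrame(draws, columns=params)
        if "shape_factor" in params:
            df["shape_factor"] = df["shape_factor"].clip(1e-6, 1.0)
        for q in params:
            if q != "shape_factor":
                df[q] = df[q].clip(lower=1e-9)
        # enforce the caliper/axis ordering invariants of measured records
        if {"feret_d", "min_feret_d"} <= set(params):
            df["min_feret_d"] = df[["min_feret_d", "feret_d"]].min(axis=1)
        if {"feret_d", "minor_axis"} <= set(params):
            df["minor_axis"] = df[["minor_axis", "feret_d"]].min(axis=1)
        df.insert(0, "unit", unit)
        df.insert(1, "label", np.arange(1, n_per_group + 1))
        df.insert(2, "line", line)
        df.insert(3, "passage", rng.choice(passages, size=n_per_group))
        df.insert(4, "time_h", rng.choice(times, size=n_per_group))
        df.insert(5, "phenotype", phenotype)
        df.insert(6, "clonality",
                  rng.choice(["clonal", "nonclonal"], size=n_per_group))
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    for col in RECORD_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    return out[[c for c in RECORD_COLUMNS if c in out.columns]]


def default_descriptor_presets(
    lines: Sequence[LineSpec] = DEFAULT_LINES,
) -> tuple[dict[tuple[str, str], dict[str, float]], np.ndarray]:
    """Study-condition group means and covariance for colony descriptors.

    The planted structure mirrors the study design: in the ES-like line the
    size descriptors are larger for good colonies while the intercellular
    space is smaller; in one iPS-like line the size effects point the other
    way; the remaining line shows no mean shift in any single colony
    descriptor (its phenotypes are only separable by descriptor
    combinations).  Effect sizes are calibrated so the default presets are
    separable at roughly 75 % cross-validation accuracy.
    """
    base = {
        "area": 5.0e4, "perimeter": 950.0, "minor_axis": 220.0,
        "feret_d": 330.0, "min_feret_d": 240.0, "shape_factor": 0.72,
        "ais": 4.2e3,
    }
    scale = {"area": 1.0e4, "perimeter": 160.0, "minor_axis": 38.0,
             "feret_d": 55.0, "min_feret_d": 42.0, "shape_factor": 0.09,
             "ais": 1.4e3}
    # phenotype effects in units of the descriptor SD, per line
    direction = {lines[0].name: +1.0, lines[1].name: 0.0, lines[2].name: -1.0}
    size_params = ["area", "perimeter", "minor_axis", "feret_d", "min_feret_d"]
    line_size = {lines[0].name: +0.8, lines[1].name: -0.2, lines[2].name: -0.5}
    means: dict[tuple[str, str], dict[str, float]] = {}
    for spec in lines:
        for phenotype in ("good", "bad"):
            sgn = 1.0 if phenotype == "good" else -1.0
            d = direction[spec.name]
            m = {}
            for q in size_params:
                m[q] = base[q] + scale[q] * (line_size[spec.name]
                                             + 0.45 * sgn * d)
            # packing: good colonies always have less free space, with a
            # line-dependent magnitude; shape factor shifts only weakly
            ais_shift = 0.9 if d != 0.0 else 0.25
            m["ais"] = base["ais"] - scale["ais"] * sgn * ais_shift
            m["shape_factor"] = base["shape_factor"] + scale["shape_factor"] * (
                0.30 * sgn if d == 0.0 else 0.15 * sgn)
            means[(spec.name, phenotype)] = m
    # covariance: one common size factor, shape factor anti-correlated with
    # the free intercellular space
    params = COLONY_PARAMETERS
    corr = np.eye(7)
    size_idx = [params.index(q) for q in size_params]
    for i in size_idx:
        for j in size_idx:
            if i != j:
                corr[i, j] = 0.7
    sf, ais = params.index("shape_factor"), params.index("ais")
    corr[sf, ais] = corr[ais, sf] = -0.3
    for i in size_idx:
        corr[i, ais] = corr[ais, i] = 0.4
    sd = np.asarray([scale[q] for q in params])
    cov = pd.DataFrame(corr * np.outer(sd, sd), index=params, columns=params)
    return means, cov


def planted_signal_table(
    informative: Mapping[str, float],
    n_per_group: int,
    seed: int,
    parameters: Sequence[str] = COLONY_PARAMETERS,
) -> pd.DataFrame:
    """Two-phenotype table where only the named descriptors carry signal.

    ``informative`` maps descriptor names to the mean shift of the good
    phenotype in within-group SD units; every other descriptor is
    exchangeable noise.  Descriptors are independent with unit SD (0.1 for
    the shape factor, which lives on a (0, 1] scale), so the planted effect
    size directly sets the Bayes-optimal separability.
    """
    base = {q: (0.5 if q == "shape_factor" else 10.0) for q in parameters}
    good = dict(base)
    for q, shift in informative.items():
        if q not in base:
            raise KeyError(f"unknown descriptor {q!r}")
        good[q] = base[q] + shift * (0.1 if q == "shape_factor" else 1.0)
    cov = np.diag([0.01 if q == "shape_factor" else 1.0 for q in parameters])
    return generate_feature_table(
        {("L1", "good"): good, ("L1", "bad"): base}, cov, n_per_group, seed)


def generate_dynamics_records(
    lines: Sequence[LineSpec] = DEFAULT_LINES,
    n_per_time: int = 12,
    noise_cv: float = 0.10,
    gap_fraction: float = 0.08,
    seed: int = 0,
) -> pd.DataFrame:
    """Colony records over the full 24-120 h time course.

    Expected size descriptors follow each line's monotone growth curve
    (areas scale with the curve, lengths with its square root); the shape
    factor follows the line's per-bin trend.  Noise is multiplicative
    lognormal with coefficient of variation ``noise_cv``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    bins = {24.0: 0, 48.0: 1, 72.0: 2, 96.0: 2, 120.0: 2}
    label = 1
    for spec in lines:
        for t in VALID_TIMES:
            area = spec.colony_area_at(t)
            sf = 0.72 + spec.shape_factor_trend[bins[t]]
            diam = 2.0 * math.sqrt(area / math.pi)
            mean = {
                "area": area,
                "perimeter": math.sqrt(4.0 * math.pi * area / sf),
                "minor_axis": 0.92 * diam,
                "feret_d": 1.12 * diam,
                "min_feret_d": 0.90 * diam,
                "shape_factor": sf,
                "ais": gap_fraction * area,
            }
            sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))
            for _ in range(n_per_time):
                noise = rng.lognormal(-sigma ** 2 / 2.0, sigma, size=7)
                row = {q: mean[q] * noise[i]
                       for i, q in enumerate(COLONY_PARAMETERS)}
                row["shape_factor"] = min(row["shape_factor"], 1.0)
                rows.append({
                    "unit": "colony", "label": label, "line": spec.name,
                    "passage": 24, "time_h": t,
                    "phenotype": "good", "clonality": "clonal", **row,
                })
                label += 1
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


# --------------------------------------------------------------------------
# qPCR Ct panels
# --------------------------------------------------------------------------

#: pluripotency marker panel assayed across lines, clonality and phenotype
PLURIPOTENCY_GENES = ("DNMT3B", "SALL4", "IGF1R", "CD9", "DPPA4", "OCT4",
                      "REX1", "NANOG", "SOX2", "KLF4")

#: germ-layer / differentiation markers assayed in embryoid bodies
DIFFERENTIATION_GENES = ("NESTIN", "TUBB3", "MSX2", "T", "SOX17", "GATA4")

#: housekeeping candidates for the reference-stability screen
HOUSEKEEPING_GENES = ("RN18S", "GAPDH", "RPL13A")

CT_COLUMNS = ["gene", "line", "clonality", "phenotype", "bio_rep", "tech_rep", "ct"]


@dataclass
class CtPanel:
    """Long-format qPCR panel: one row per technical measurement."""

    data: pd.DataFrame
    reference_gene: str = "RN18S"

    def __post_init__(self) -> None:
        missing = [c for c in CT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"Ct panel is missing columns: {missing}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("all Ct values must be positive")
        samples = self.data[["line", "clonality", "phenotype", "bio_rep"]]
        have_ref = set(map(tuple, samples[self.data["gene"] == self.reference_gene]
                           .itertuples(index=False)))
        all_samples = set(map(tuple, samples.itertuples(index=False)))
        if all_samples - have_ref:
            raise ValueError(
                f"reference gene {self.reference_gene!r} missing for "
                f"{len(all_samples - have_ref)} sample(s)")

    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out["reference_gene"] = self.reference_gene
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CtPanel":
        df = pd.read_csv(path)
        ref = "RN18S"
        if "reference_gene" in df.columns:
            ref = str(df["reference_gene"].iloc[0])
            df = df.drop(columns="reference_gene")
        return cls(df[CT_COLUMNS], reference_gene=ref)


def generate_ct_panel(
    genes: Sequence[str],
    groups: Sequence[str],
    fold_changes: Mapping[tuple[str, str], float] | None,
    ref_gene_ct: float = 18.0,
    noise_sd: float = 0.2,
    n_bio: int = 3,
    n_tech: int = 3,
    seed: int = 0,
    group_factor: str = "line",
    reference_gene: str = "RN18S",
    reference_group: str | None = None,
    base_ct: float = 25.0,
    extra_reference_sds: Mapping[str, float] | None = None,
) -> CtPanel:
    """Simulate a Ct panel with planted fold changes.

    For each target gene the true Ct in a group is lowered by log2 of the
    planted fold change relative to the reference group, so the expected
    2^-ddCt recovered downstream equals the planted fold.  The reference
    gene sits at ``ref_gene_ct`` in every sample with only measurement noise
    (``noise_sd``, per technical measurement).  ``extra_reference_sds`` adds
    per-sample instability to named candidate housekeeping genes, for
    exercising the reference-stability screen.
    """
    if group_factor not in ("line", "clonality", "phenotype"):
        raise ValueError("group_factor must be line, clonality or phenotype")
    fold_changes = dict(fold_changes or {})
    for (g, grp), f in fold_changes.items():
        if f <= 0:
            raise ValueError(f"fold change for ({g}, {grp}) must be positive")
    if reference_group is None:
        reference_group = groups[0]
    rng = np.random.default_rng(seed)
    extra = dict(extra_reference_sds or {})
    constants = {"line": "L1", "clonality": "clonal", "phenotype": "good"}
    rows = []
    all_genes = list(genes)
    for extra_gene in extra:
        if extra_gene not in all_genes:
            all_genes.append(extra_gene)
    if reference_gene not in all_genes:
        all_genes.append(reference_gene)
    for gene in all_genes:
        for group in groups:
            for b in range(1, n_bio + 1):
                if gene == reference_gene:
                    true_ct = ref_gene_ct
                elif gene in extra:
                    true_ct = ref_gene_ct + 2.0 + rng.normal(0.0, extra[gene])
                else:
                    fold = fold_changes.get((gene, group), 1.0)
                    true_ct = base_ct - math.log2(fold)
                for t in range(1, n_tech + 1):
                    ct = true_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                    row = dict(constants)
                    row[group_factor] = group
                    rows.append({"gene": gene, **row, "bio_rep": b,
                                 "tech_rep": t, "ct": ct})
    df = pd.DataFrame(rows, columns=CT_COLUMNS)
    return CtPanel(df, reference_gene=reference_gene)
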