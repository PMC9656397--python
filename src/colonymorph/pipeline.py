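"""End-to-end orchestration: simulate -> measure -> stats -> classify ->
express -> report.

A run is fully described by a :class:`RunConfig` (serializable to YAML) and
a seed; every output CSV is reproducible byte-for-byte from (config, seed,
inputs) and the report embeds the config hash.  Each stage is usable on its
own through the documented CSV contracts, which is also how the
command-line interface exposes them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import expression as expr
from . import stats as st
from . import synth
from .image import LabeledColonyImage
from .morphometry import RECORD_COLUMNS, measure_image

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"

ALL_STAGES = ("simulate", "measure", "stats", "classify", "express", "report")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    seed: int = 0
    outdir: str = "colonymorph_run"
    stages: tuple[str, ...] = ALL_STAGES
    # simulate
    n_per_group: int = 60
    n_images: int = 1  # labeled images rendered per (line, phenotype)
    image_time_h: float = 24.0
    ct_noise_sd: float = 0.2
    ct_n_bio: int = 3
    # stats
    screen_window: tuple[float, float] = (24.0, 48.0)
    # classify
    model_family: str = "logistic"
    cv_folds: int = 5
    cv_repeats: int = 2
    classify_window: tuple[float, float] | None = None
    # external input (instead of simulation)
    input_records: str | None = None
    column_map: dict = field(default_factory=dict)

    def classifier_config(self) -> clf.ClassifierConfig:
        return clf.ClassifierConfig(
            model_family=self.model_family, cv_folds=self.cv_folds,
            cv_repeats=self.cv_repeats, seed=self.seed % 2**31)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        for name in ("stages",):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        if cfg.screen_window is not None:
            cfg.screen_window = tuple(cfg.screen_window)
        if cfg.classify_window is not None:
            cfg.classify_window = tuple(cfg.classify_window)
        return cfg

    def hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, float_format=FLOAT_FORMAT)


REQUIRED_NUMERIC = ["area", "perimeter", "minor_axis", "feret_d",
                    "min_feret_d", "shape_factor"]
REQUIRED_META = ["line", "phenotype"]


def load_parameter_table(
    path,
    column_mapping: dict | None = None,
    unit: str | None = None,
    time_window: tuple[float, float] | None = None,
    return_rejected: bool = False,
):
    """Load and validate an external per-colony / per-cell parameter table.

    ``column_mapping`` maps the file's column names onto the canonical
    ones, absorbing whatever dialect an external deposit uses.  Rows that
    violate the record invariants (non-positive sizes, caliper ordering,
    intercellular space out of range, unparseable numerics) are rejected
    individually and reported with their row index; missing required
    columns raise immediately.  The measured unit is taken from a ``unit``
    column, from the argument, or inferred from the presence of
    intercellular-space values.
    """
    df = pd.read_csv(path)
    if column_mapping:
        df = df.rename(columns=dict(column_mapping))
    missing = [c for c in REQUIRED_NUMERIC + REQUIRED_META
               if c not in df.columns]
    if missing:
        raise ValueError(f"unmapped required column(s): {missing}")
    if "unit" not in df.columns:
        if unit is not None:
            df["unit"] = unit
        elif "ais" in df.columns:
            df["unit"] = np.where(df["ais"].notna(), "colony", "cell")
        else:
            df["unit"] = "cell"
    for optional, default in (("passage", 0), ("time_h", np.nan),
                              ("clonality", "unknown"), ("ais", np.nan),
                              ("label", 0)):
        if optional not in df.columns:
            df[optional] = default

    numeric = REQUIRED_NUMERIC + ["ais", "time_h"]
    parsed = df.copy()
    for col in numeric:
        parsed[col] = pd.to_numeric(parsed[col], errors="coerce")

    reasons = pd.Series("", index=parsed.index)
    for col in REQUIRED_NUMERIC:
        bad = parsed[col].isna() & df[col].notna()
        reasons[bad] += f"unparseable {col};"
    for col in ("area", "perimeter", "minor_axis", "feret_d", "min_feret_d",
                "shape_factor"):
        reasons[parsed[col] <= 0] += f"non-positive {col};"
    reasons[parsed[col].isna() & (reasons == "")] = ""  # NaN handled above
    reasons[parsed["min_feret_d"] > parsed["feret_d"] * (1 + 1e-9)] += \
        "min_feret_d > feret_d;"
    is_colony = parsed["unit"] == "colony"
    reasons[is_colony & parsed["ais"].notna()
            & ((parsed["ais"] < 0) | (parsed["ais"] >= parsed["area"]))] += \
        "ais outside [0, area);"
    rejected_mask = reasons != ""
    rejected = parsed[rejected_mask].copy()
    rejected["reason"] = reasons[rejected_mask]
    if len(rejected):
        logger.warning("rejected %d row(s): indices %s", len(rejected),
                       list(rejected.index[:20]))
    records = parsed[~rejected_mask].copy()
    if time_window is not None:
        records = records[records["time_h"].between(*time_window)]
    records = records[[c for c in RECORD_COLUMNS if c in records.columns]]
    records = records.reset_index(drop=True)
    if return_rejected:
        return records, rejected
    return records


@dataclass
class PipelineResult:
    """Paths and in-memory results of one pipeline run."""

    outdir: Path
    config: RunConfig
    records: pd.DataFrame | None = None
    classification: clf.PhenotypeClassifierResults | None = None
    expression: dict[str, pd.DataFrame] = field(default_factory=dict)


def _stage_simulate(cfg: RunConfig, out: Path, log: list[str]) -> pd.DataFrame:
    means, cov = synth.default_descriptor_presets()
    records = synth.generate_feature_table(
        means, cov, cfg.n_per_group, seed=cfg.seed % 2**31)
    write_records(records, out / "records.csv")
    dynamics = synth.generate_dynamics_records(seed=(cfg.seed + 1) % 2**31)
    write_records(dynamics, out / "dynamics_records.csv")
    log.append(f"simulate: {len(records)} descriptor records, "
               f"{len(dynamics)} dynamics records")
    if cfg.n_images > 0:
        img_dir = out / "images"
        pheno = {"good": synth.GOOD_PHENOTYPE, "bad": synth.BAD_PHENOTYPE}
        k = 0
        for line in synth.DEFAULT_LINES:
            for label, spec in pheno.items():
                for i in range(cfg.n_images):
                    img = synth.generate_colony_image(
                        line, spec, cfg.image_time_h,
                        seed=(cfg.seed + 7919 * k) % 2**31)
                    img.save(img_dir / f"{line.name}_{label}_{i}")
                    k += 1
        log.append(f"simulate: rendered {k} labeled colony images")
    panel = synth.generate_ct_panel(
        list(synth.PLURIPOTENCY_GENES),
        [s.name for s in synth.DEFAULT_LINES],
        fold_changes={("SOX2", "iPS1"): 2.0, ("KLF4", "iPS1"): 2.5,
                      ("REX1", "iPS2"): 0.5, ("SALL4", "iPS2"): 0.6},
        noise_sd=cfg.ct_noise_sd, n_bio=cfg.ct_n_bio,
        seed=(cfg.seed + 2) % 2**31,
        extra_reference_sds={"GAPDH": 0.6, "RPL13A": 1.0})
    panel.to_csv(out / "ct_panel.csv")
    log.append(f"simulate: Ct panel with {panel.data['gene'].nunique()} genes")
    return records


def _stage_measure(cfg: RunConfig, out: Path, log: list[str]) -> None:
    img_dir = out / "images"
    if not img_dir.exists():
        log.append("measure: no images directory; skipped")
        return
    stems = sorted({p.name[:-len("_labels.tif")]
                    for p in img_dir.glob("*_labels.tif")})
    frames = []
    for stem in stems:
        img = LabeledColonyImage.load(img_dir / stem)
        frames.append(measure_image(img))
    if frames:
        measured = pd.concat(frames, ignore_index=True)
        write_records(measured, out / "measured_records.csv")
        log.append(f"measure: {len(measured)} records from {len(stems)} images")


def _stage_stats(cfg: RunConfig, out: Path, records: pd.DataFrame,
                 log: list[str]) -> None:
    dyn_path = out / "dynamics_records.csv"
    if dyn_path.exists():
        dynamics = pd.read_csv(dyn_path)
        table = st.dynamics_table(dynamics, unit="colony")
        table.to_csv(out / "dynamics_summary.csv", index=False,
                     float_format=FLOAT_FORMAT)
        log.append(f"stats: dynamics summary ({len(table)} rows)")
    anova_rows = []
    for param in st.COLONY_PARAMETERS:
        res = st.two_way_anova(records[records["unit"] == "colony"], param)
        anova_rows.append({"parameter": param, "F": res.statistic,
                           "p_value": res.p_value,
                           "significant": res.significant})
    pd.DataFrame(anova_rows).to_csv(out / "anova_interaction.csv",
                                    index=False, float_format=FLOAT_FORMAT)
    screen = st.phenotype_screen(records, unit="colony",
                                 time_window=cfg.screen_window)
    screen.to_csv(out / "phenotype_screen.csv", index=False,
                  float_format=FLOAT_FORMAT)
    log.append(f"stats: ANOVA on 7 descriptors, screen on "
               f"{screen['line'].nunique()} lines "
               f"(window {cfg.screen_window[0]:g}-{cfg.screen_window[1]:g} h)")


def _stage_classify(cfg: RunConfig, out: Path, records: pd.DataFrame,
                    log: list[str]) -> clf.PhenotypeClassifierResults:
    data = records
    if cfg.classify_window is not None:
        data = records[records["time_h"].between(*cfg.classify_window)]
    model = clf.PhenotypeClassifier(data, config=cfg.classifier_config())
    results = model.fit(per_line=True)
    results.importance.table.to_csv(out / "importance.csv", index=False,
                                    float_format=FLOAT_FORMAT)
    results.curve_frame().to_csv(out / "topk_curve.csv", index=False,
                                 float_format=FLOAT_FORMAT)
    results.evaluation.confusion.to_frame().to_csv(out / "confusion.csv")
    subset_rows = [{"subset": "+".join(r.subset), "size": len(r.subset),
                    "mean_accuracy": r.mean_accuracy,
                    "sem_accuracy": r.sem_accuracy}
                   for r in results.importance.subset_results]
    pd.DataFrame(subset_rows).to_csv(out / "subset_results.csv", index=False,
                                     float_format=FLOAT_FORMAT)
    log.append(
        f"classify: full model {100 * results.full_model.mean_accuracy:.1f}% "
        f"+/- {100 * results.full_model.sem_accuracy:.1f}%, minimal model "
        f"k={results.minimal_k} ({', '.join(results.minimal_subset)}), "
        f"whole-sample accuracy {results.evaluation.accuracy_pct}%")
    return results


def _stage_express(cfg: RunConfig, out: Path, log: list[str]
                   ) -> dict[str, pd.DataFrame]:
    panel_path = out / "ct_panel.csv"
    if not panel_path.exists():
        log.append("express: no Ct panel; skipped")
        return {}
    panel = synth.CtPanel.from_csv(panel_path)
    stability = expr.reference_stability(
        panel, [g for g in synth.HOUSEKEEPING_GENES
                if g in set(panel.data["gene"]) or g == panel.reference_gene])
    stability.to_csv(out / "reference_stability.csv", index=False,
                     float_format=FLOAT_FORMAT)
    tables: dict[str, pd.DataFrame] = {}
    ref_line = sorted(panel.data["line"].unique())[0]
    table = expr.relative_expression(panel, "line", ref_line)
    table.to_csv(out / "expression_by_line.csv", index=False,
                 float_format=FLOAT_FORMAT)
    tables["line"] = table
    screen = expr.marker_screen(tables)
    screen.to_csv(out / "marker_screen.csv", index=False,
                  float_format=FLOAT_FORMAT)
    log.append(f"express: reference gene {stability.iloc[0]['gene']} most "
               f"stable; {len(table)} fold-change rows vs line {ref_line}")
    return tables


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the configured stages; outputs land in ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    log: list[str] = []
    result = PipelineResult(out, config)
    stages = tuple(config.stages)
    records = None
    try:
        if "simulate" in stages:
            records = _stage_simulate(config, out, log)
        elif config.input_records:
            records = load_parameter_table(config.input_records,
                                           config.column_map)
            log.append(f"load: {len(records)} records from "
                       f"{config.input_records}")
        elif (out / "records.csv").exists():
            records = pd.read_csv(out / "records.csv")
        result.records = records
        if "measure" in stages:
            _stage_measure(config, out, log)
        if "stats" in stages:
            if records is None:
                raise RuntimeError("stats stage needs records")
            _stage_stats(config, out, records, log)
        if "classify" in stages:
            if records is None:
                raise RuntimeError("classify stage needs records")
            result.classification = _stage_classify(config, out, records, log)
        if "express" in stages:
            result.expression = _stage_express(config, out, log)
    except Exception as err:
        stage = log[-1].split(":")[0] if log else "setup"
        raise RuntimeError(f"pipeline aborted after stage '{stage}': {err}"
                           ) from err
    if "report" in stages:
        report = [
            "# colonymorph run report",
            "",
            f"- config hash: `{config.hash()}`",
            f"- seed: {config.seed}",
            "",
            "## stages",
            "",
        ]
        report += [f"- {line}" for line in log]
        if result.classification is not None:
            report += ["", "## classification summary", "",
                       "```", result.classification.summary(), "```"]
        (out / "report.md").write_text("\n".join(report) + "\n")
    return result
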