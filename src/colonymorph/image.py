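"""Labeled colony image container and on-disk format.

A :class:`LabeledColonyImage` bundles the two rasters the measurement stage
needs — an integer cell-label mask (0 = background, k > 0 = cell k) and the
binary colony footprint — together with the physical pixel size and the
experimental metadata (cell line, passage, hours post-plating, phenotype and
clonality labels).

On disk an image is a triplet sharing a common stem:

* ``<stem>_labels.tif``   — 16-bit single-channel TIFF of cell labels
* ``<stem>_footprint.png``— 8-bit PNG of the footprint (0 / 255)
* ``<stem>_meta.txt``     — flat ``key=value`` sidecar
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import tifffile


@dataclass
class ImageMeta:
    line: str = "unknown"
    passage: int = 0
    time_h: float = 24.0
    phenotype: str = "good"
    clonality: str = "clonal"

    def as_dict(self) -> dict[str, Any]:
        return {
            "line": self.line,
            "passage": self.passage,
            "time_h": self.time_h,
            "phenotype": self.phenotype,
            "clonality": self.clonality,
        }


@dataclass
class LabeledColonyImage:
    """Cell label mask + colony footprint at a known pixel size."""

    cell_labels: np.ndarray
    colony_footprint: np.ndarray
    pixel_size: float = 1.0  # micrometres per pixel
    meta: ImageMeta = field(default_factory=ImageMeta)
    truth: Any = None  # generator ground truth (PhenotypeSpec), when synthetic

    def __post_init__(self) -> None:
        self.cell_labels = np.asarray(self.cell_labels)
        self.colony_footprint = np.asarray(self.colony_footprint, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.cell_labels.shape != self.colony_footprint.shape:
            raise ValueError("cell_labels and colony_footprint shapes differ")
        if self.cell_labels.min() < 0:
            raise ValueError("cell labels must be non-negative")
        outside = (self.cell_labels > 0) & ~self.colony_footprint
        if outside.any():
            raise ValueError(
                f"{int(outside.sum())} cell pixel(s) lie outside the colony footprint"
            )
        labels = np.unique(self.cell_labels)
        labels = labels[labels > 0]
        if labels.size and not np.array_equal(labels, np.arange(1, labels.size + 1)):
            raise ValueError("cell labels must be contiguous positive integers 1..n")

    @property
    def n_cells(self) -> int:
        return int(self.cell_labels.max())

    # ------------------------------------------------------------------ I/O
    def save(self, stem: str | Path) -> None:
        stem = Path(stem)
        stem.parent.mkdir(parents=True, exist_ok=True)
        if self.n_cells > np.iinfo(np.uint16).max:
            raise ValueError("too many cells for a 16-bit label raster")
        tifffile.imwrite(f"{stem}_labels.tif", self.cell_labels.astype(np.uint16))
        iio.imwrite(
            f"{stem}_footprint.png",
            (self.colony_footprint.astype(np.uint8) * 255),
        )
        lines = [f"pixel_size={self.pixel_size!r}"]
        lines += [f"{k}={v}" for k, v in self.meta.as_dict().items()]
        Path(f"{stem}_meta.txt").write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, stem: str | Path) -> "LabeledColonyImage":
        stem = Path(stem)
        labels = tifffile.imread(f"{stem}_labels.tif").astype(np.int64)
        footprint = iio.imread(f"{stem}_footprint.png") > 0
        raw = {}
        for line in Path(f"{stem}_meta.txt").read_text().splitlines():
            if "=" in line:
                k, v = line.split("=", 1)
                raw[k.strip()] = v.strip()
        meta = ImageMeta(
            line=raw.get("line", "unknown"),
            passage=int(raw.get("passage", 0)),
            time_h=float(raw.get("time_h", 24.0)),
            phenotype=raw.get("phenotype", "good"),
            clonality=raw.get("clonality", "clonal"),
        )
        return cls(labels, footprint, float(raw.get("pixel_size", 1.0)), meta)
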