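"""Shared fixtures: small rasters and tables generated at test time."""

import numpy as np
import pytest

from colonymorph import synth


def make_disk(radius: int, size: int | None = None) -> np.ndarray:
    """Digitized disk: pixel centers within ``radius`` of the raster center."""
    size = size or 2 * radius + 9
    yy, xx = np.mgrid[:size, :size]
    c = size / 2
    return ((yy - c + 0.5) ** 2 + (xx - c + 0.5) ** 2) <= radius * radius


def random_blob(rng: np.random.Generator, shape=(40, 60),
                density: float = 0.55) -> np.ndarray:
    """A filled, 4-connected random blob (largest component of noise)."""
    from scipy import ndimage

    noise = rng.random(shape) < density
    closed = ndimage.binary_closing(noise, iterations=2)
    lab, n = ndimage.label(closed)
    if n == 0:
        out = np.zeros(shape, bool)
        out[shape[0] // 2, shape[1] // 2] = True
        return out
    sizes = ndimage.sum_labels(closed, lab, np.arange(1, n + 1))
    blob = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(blob)


@pytest.fixture(scope="session")
def default_presets():
    return synth.default_descriptor_presets()


@pytest.fixture(scope="session")
def feature_table(default_presets):
    """Default study-condition descriptor table (3 lines x 2 phenotypes)."""
    means, cov = default_presets
    return synth.generate_feature_table(means, cov, n_per_group=60, seed=42)


@pytest.fixture(scope="session")
def small_colony_image():
    """One quickly generated colony image with a moderate gap fraction."""
    line = synth.LineSpec("test", base_area=1.5e4, growth_rate=0.0)
    pheno = synth.PhenotypeSpec("bad", gap_fraction=0.15, cell_elongation=1.5,
                                boundary_irregularity=0.04)
    return synth.generate_colony_image(line, pheno, time_h=24, seed=11)
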