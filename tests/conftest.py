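"""Shared fixtures: parametric contour families and small study designs."""

from __future__ import annotations

import numpy as np
import pytest

from owhshapes.synthetic_data import StudyDesign


def make_disc(rng: np.random.Generator, radius: float = 10.0, n: int = 72) -> np.ndarray:
    """Noisy circle contour (row, col)."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = radius * (1 + 0.03 * rng.normal(size=n))
    return np.column_stack([r * np.sin(th), r * np.cos(th)])


def make_rod(rng: np.random.Generator, length: float = 30.0, width: float = 4.0,
             n: int = 72) -> np.ndarray:
    """Elongated ellipse contour."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    w = width * (1 + 0.05 * rng.normal(size=n))
    return np.column_stack([w * np.sin(th), length * np.cos(th)])


def make_star(rng: np.random.Generator, radius: float = 12.0, arms: int = 6,
              n: int = 144) -> np.ndarray:
    """Spiky radial contour with ``arms`` lobes."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = radius * (1 + 0.6 * np.cos(arms * th) + 0.03 * rng.normal(size=n))
    return np.column_stack([r * np.sin(th), r * np.cos(th)])


FAMILIES = {"disc": make_disc, "rod": make_rod, "star": make_star}


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def shape_families(rng):
    """200 contours per family with ground-truth labels."""
    contours, labels = [], []
    for i, (name, make) in enumerate(FAMILIES.items()):
        for _ in range(200):
            contours.append(make(rng))
            labels.append(i)
    return contours, np.array(labels)


@pytest.fixture
def tiny_design():
    """Smallest study design satisfying every stage's preconditions."""
    return StudyDesign(
        regions=("cortex", "thalamus"),
        groups=("NC", "OGD2h", "Epo"),
        sexes=("M", "F"),
        slices_per_cell_of_design=2,
        cells_per_image=12,
        image_size=(320, 320),
        seed=11,
    )
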