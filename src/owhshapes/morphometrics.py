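"""Per-cell morphology parameters and test-set cell-count scaling.

Three parameters are computed for every segmented cell: perimeter (Euclidean
length of the sub-pixel outline polygon), area coverage (number of pixels
inside the segmented outline) and circularity (4*pi*A/P**2, a dimensionless
compactness that is 1 for a disc and approaches 0 for filamentous shapes).

Circularity uses the shoelace area of the sub-pixel contour polygon rather
than the raw pixel count: mixing a pixel-count area with a sub-pixel
perimeter can push the ratio above 1 for small discs.  The raw pixel count
is still reported as ``area_coverage`` because that is the quantity the
count-based analyses consume.  Both values are kept on each record.

Total cells per region/slice are estimated from the 20% test split by
multiplying the test-image count by 5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import CellObject

__all__ = [
    "MorphologyRecord",
    "CountEstimate",
    "polygon_area",
    "perimeter",
    "area_coverage",
    "circularity",
    "measure_cell",
    "measure_cells",
    "estimate_total_cells",
]

#: Factor mapping test-split counts to whole-study counts (test fraction 0.2).
COUNT_SCALE = 5


@dataclass(frozen=True)
class MorphologyRecord:
    """Morphology parameters for one segmented cell."""

    cell_id: str
    perimeter: float
    area_coverage: int
    circularity: float
    polygon_area: float


@dataclass(frozen=True)
class CountEstimate:
    """Estimated total cell count for one (region, group, slice) stratum."""

    region: str
    group: str
    slice_id: str
    test_count: int
    estimated_total: int


def _as_closed_vertices(contour: np.ndarray) -> np.ndarray:
    """Return contour vertices without a duplicated closing vertex."""
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("contour must be an (n, 2) array of vertices")
    if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        raise ValueError("degenerate contour: fewer than 3 distinct vertices")
    return pts


def polygon_area(contour: np.ndarray) -> float:
    """Unsigned shoelace area of a closed polygon.

    Vertices are (row, col) pairs; the closing edge back to the first vertex
    is implied.
    """
    pts = _as_closed_vertices(contour)
    r, c = pts[:, 0], pts[:, 1]
    return float(abs(np.sum(c * np.roll(r, -1) - np.roll(c, -1) * r)) / 2.0)


def perimeter(contour: np.ndarray) -> float:
    """Euclidean length of the closed contour polygon."""
    pts = _as_closed_vertices(contour)
    diffs = np.diff(np.vstack([pts, pts[:1]]), axis=0)
    return float(np.sum(np.hypot(diffs[:, 0], diffs[:, 1])))


def area_coverage(cell: CellObject) -> int:
    """Number of pixels inside the segmented cell outline (holes filled)."""
    return int(cell.pixel_count)


def circularity(area: float, perim: float) -> float:
    """Compactness 4*pi*A/P**2, clipped to at most 1.

    A disc scores 1; long thin or heavily branched shapes approach 0.
    """
    if area <= 0 or perim <= 0:
        raise ValueError("area and perimeter must both be positive")
    return min(1.0, 4.0 * np.pi * area / perim**2)


def measure_cell(cell: CellObject) -> MorphologyRecord:
    """Compute the full morphology record for one cell."""
    p = perimeter(cell.contour)
    a_poly = polygon_area(cell.contour)
    return MorphologyRecord(
        cell_id=cell.cell_id,
        perimeter=p,
        area_coverage=area_coverage(cell),
        circularity=circularity(a_poly, p),
        polygon_area=a_poly,
    )


def measure_cells(cells) -> pd.DataFrame:
    """Morphology table for a collection of :class:`CellObject`.

    Returns one row per cell with the image provenance carried along so the
    table can be joined to study metadata.
    """
    rows = []
    for cell in cells:
        rec = measure_cell(cell)
        rows.append(
            {
                "cell_id": rec.cell_id,
                "image_id": cell.image_id,
                "perimeter": rec.perimeter,
                "area_coverage": rec.area_coverage,
                "circularity": rec.circularity,
                "polygon_area": rec.polygon_area,
                "touches_border": cell.touches_border,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "image_id",
            "perimeter",
            "area_coverage",
            "circularity",
            "polygon_area",
            "touches_border",
        ],
    )


def estimate_total_cells(
    counts: pd.DataFrame,
    split: dict[str, str] | None = None,
) -> list[CountEstimate]:
    """Scale test-split cell counts to whole-study estimates.

    Parameters
    ----------
    counts
        One row per (region, group, slice_id) with a ``test_count`` column,
        or per-image rows with ``image_id`` that are summed per stratum.
    split
        Optional image_id -> {"train", "test"} assignment.  When given and
        the table carries ``image_id``, any train image present raises: the
        x5 scaling is only unbiased on the held-out 20%.
    """
    df = counts.copy()
    if split is not None and "image_id" in df.columns:
        assigned = df["image_id"].map(split)
        bad = df.loc[assigned != "test", "image_id"].tolist()
        if bad:
            raise ValueError(
                f"count table contaminated with non-test images: {bad[:5]}"
            )
    if "test_count" not in df.columns:
        df = (
            df.groupby(["region", "group", "slice_id"], sort=True)
            .size()
            .rename("test_count")
            .reset_index()
        )
    out = []
    for row in df.itertuples(index=False):
        n = int(row.test_count)
        if n < 0:
            raise ValueError("negative cell count")
        out.append(
            CountEstimate(
                region=row.region,
                group=row.group,
                slice_id=str(row.slice_id),
                test_count=n,
                estimated_total=COUNT_SCALE * n,
            )
        )
    return out
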