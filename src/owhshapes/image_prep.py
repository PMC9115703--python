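"""Channel handling, quadrant tiling, and the stratified 80:20 split.

Each acquired two-channel image (cell marker + nuclear stain) is split by
channel, tiled into four equal quadrants to increase image number, and the
resulting images are divided 80:20 into train and test sets stratified by
(sex, region, group).  The "at least two images remain per stratum"
constraint is enforced on the test side by default — the side whose counts
the x5 total-cell scaling treats as representative — with a switch to
enforce it on train instead.

Conventions: pixel coordinates are 0-based row-major.  Quadrants are
ordered (top-left, top-right, bottom-left, bottom-right); for odd
dimensions row ``H // 2`` starts the bottom pair and column ``W // 2``
starts the right pair, so larger remainders go rightward/downward.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "AnnotatedImage",
    "SplitAssignment",
    "split_channels",
    "restack_channels",
    "split_quadrants",
    "stratified_split",
    "write_tiff",
    "read_tiff",
]

MARKER = "marker"
NUCLEAR = "nuclear"


@dataclass(frozen=True)
class AnnotatedImage:
    """Pixel data plus the study metadata the statistics need.

    ``pixels`` is (C, H, W) unsigned-integer; ``channels`` maps a role name
    ("marker", "nuclear") to its channel index.  ``quadrant`` is None for a
    full frame and 1..4 for a tile.
    """

    image_id: str
    pixels: np.ndarray = field(repr=False)
    channels: dict[str, int]
    slice_id: str
    sex: str
    region: str
    group: str
    quadrant: int | None = None
    source: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = px[None]
        if px.ndim != 3:
            raise ValueError("pixels must be (C, H, W) or (H, W)")
        object.__setattr__(self, "pixels", px)
        for role, idx in self.channels.items():
            if not 0 <= idx < px.shape[0]:
                raise ValueError(f"channel role {role!r} points at missing plane {idx}")

    @property
    def stratum(self) -> tuple[str, str, str]:
        return (self.sex, self.region, self.group)

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channels:
            raise KeyError(f"{role} channel absent")
        return self.pixels[self.channels[role]]


@dataclass(frozen=True)
class SplitAssignment:
    """image_id -> {"train", "test"} with the per-stratum report."""

    assignment: dict[str, str]
    seed: int
    report: pd.DataFrame

    def __getitem__(self, image_id: str) -> str:
        return self.assignment[image_id]

    def ids(self, side: str) -> list[str]:
        return sorted(k for k, v in self.assignment.items() if v == side)


def split_channels(image: AnnotatedImage) -> tuple[AnnotatedImage, AnnotatedImage]:
    """Separate the marker and nuclear planes into single-channel images."""
    for role in (MARKER, NUCLEAR):
        if role not in image.channels:
            raise KeyError(f"{role} channel absent")
    out = []
    for role in (MARKER, NUCLEAR):
        out.append(
            replace(
                image,
                image_id=f"{image.image_id}_{role}",
                pixels=image.channel(role)[None].copy(),
                channels={role: 0},
            )
        )
    return out[0], out[1]


def restack_channels(marker: AnnotatedImage, nuclear: AnnotatedImage) -> np.ndarray:
    """Inverse of :func:`split_channels` at the pixel level."""
    return np.stack([marker.channel(MARKER), nuclear.channel(NUCLEAR)])


def split_quadrants(image: AnnotatedImage) -> list[AnnotatedImage]:
    """Tile an image into its four quadrants (a partition of the pixels)."""
    _, H, W = image.pixels.shape
    if H < 2 or W < 2:
        raise ValueError(f"cannot tile a {H}x{W} image into quadrants")
    r, c = H // 2, W // 2
    windows = [
        (slice(0, r), slice(0, c)),
        (slice(0, r), slice(c, W)),
        (slice(r, H), slice(0, c)),
        (slice(r, H), slice(c, W)),
    ]
    tiles = []
    for q, (rs, cs) in enumerate(windows, start=1):
        tiles.append(
            replace(
                image,
                image_id=f"{image.image_id}_q{q}",
                pixels=image.pixels[:, rs, cs].copy(),
                quadrant=q,
            )
        )
    return tiles


def _stratum_rng(seed: int, stratum: tuple[str, str, str]) -> np.random.Generator:
    # stable per-stratum stream: input order of images never matters
    digest = hashlib.sha256(("|".join(stratum)).encode()).digest()
    sub = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([seed, sub]))


def stratified_split(
    images,
    ratio: float = 0.80,
    seed: int = 0,
    min_per_stratum: int = 2,
    enforce_on: str = "test",
) -> SplitAssignment:
    """Deterministic stratified train/test split of annotated images.

    Within every (sex, region, group) stratum of ``n`` images,
    ``round((1 - ratio) * n)`` go to test, raised if needed so the
    ``enforce_on`` side keeps at least ``min_per_stratum`` images.  The
    draw depends only on the sorted image ids and the seed.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    if enforce_on not in ("test", "train"):
        raise ValueError("enforce_on must be 'test' or 'train'")
    strata: dict[tuple[str, str, str], list[str]] = {}
    for im in images:
        strata.setdefault(im.stratum, []).append(im.image_id)

    assignment: dict[str, str] = {}
    report_rows = []
    for stratum in sorted(strata):
        ids = sorted(strata[stratum])
        n = len(ids)
        floor_needed = 2 * min_per_stratum - 1  # one side gets min, other >= min-1
        if n < max(min_per_stratum + 1, floor_needed):
            raise ValueError(
                f"stratum {stratum} has only {n} images; cannot keep "
                f"{min_per_stratum} on the {enforce_on} side with both sides non-empty"
            )
        n_test = round((1.0 - ratio) * n)
        if enforce_on == "test":
            n_test = max(n_test, min_per_stratum)
            n_test = min(n_test, n - 1)
        else:
            n_test = min(n_test, n - min_per_stratum)
            n_test = max(n_test, 1)
        rng = _stratum_rng(seed, stratum)
        order = rng.permutation(n)
        test_ids = {ids[i] for i in order[:n_test]}
        for iid in ids:
            assignment[iid] = "test" if iid in test_ids else "train"
        report_rows.append(
            {
                "sex": stratum[0],
                "region": stratum[1],
                "group": stratum[2],
                "n_images": n,
                "n_train": n - n_test,
                "n_test": n_test,
            }
        )
    return SplitAssignment(
        assignment=assignment, seed=seed, report=pd.DataFrame(report_rows)
    )


def write_tiff(path, image: AnnotatedImage) -> None:
    """Write pixels as multi-channel 16-bit TIFF."""
    tifffile.imwrite(path, image.pixels.astype(np.uint16))


def read_tiff(path, **meta) -> AnnotatedImage:
    """Read a TIFF written by :func:`write_tiff`; metadata via keywords."""
    px = tifffile.imread(path)
    meta.setdefault("channels", {MARKER: 0, NUCLEAR: 1} if px.ndim == 3 else {MARKER: 0})
    meta.setdefault("image_id", str(path))
    meta.setdefault("slice_id", "")
    meta.setdefault("sex", "")
    meta.setdefault("region", "")
    meta.setdefault("group", "")
    return AnnotatedImage(pixels=px, source=str(path), **meta)
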