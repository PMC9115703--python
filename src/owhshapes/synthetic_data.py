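"""Synthetic fluorescence study generator with full ground truth.

Emulates the data the analysis pipeline consumes, at two levels:

* **Images** — two-channel (cell marker + nuclear stain) 16-bit frames
  containing non-overlapping cells of three morphological archetypes:
  *ameboid* (small, compact, near-circular), *ramified* (branched, low
  circularity) and *hyper-ramified* (larger, heavily branched, very low
  circularity).  Cells sit on a Gaussian-noise background; every rendered
  cell has a ground-truth record (phenotype, centroid, pixel count).

* **Regional outcomes** — per (region, slice, group) percentages of
  PI-positive cells.  Injury (OGD 2 h) adds a region-specific increment to
  the control baseline; a treatment removes a fraction of that increment.
  The removed fraction is a logistic function of the region's injury-induced
  phenotype-proportion shift weighted by ``coupling_beta``, so the strength
  of the phenotype/protection association is tunable (zero coupling gives a
  null design).  Slices are the unit of noise.

Determinism: a study uses one seed; per-image streams are derived by stable
hashing of the image's metadata, so adding images never perturbs existing
ones, and identical (design, seed) reproduce byte-identical output.

The outcome simulator can run without rendering pixels
(:func:`simulate_regional_outcomes`), which is how the statistical
parameter-recovery experiments reach hundreds of replicates; there the true
per-cell phenotype labels stand in for shape-mode labels.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage import draw as _skdraw

from .image_prep import MARKER, NUCLEAR, AnnotatedImage

__all__ = [
    "PhenotypeSpec",
    "StudyDesign",
    "StudyData",
    "default_phenotypes",
    "default_mixtures",
    "render_cell",
    "render_image",
    "simulate_regional_outcomes",
    "generate_study",
    "design_from_yaml",
    "design_to_yaml",
]

REGIONS = ("cortex", "thalamus", "corpus_callosum", "white_matter",
           "hippocampus", "basal_ganglia")
GROUPS = ("NC", "OGD1h", "OGD2h", "Epo", "AcAc")
SEXES = ("M", "F")
PHENOTYPES = ("ameboid", "ramified", "hyper_ramified")

CONTROL_GROUP = "NC"
INJURY_GROUP = "OGD2h"
TREATMENT_GROUPS = ("Epo", "AcAc")

_BRANCH_WIDTH = 2  # px, half-width of rendered processes


@dataclass(frozen=True)
class PhenotypeSpec:
    """Geometric recipe for one morphological archetype.

    ``size_px`` is the target cell area (mean, sd) in pixels; branched
    phenotypes spend part of that budget on ``branch_count`` processes of
    mean length ``branch_length_px``.  ``circularity_target`` is the rough
    compactness the rendering aims at and is used only for validation
    (a perfectly circular cell cannot carry branches).
    """

    name: str
    size_px: tuple[float, float]
    branch_count: int = 0
    branch_length_px: float = 0.0
    circularity_target: float = 0.9

    def __post_init__(self):
        mean, sd = self.size_px
        if mean <= 0 or sd < 0:
            raise ValueError("size_px mean must be positive, sd nonnegative")
        if not 0 < self.circularity_target <= 1:
            raise ValueError("circularity_target must be in (0, 1]")
        if self.branch_count < 0:
            raise ValueError("branch_count must be >= 0")
        if self.circularity_target >= 1.0 and self.branch_count > 0:
            raise ValueError(
                f"unsatisfiable spec {self.name!r}: circularity_target 1.0 "
                "is incompatible with branch_count > 0"
            )


def default_phenotypes() -> dict[str, PhenotypeSpec]:
    """The three archetypes with sizes well above the 25-pixel filter."""
    return {
        "ameboid": PhenotypeSpec("ameboid", (220.0, 30.0), 0, 0.0, 0.9),
        "ramified": PhenotypeSpec("ramified", (420.0, 60.0), 5, 28.0, 0.25),
        "hyper_ramified": PhenotypeSpec("hyper_ramified", (700.0, 90.0), 9, 30.0, 0.1),
    }


# Region-specific injury shift of phenotype mixture, as the fraction of
# probability mass moved under OGD 2 h: positive values move ramified mass
# toward ameboid (deramification), negative move it toward hyper-ramified.
_INJURY_SHIFT = {
    "cortex": 0.20,
    "basal_ganglia": 0.16,
    "corpus_callosum": 0.12,
    "hippocampus": 0.08,
    "thalamus": -0.04,
    "white_matter": -0.08,
}
_BASE_MIX = {"ameboid": 0.15, "ramified": 0.60, "hyper_ramified": 0.25}
# Fraction of the injury shift still present under each group.
_GROUP_SHIFT_FRACTION = {"NC": 0.0, "OGD1h": 0.5, "OGD2h": 1.0, "Epo": 0.4, "AcAc": 0.5}


def _shift_mixture(base: dict[str, float], delta: float) -> dict[str, float]:
    mix = dict(base)
    if delta >= 0:
        moved = min(delta, mix["ramified"])
        mix["ramified"] -= moved
        mix["ameboid"] += moved
    else:
        moved = min(-delta, mix["ramified"])
        mix["ramified"] -= moved
        mix["hyper_ramified"] += moved
    return mix


def default_mixtures(
    regions=REGIONS, groups=GROUPS, sexes=SEXES
) -> dict[tuple[str, str, str], dict[str, float]]:
    """Default phenotype mixture per (region, group, sex).

    Both sexes share mixtures by default; regional injury shifts follow the
    deramification-in-grey-matter / hypertrophy-in-white-matter pattern.
    """
    mixtures = {}
    for region in regions:
        shift = _INJURY_SHIFT.get(region, 0.10)
        for group in groups:
            frac = _GROUP_SHIFT_FRACTION.get(group, 0.0)
            mix = _shift_mixture(_BASE_MIX, frac * shift)
            for sex in sexes:
                mixtures[(region, group, sex)] = mix
    return mixtures


_PI_BASELINE = {
    "cortex": 12.0, "thalamus": 15.0, "corpus_callosum": 10.0,
    "white_matter": 14.0, "hippocampus": 11.0, "basal_ganglia": 13.0,
}
_PI_INJURY = {
    "cortex": 35.0, "thalamus": 25.0, "corpus_callosum": 30.0,
    "white_matter": 22.0, "hippocampus": 32.0, "basal_ganglia": 28.0,
}


@dataclass
class StudyDesign:
    """Everything that determines a synthetic study.

    All generator parameters are surfaced here (and in the YAML config)
    rather than hard-coded.  ``coupling_beta`` gives, per phenotype, the
    log-odds weight (per percentage point of injury-induced proportion
    shift) that drives treatment protection; all-zero coupling yields a
    null study.
    """

    regions: tuple[str, ...] = REGIONS
    groups: tuple[str, ...] = GROUPS
    sexes: tuple[str, ...] = SEXES
    slices_per_cell_of_design: int = 8
    phenotypes: dict[str, PhenotypeSpec] = field(default_factory=default_phenotypes)
    phenotype_mixtures: dict[tuple[str, str, str], dict[str, float]] = field(
        default_factory=default_mixtures
    )
    cells_per_image: int = 40
    image_size: tuple[int, int] = (512, 512)
    marker_intensity: float = 12000.0
    nuclear_intensity: float = 20000.0
    noise_sd: float = 800.0
    coupling_beta: dict[str, float] = field(
        default_factory=lambda: {"ameboid": 0.08, "ramified": 0.0,
                                 "hyper_ramified": -0.03}
    )
    pi_baseline: dict[str, float] = field(default_factory=lambda: dict(_PI_BASELINE))
    pi_injury_effect: dict[str, float] = field(default_factory=lambda: dict(_PI_INJURY))
    pi_noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for key, mix in self.phenotype_mixtures.items():
            props = np.array([mix.get(p, 0.0) for p in self.phenotypes])
            if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"mixture for {key} must be nonnegative and sum to 1"
                )
        for region in self.regions:
            for d in (self.pi_baseline, self.pi_injury_effect):
                v = d.get(region, 0.0)
                if not 0.0 <= v <= 100.0:
                    raise ValueError(f"PI percentage {v} for {region} outside [0, 100]")

    def mixture(self, region: str, group: str, sex: str) -> dict[str, float]:
        return self.phenotype_mixtures[(region, group, sex)]


@dataclass
class StudyData:
    """Output bundle of :func:`generate_study`."""

    images: list[AnnotatedImage]
    cell_truth: pd.DataFrame       # one row per rendered cell
    regional: pd.DataFrame         # one row per (region, group, sex, slice)


# ---------------------------------------------------------------------------
# deterministic sub-streams
# ---------------------------------------------------------------------------

def substream(seed: int, *key: str) -> np.random.Generator:
    """Child generator derived by stable hashing of string metadata."""
    digest = hashlib.sha256("|".join(key).encode()).digest()
    sub = int.from_bytes(digest[:4], "big") % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(seed), sub]))


# ---------------------------------------------------------------------------
# cell and image rendering
# ---------------------------------------------------------------------------

def _stamp_canvas(spec: PhenotypeSpec) -> int:
    body_r = max(np.sqrt(spec.size_px[0] / np.pi), 3.0)
    reach = body_r + 1.6 * max(spec.branch_length_px, 0.0)
    return int(2 * reach + 8)


def render_cell(spec: PhenotypeSpec, rng: np.random.Generator) -> np.ndarray:
    """Render one connected binary stamp matching the phenotype recipe.

    The achieved pixel area lands within 3 sd of the spec's target mean.
    Branchless specs give near-circular blobs; branched specs radiate
    thin processes from a central body, driving circularity down.
    """
    mean, sd = spec.size_px
    target = float(np.clip(rng.normal(mean, sd), max(0.3 * mean, 5.0), 2.0 * mean))
    size = _stamp_canvas(spec)
    center = size / 2.0

    n_br = spec.branch_count
    angles = None
    lengths = None
    if n_br > 0:
        base = rng.uniform(0, 2 * np.pi)
        angles = base + np.arange(n_br) * (2 * np.pi / n_br) \
            + rng.normal(0, 0.25, n_br)
        lengths = np.maximum(
            spec.branch_length_px * rng.uniform(0.7, 1.3, n_br), 3.0
        )
    wiggle = rng.normal(0, 0.18, n_br) if n_br else None
    branch_px_budget = float(np.sum(lengths) * _BRANCH_WIDTH) if n_br else 0.0
    # keep a visible body even when branches exhaust the area budget, but
    # never inflate a deliberately undersized cell past its target
    body_area = max(target - branch_px_budget, min(28.0, 0.9 * target))
    body_r = np.sqrt(body_area / np.pi)
    aspect = rng.uniform(0.85, 1.0)

    def _draw(scale: float) -> np.ndarray:
        img = np.zeros((size, size), dtype=bool)
        rr, cc = _skdraw.ellipse(
            center, center, scale * body_r / np.sqrt(aspect),
            scale * body_r * np.sqrt(aspect), shape=img.shape,
        )
        img[rr, cc] = True
        if n_br:
            for ang, ln, wg in zip(angles, lengths, wiggle):
                # each process: two straight segments with a kink mid-way
                r0, c0 = center, center
                seg = scale * ln / 2.0
                for k in range(2):
                    a = ang + k * wg * 4.0
                    r1 = r0 + seg * np.sin(a)
                    c1 = c0 + seg * np.cos(a)
                    rr, cc = _skdraw.line(
                        int(round(r0)), int(round(c0)),
                        int(round(np.clip(r1, 1, size - 2))),
                        int(round(np.clip(c1, 1, size - 2))),
                    )
                    img[rr, cc] = True
                    r0, c0 = np.clip(r1, 1, size - 2), np.clip(c1, 1, size - 2)
            img = ndimage.binary_dilation(img, iterations=_BRANCH_WIDTH // 2)
        # cells carry no internal holes (downstream masks are hole-filled)
        return ndimage.binary_fill_holes(img)

    scale = 1.0
    stamp = _draw(scale)
    for _ in range(6):
        area = int(stamp.sum())
        if abs(area - mean) <= 3 * sd or sd == 0:
            break
        scale *= np.sqrt(np.clip(target / max(area, 1), 0.5, 2.0))
        stamp = _draw(scale)
    # trim to tight bounding box
    rows = np.any(stamp, axis=1)
    cols = np.any(stamp, axis=0)
    stamp = stamp[rows.argmax():len(rows) - rows[::-1].argmax(),
                  cols.argmax():len(cols) - cols[::-1].argmax()]
    return stamp


def render_image(
    design: StudyDesign,
    region: str,
    group: str,
    sex: str,
    n_cells: int,
    rng: np.random.Generator,
    image_id: str = "img",
    slice_id: str = "s0",
    max_retries: int = 400,
) -> tuple[AnnotatedImage, pd.DataFrame]:
    """Render one two-channel frame plus its ground-truth cell table.

    Cells are drawn from the (region, group, sex) phenotype mixture and
    placed fully inside the frame without overlap by rejection sampling.
    """
    H, W = design.image_size
    marker = np.zeros((H, W), dtype=float)
    nuclear = np.zeros((H, W), dtype=float)
    occupancy = np.zeros((H, W), dtype=bool)

    phen_names = list(design.phenotypes)
    if n_cells > 0:
        mix = design.mixture(region, group, sex)
        probs = np.array([mix.get(p, 0.0) for p in phen_names])
        labels = rng.choice(len(phen_names), size=n_cells, p=probs)
    else:
        labels = np.array([], dtype=int)

    truth_rows = []
    for i, lab in enumerate(labels):
        spec = design.phenotypes[phen_names[lab]]
        stamp = render_cell(spec, rng)
        pad = ndimage.binary_dilation(stamp, iterations=2)
        h, w = stamp.shape
        if h >= H - 2 or w >= W - 2:
            raise ValueError(
                f"cell stamp {h}x{w} does not fit a {H}x{W} frame"
            )
        placed = False
        for _ in range(max_retries):
            r0 = int(rng.integers(1, H - h - 1))
            c0 = int(rng.integers(1, W - w - 1))
            if not np.any(occupancy[r0:r0 + h, c0:c0 + w] & pad):
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell {i + 1}/{n_cells} after {max_retries} "
                f"retries; density too high for a {H}x{W} frame"
            )
        occupancy[r0:r0 + h, c0:c0 + w] |= pad
        marker[r0:r0 + h, c0:c0 + w][stamp] = design.marker_intensity
        rows, cols = np.nonzero(stamp)
        cy, cx = float(rows.mean() + r0), float(cols.mean() + c0)
        rr, cc = _skdraw.disk((cy, cx), 3.0, shape=(H, W))
        nuclear[rr, cc] = design.nuclear_intensity
        truth_rows.append(
            {
                "image_id": image_id,
                "cell_id": f"{image_id}:t{i:04d}",
                "phenotype": phen_names[lab],
                "centroid_row": cy,
                "centroid_col": cx,
                "true_pixel_count": int(stamp.sum()),
            }
        )

    if design.noise_sd > 0:
        marker += rng.normal(0.0, design.noise_sd, size=(H, W))
        nuclear += rng.normal(0.0, design.noise_sd, size=(H, W))
    pixels = np.clip(np.stack([marker, nuclear]), 0, 65535).astype(np.uint16)
    image = AnnotatedImage(
        image_id=image_id,
        pixels=pixels,
        channels={MARKER: 0, NUCLEAR: 1},
        slice_id=slice_id,
        sex=sex,
        region=region,
        group=group,
    )
    cols = ["image_id", "cell_id", "phenotype", "centroid_row", "centroid_col",
            "true_pixel_count"]
    return image, pd.DataFrame(truth_rows, columns=cols)


# ---------------------------------------------------------------------------
# regional outcome model
# ---------------------------------------------------------------------------

def _injury_fraction(group: str) -> float:
    return {"NC": 0.0, "OGD1h": 0.5, "OGD2h": 1.0}.get(group, 1.0)


def phenotype_shift_points(design: StudyDesign, region: str, sex: str) -> dict[str, float]:
    """True injury shift of each phenotype's proportion, in percentage points
    (injury-group mixture minus control mixture)."""
    inj = design.mixture(region, INJURY_GROUP, sex)
    ctl = design.mixture(region, CONTROL_GROUP, sex)
    return {p: 100.0 * (inj.get(p, 0.0) - ctl.get(p, 0.0)) for p in design.phenotypes}


def protection_fraction(design: StudyDesign, region: str, sex: str) -> float:
    """Fraction of the injury PI increment removed by treatment, in (-1, 1).

    2*sigmoid(beta . shift) - 1: zero coupling gives 0 (no systematic
    effect); strong positive coupling on a phenotype that increases with
    injury approaches full protection.  Negative values model exacerbation.
    """
    shift = phenotype_shift_points(design, region, sex)
    score = sum(design.coupling_beta.get(p, 0.0) * shift[p] for p in shift)
    return float(2.0 / (1.0 + np.exp(-score)) - 1.0)


def simulate_regional_outcomes(
    design: StudyDesign, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-slice PI percentages and phenotype counts without rendering pixels.

    One row per (region, group, sex, slice): PI_pct from the outcome model,
    multinomial phenotype counts (``n_<phenotype>`` columns, total =
    ``cells_per_image``), the true protection fraction and the true
    protected indicator (positive systematic protection).
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([design.seed]))
    phen_names = list(design.phenotypes)
    rows = []
    for region in design.regions:
        base = design.pi_baseline.get(region, 10.0)
        injury = design.pi_injury_effect.get(region, 25.0)
        for group in design.groups:
            for sex in design.sexes:
                mix = design.mixture(region, group, sex)
                probs = np.array([mix.get(p, 0.0) for p in phen_names])
                f = (
                    protection_fraction(design, region, sex)
                    if group in TREATMENT_GROUPS
                    else 0.0
                )
                mean_pi = base + injury * _injury_fraction(group) * (1.0 - f)
                for s in range(design.slices_per_cell_of_design):
                    counts = rng.multinomial(design.cells_per_image, probs)
                    pi = float(
                        np.clip(rng.normal(mean_pi, design.pi_noise_sd), 0.0, 100.0)
                    )
                    row = {
                        "region": region,
                        "group": group,
                        "sex": sex,
                        "slice_id": f"{region[:3]}_{group}_{sex}_{s:02d}",
                        "PI_pct": pi,
                        "protection_fraction_true": f if group in TREATMENT_GROUPS else np.nan,
                        "protected_true": bool(f > 0) if group in TREATMENT_GROUPS else False,
                    }
                    row.update({f"n_{p}": int(c) for p, c in zip(phen_names, counts)})
                    rows.append(row)
    return pd.DataFrame(rows)


def generate_study(design: StudyDesign) -> StudyData:
    """Render the full synthetic study: images, cell truth, regional table.

    One image per (region, group, sex, slice), each with
    ``cells_per_image`` cells on average (Poisson).  The regional table is
    produced by the same outcome model as
    :func:`simulate_regional_outcomes` (under its own sub-stream), so the
    tabular and image routes share the coupling structure.
    """
    images: list[AnnotatedImage] = []
    truths = []
    for region in design.regions:
        for group in design.groups:
            for sex in design.sexes:
                for s in range(design.slices_per_cell_of_design):
                    slice_id = f"{region[:3]}_{group}_{sex}_{s:02d}"
                    image_id = f"{slice_id}_i0"
                    rng = substream(design.seed, "image", region, group, sex, str(s))
                    n_cells = int(rng.poisson(design.cells_per_image))
                    img, truth = render_image(
                        design, region, group, sex, n_cells, rng,
                        image_id=image_id, slice_id=slice_id,
                    )
                    images.append(img)
                    truths.append(truth)
    outcome_rng = substream(design.seed, "regional_outcomes")
    regional = simulate_regional_outcomes(design, outcome_rng)
    cell_truth = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame(
            columns=["image_id", "cell_id", "phenotype", "centroid_row",
                     "centroid_col", "true_pixel_count"]
        )
    )
    return StudyData(images=images, cell_truth=cell_truth, regional=regional)


# ---------------------------------------------------------------------------
# YAML config round-trip
# ---------------------------------------------------------------------------

def design_to_yaml(design: StudyDesign, path) -> None:
    doc = {
        "regions": list(design.regions),
        "groups": list(design.groups),
        "sexes": list(design.sexes),
        "slices_per_cell_of_design": design.slices_per_cell_of_design,
        "cells_per_image": design.cells_per_image,
        "image_size": list(design.image_size),
        "marker_intensity": design.marker_intensity,
        "nuclear_intensity": design.nuclear_intensity,
        "noise_sd": design.noise_sd,
        "pi_noise_sd": design.pi_noise_sd,
        "seed": design.seed,
        "coupling_beta": dict(design.coupling_beta),
        "pi_baseline": dict(design.pi_baseline),
        "pi_injury_effect": dict(design.pi_injury_effect),
        "phenotypes": {
            name: {
                "size_px": list(spec.size_px),
                "branch_count": spec.branch_count,
                "branch_length_px": spec.branch_length_px,
                "circularity_target": spec.circularity_target,
            }
            for name, spec in design.phenotypes.items()
        },
        "phenotype_mixtures": {
            f"{r}|{g}|{x}": dict(mix)
            for (r, g, x), mix in design.phenotype_mixtures.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def design_from_yaml(path) -> StudyDesign:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    kwargs = {}
    for key in ("slices_per_cell_of_design", "cells_per_image", "marker_intensity",
                "nuclear_intensity", "noise_sd", "pi_noise_sd", "seed",
                "coupling_beta", "pi_baseline", "pi_injury_effect"):
        if key in doc:
            kwargs[key] = doc[key]
    for key in ("regions", "groups", "sexes"):
        if key in doc:
            kwargs[key] = tuple(doc[key])
    if "image_size" in doc:
        kwargs["image_size"] = tuple(doc["image_size"])
    if "phenotypes" in doc:
        kwargs["phenotypes"] = {
            name: PhenotypeSpec(
                name=name,
                size_px=tuple(spec["size_px"]),
                branch_count=spec.get("branch_count", 0),
                branch_length_px=spec.get("branch_length_px", 0.0),
                circularity_target=spec.get("circularity_target", 0.9),
            )
            for name, spec in doc["phenotypes"].items()
        }
    if "phenotype_mixtures" in doc:
        kwargs["phenotype_mixtures"] = {
            tuple(key.split("|")): dict(mix)
            for key, mix in doc["phenotype_mixtures"].items()
        }
    return StudyDesign(**kwargs)
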