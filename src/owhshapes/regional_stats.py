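"""Regional statistics linking morphology shifts to neuroprotection.

The analysis layer consumes three tidy tables — per-cell morphology,
per-cell shape-mode assignments, and per-slice regional PI percentages —
and produces the study's statistical readouts:

* a-priori Kruskal–Wallis + Dunn pairwise comparisons (injury vs control,
  injury vs each treatment), adjusted over the planned pairs only;
* the neuroprotection metric: relative change in PI-positive percentage
  against the regional OGD 2 h median, and its dichotomization
  (protected <=> PI% strictly below that median);
* generalized linear models of region-level morphology change vs
  per-slice neuroprotection percent (identity link; R^2 and slope p);
* per-mode odds contrasts from cell-level logistic models with
  sex + region*group terms (cortex and OGD 2 h as references);
* logistic prediction of the protected indicator from per-region
  shape-mode proportion shifts, reporting the odds ratio per percentage
  point, Wald 95% CI and in-sample AUROC (rank statistic, ties counted
  half).

Cells are treated as independent in the odds models and AUROC is
in-sample, matching how such slice studies are usually summarized;
inestimable contrasts from empty design cells are reported as NaN rows
flagged ``inestimable`` rather than raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "StatResult",
    "results_to_frame",
    "auroc",
    "kruskal_dunn",
    "neuroprotection_percent",
    "dichotomize_protection",
    "regress_morphchange_vs_protection",
    "sm_odds_contrasts",
    "sm_shift",
    "predict_protection_from_sm_shift",
]

PLANNED_PAIRS = (("OGD2h", "NC"), ("OGD2h", "Epo"), ("OGD2h", "AcAc"))


@dataclass
class StatResult:
    """One comparison or model term."""

    label: str
    statistic: str                # "H", "z", "OR", "R2", "AUROC", ...
    estimate: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_raw: float = float("nan")
    p_adjusted: float = float("nan")
    method: str = ""
    flags: tuple[str, ...] = field(default_factory=tuple)


def results_to_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "statistic": r.statistic,
                "estimate": r.estimate,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "method": r.method,
                "flags": ";".join(r.flags),
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# rank statistics
# ---------------------------------------------------------------------------

def auroc(outcome, score) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) statistic.

    Equals the probability that a random positive outscores a random
    negative, ties counted one half.  Raises when only one class is
    present, where the curve is undefined.
    """
    y = np.asarray(outcome, dtype=bool)
    x = np.asarray(score, dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("separation: AUROC undefined with a single outcome class")
    ranks = sps.rankdata(x)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def kruskal_dunn(
    values_by_group: dict[str, np.ndarray],
    planned_pairs=PLANNED_PAIRS,
    adjust: str = "holm",
) -> list[StatResult]:
    """Kruskal–Wallis H (tie-corrected) plus Dunn z tests on planned pairs.

    Only pairs whose two groups are present are tested; the multiplicity
    adjustment runs over those planned pairs alone.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    for g, v in groups.items():
        if v.size == 0:
            raise ValueError(f"empty group {g!r}")
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    H, p_kw = sps.kruskal(*groups.values())
    out = [
        StatResult(
            label="omnibus", statistic="H", estimate=float(H),
            p_raw=float(p_kw), method="kruskal-wallis",
        )
    ]

    pooled = np.concatenate(list(groups.values()))
    ranks = sps.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    start = 0
    for g, v in groups.items():
        mean_rank[g] = float(ranks[start:start + v.size].mean())
        start += v.size
    N = pooled.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_base = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))

    pairs = [p for p in planned_pairs if p[0] in groups and p[1] in groups]
    dunn: list[StatResult] = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / groups[a].size + 1.0 / groups[b].size))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = float(2.0 * sps.norm.sf(abs(z)))
        dunn.append(
            StatResult(
                label=f"{a} vs {b}", statistic="z", estimate=float(z),
                p_raw=p, method=f"dunn-{adjust}",
            )
        )
    if dunn:
        if adjust == "none":
            adj = [r.p_raw for r in dunn]
        else:
            adj = multipletests([r.p_raw for r in dunn], method=adjust)[1]
        for r, pa in zip(dunn, adj):
            r.p_adjusted = float(pa)
    return out + dunn


# ---------------------------------------------------------------------------
# neuroprotection metric
# ---------------------------------------------------------------------------

def neuroprotection_percent(pi_pct: float, reference_median: float) -> float:
    """Relative reduction in PI-positive % vs the injury reference median.

    Positive values mean protection; -100 means a doubling of PI-positive
    cells relative to the reference.
    """
    if reference_median <= 0:
        raise ValueError("reference median must be positive")
    return 100.0 * (reference_median - pi_pct) / reference_median


def dichotomize_protection(
    table: pd.DataFrame,
    injury_group: str = "OGD2h",
    treatment_groups=("Epo", "AcAc"),
    pi_col: str = "PI_pct",
) -> pd.DataFrame:
    """Per-slice protected indicator against the regional injury median.

    A treated slice counts as protected when its PI% is strictly below the
    median PI% of the injury-group slices in the same region; a tie is not
    protection.  Also reports the continuous relative change.
    """
    out_rows = []
    for region, sub in table.groupby("region", sort=True):
        ref_rows = sub[sub["group"] == injury_group]
        if ref_rows.empty:
            raise ValueError(f"region {region!r} has no {injury_group} slices")
        ref = float(ref_rows[pi_col].median())
        for row in sub[sub["group"].isin(treatment_groups)].itertuples(index=False):
            pi = float(getattr(row, pi_col))
            out_rows.append(
                {
                    "region": region,
                    "slice_id": row.slice_id,
                    "group": row.group,
                    "PI_pct": pi,
                    "reference_median": ref,
                    "relative_change": neuroprotection_percent(pi, ref)
                    if ref > 0 else np.nan,
                    "protected": bool(pi < ref),
                }
            )
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

def regress_morphchange_vs_protection(
    morph_change: pd.DataFrame,
    protection: pd.DataFrame,
    predictor_col: str,
    response_col: str = "relative_change",
) -> StatResult:
    """Identity-link linear model: per-slice neuroprotection % on the
    region-level change of one morphology parameter.

    ``morph_change`` holds one row per region with ``predictor_col``;
    ``protection`` one row per (region, slice) with ``response_col``.
    """
    df = protection.merge(morph_change[["region", predictor_col]], on="region")
    x = df[predictor_col].to_numpy(float)
    y = df[response_col].to_numpy(float)
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct predictor values")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return StatResult(
        label=predictor_col,
        statistic="R2",
        estimate=float(res.rsquared),
        p_raw=float(res.pvalues[1]),
        method="ols-identity",
    )


# ---------------------------------------------------------------------------
# shape-mode odds models
# ---------------------------------------------------------------------------

def _logit_fit(formula: str, data: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = smf.logit(formula, data=data)
        return model.fit(disp=0, maxiter=200)


def sm_odds_contrasts(
    cells: pd.DataFrame,
    modes=None,
    region_ref: str = "cortex",
    group_ref: str = "OGD2h",
    sex_ref: str = "F",
) -> pd.DataFrame:
    """Cell-level odds of displaying each shape mode.

    For every mode, a binomial logistic model (that mode vs all others)
    with sex + region*group terms is fit on the cell table (columns
    ``sm``, ``sex``, ``region``, ``group``).  Reported contrasts: sex
    (M vs F), each region vs the cortex reference (at the reference
    group), and each treatment vs OGD 2 h within each region.  Wald ORs
    with 95% CI; contrasts that cannot be estimated (empty design cells,
    separation) come back as NaN rows flagged ``inestimable``.
    """
    req = {"sm", "sex", "region", "group"}
    if not req.issubset(cells.columns):
        raise ValueError(f"cell table must have columns {sorted(req)}")
    if modes is None:
        modes = sorted(cells["sm"].unique())
    regions = sorted(cells["region"].unique())
    groups = sorted(cells["group"].unique())
    sex_term = f"C(sex, Treatment('{sex_ref}'))"
    region_term = f"C(region, Treatment('{region_ref}'))"
    group_term = f"C(group, Treatment('{group_ref}'))"
    formula = f"y ~ {sex_term} + {region_term} * {group_term}"

    rows = []

    def _add(sm_label, contrast, estimate=None, se=None, p=None, flags=()):
        if estimate is None:
            rows.append(
                {
                    "sm": sm_label, "contrast": contrast, "OR": np.nan,
                    "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                    "flags": ";".join(flags) or "inestimable",
                }
            )
        else:
            half = 1.959963984540054 * se
            rows.append(
                {
                    "sm": sm_label, "contrast": contrast,
                    "OR": float(np.exp(estimate)),
                    "ci_low": float(np.exp(estimate - half)),
                    "ci_high": float(np.exp(estimate + half)),
                    "p": float(p), "flags": ";".join(flags),
                }
            )

    for mode in modes:
        data = cells.assign(y=(cells["sm"] == mode).astype(int))
        contrasts: list[tuple[str, str]] = [("sex: M vs F", f"{sex_term}[T.M]")]
        for region in regions:
            if region != region_ref:
                contrasts.append(
                    (f"region: {region} vs {region_ref}", f"{region_term}[T.{region}]")
                )
        for group in groups:
            if group == group_ref:
                continue
            for region in regions:
                name = f"group: {group} vs {group_ref} in {region}"
                term = f"{group_term}[T.{group}]"
                if region != region_ref:
                    term = f"{term} + {region_term}[T.{region}]:{group_term}[T.{group}]"
                contrasts.append((name, term))
        try:
            res = _logit_fit(formula, data)
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
            for name, _ in contrasts:
                _add(mode, name)
            continue
        small = _small_cells(data)
        for name, term in contrasts:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    tt = res.t_test(f"{term} = 0")
                est = float(np.atleast_1d(tt.effect)[0])
                se = float(np.atleast_1d(tt.sd.ravel())[0])
                if not np.isfinite(est) or not np.isfinite(se) or se > 50:
                    _add(mode, name, flags=("inestimable",))
                else:
                    flags = ("small-sample",) if name in small else ()
                    _add(mode, name, est, se, float(tt.pvalue), flags)
            except (ValueError, np.linalg.LinAlgError):
                _add(mode, name)
    return pd.DataFrame(rows)


def _small_cells(data: pd.DataFrame, min_count: int = 5) -> set[str]:
    """Contrast names touching a design cell with very few positives."""
    flagged: set[str] = set()
    counts = data.groupby(["region", "group"], observed=True)["y"].sum()
    for (region, group), c in counts.items():
        if c < min_count:
            flagged.add(f"group: {group} vs OGD2h in {region}")
    return flagged


# ---------------------------------------------------------------------------
# shape-mode shifts -> protection
# ---------------------------------------------------------------------------

def sm_shift(
    table: pd.DataFrame,
    group_a: str,
    group_b: str,
    proportion_cols=None,
) -> pd.DataFrame:
    """Per-region change of each mode's mean proportion, group_a - group_b,
    in percentage points.  Rows sum to zero across modes."""
    if proportion_cols is None:
        proportion_cols = [c for c in table.columns if c.startswith("p_sm")]
    if not proportion_cols:
        raise ValueError("no shape-mode proportion columns found")
    out = []
    for region, sub in table.groupby("region", sort=True):
        a = sub[sub["group"] == group_a]
        b = sub[sub["group"] == group_b]
        if a.empty or b.empty:
            raise ValueError(
                f"region {region!r} lacks group "
                f"{group_a if a.empty else group_b!r}"
            )
        row = {"region": region}
        for col in proportion_cols:
            row[f"d_{col}"] = 100.0 * (a[col].mean() - b[col].mean())
        out.append(row)
    return pd.DataFrame(out)


def _single_logistic(x: np.ndarray, y: np.ndarray, groups=None) -> dict:
    """Logistic fit of a binary outcome on one continuous predictor.

    Returns the slope OR per unit, Wald CI, p, in-sample AUROC of the
    fitted probabilities, and a separation flag when the predictor
    perfectly separates the classes (OR diverges there and the Wald CI is
    meaningless, but AUROC = 1 is still reported).  With ``groups`` the
    variance is cluster-robust and the CI uses a t critical value with
    (number of clusters - 1) degrees of freedom.
    """
    y = np.asarray(y, dtype=int)
    if y.min() == y.max():
        raise ValueError("separation: AUROC undefined with a single outcome class")
    X = sm.add_constant(np.asarray(x, dtype=float))
    predictor_auc = auroc(y.astype(bool), x)
    separated = predictor_auc in (0.0, 1.0)
    crit = 1.959963984540054
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            if groups is not None:
                res = sm.Logit(y, X).fit(
                    disp=0, maxiter=200, cov_type="cluster",
                    cov_kwds={"groups": np.asarray(groups)},
                )
                crit = float(sps.t.ppf(0.975, len(np.unique(groups)) - 1))
            else:
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            beta = float(res.params[1])
            se = float(res.bse[1])
            p = float(res.pvalues[1])
            fitted = np.asarray(res.predict(X), dtype=float)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        separated = True
        beta, se, p = np.inf, np.inf, np.nan
        fitted = np.asarray(x, dtype=float)
    if not np.isfinite(se) or se > 1e3:
        separated = True
    half = crit * se
    with np.errstate(over="ignore"):
        or_ = float(np.exp(min(beta, 700.0))) if np.isfinite(beta) else np.inf
        lo = float(np.exp(max(beta - half, -700.0))) if np.isfinite(half) else np.nan
        hi = float(np.exp(min(beta + half, 700.0))) if np.isfinite(half) else np.nan
    return {
        "OR": or_,
        "ci_low": lo,
        "ci_high": hi,
        "p": p,
        "auroc": auroc(y.astype(bool), fitted),
        "separation": separated,
    }


def predict_protection_from_sm_shift(
    shifts: pd.DataFrame,
    outcomes: pd.DataFrame,
    predictors=None,
    combined=None,
    cluster_by_region: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Logistic prediction of the protected indicator from mode shifts.

    ``shifts`` has one row per region (``d_p_sm*`` columns in percentage
    points); ``outcomes`` one row per (region, slice) with ``protected``.
    Each predictor gets its own single-variable model; ``combined`` (a
    list of predictor columns) adds one multi-predictor model whose AUROC
    uses the joint fitted probabilities.

    The default variance treats slices as independent.  Because every
    slice in a region shares the same predictor value and the same
    empirical reference median, ``cluster_by_region=True`` switches the
    single-predictor models to region-clustered robust standard errors
    with t critical values (conservative with few regions).

    Returns (results table, ROC coordinates of each model).
    """
    if predictors is None:
        predictors = [c for c in shifts.columns if c.startswith("d_")]
    df = outcomes.merge(shifts, on="region")
    groups = df["region"].to_numpy() if cluster_by_region else None
    y = df["protected"].to_numpy(bool)
    if y.min() == y.max():
        raise ValueError("separation: AUROC undefined with a single outcome class")

    rows = []
    roc_rows = []

    def _roc_points(label: str, score: np.ndarray) -> None:
        order = np.argsort(-score, kind="stable")
        tp = np.concatenate([[0], np.cumsum(y[order])])
        fp = np.concatenate([[0], np.cumsum(~y[order])])
        for t, f in zip(tp, fp):
            roc_rows.append(
                {
                    "model": label,
                    "fpr": f / max((~y).sum(), 1),
                    "tpr": t / max(y.sum(), 1),
                }
            )

    for col in predictors:
        x = df[col].to_numpy(float)
        fit = _single_logistic(x, y, groups=groups)
        rows.append(
            {
                "model": col, "term": col, "OR": fit["OR"],
                "ci_low": fit["ci_low"], "ci_high": fit["ci_high"],
                "p": fit["p"], "auroc": fit["auroc"],
                "flags": "separation" if fit["separation"] else "",
            }
        )
        _roc_points(col, x)

    if combined:
        X = sm.add_constant(df[list(combined)].to_numpy(float))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", PerfectSeparationWarning)
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                res = sm.Logit(y.astype(int), X).fit(disp=0, maxiter=200)
            fitted = np.asarray(res.predict(X), dtype=float)
            auc = auroc(y, fitted)
            label = "combined: " + "+".join(combined)
            for j, col in enumerate(combined, start=1):
                beta, se = float(res.params[j]), float(res.bse[j])
                half = 1.959963984540054 * se
                rows.append(
                    {
                        "model": label, "term": col,
                        "OR": float(np.exp(min(beta, 700.0))),
                        "ci_low": float(np.exp(max(beta - half, -700.0))),
                        "ci_high": float(np.exp(min(beta + half, 700.0))),
                        "p": float(res.pvalues[j]), "auroc": auc,
                        "flags": "" if se < 1e3 else "separation",
                    }
                )
            _roc_points(label, fitted)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            label = "combined: " + "+".join(combined)
            for col in combined:
                rows.append(
                    {
                        "model": label, "term": col, "OR": np.inf,
                        "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                        "auroc": 1.0, "flags": "separation",
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(roc_rows)
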