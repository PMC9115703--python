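"""Statistical layer: rank tests, protection metric, odds models, AUROC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from owhshapes.regional_stats import (
    auroc,
    dichotomize_protection,
    kruskal_dunn,
    neuroprotection_percent,
    predict_protection_from_sm_shift,
    regress_morphchange_vs_protection,
    sm_odds_contrasts,
    sm_shift,
)


def kruskal_by_ranks(groups):
    """Direct-ranking oracle: H = 12/(N(N+1)) * sum n_i Rbar_i^2 - 3(N+1)."""
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    H, start = 0.0, 0
    for g in groups:
        r = ranks[start:start + len(g)]
        H += len(g) * r.mean() ** 2
        start += len(g)
    return 12.0 / (N * (N + 1)) * H - 3 * (N + 1)


class TestKruskalDunn:
    def test_worked_example(self):
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        res = kruskal_dunn(groups, planned_pairs=[("a", "b")])
        assert res[0].estimate == pytest.approx(7.2)
        assert res[0].estimate == pytest.approx(
            kruskal_by_ranks([v for v in groups.values()])
        )

    def test_identical_groups_null(self):
        res = kruskal_dunn(
            {"a": [1.0, 2.0, 3.0, 4.0], "b": [1.0, 2.0, 3.0, 4.0]},
            planned_pairs=[("a", "b")],
        )
        assert res[0].estimate == pytest.approx(0.0, abs=1e-9)
        assert res[1].p_raw == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            kruskal_dunn({"a": [1, 2], "b": []})

    def test_adjustment_over_planned_pairs_only(self):
        rng = np.random.default_rng(0)
        groups = {g: rng.normal(i, 1, 10) for i, g in
                  enumerate(["NC", "OGD2h", "Epo", "AcAc"])}
        res = kruskal_dunn(groups)
        dunn = res[1:]
        assert len(dunn) == 3  # only the a-priori pairs
        assert all(r.p_adjusted >= r.p_raw - 1e-12 for r in dunn)

    def test_null_rejection_rate_calibrated(self):
        rng = np.random.default_rng(42)
        rejections = 0
        n_sim = 500
        for _ in range(n_sim):
            groups = {k: rng.normal(size=8) for k in ("a", "b", "c")}
            res = kruskal_dunn(groups, planned_pairs=[])
            rejections += res[0].p_raw < 0.05
        assert 0.02 <= rejections / n_sim <= 0.08


class TestProtectionMetric:
    @pytest.mark.parametrize(
        "pi,ref,expected", [(10, 40, 75.0), (40, 40, 0.0), (80, 40, -100.0)]
    )
    def test_relative_change(self, pi, ref, expected):
        assert neuroprotection_percent(pi, ref) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            neuroprotection_percent(10, 0)

    def test_dichotomization_strict_inequality(self):
        tbl = pd.DataFrame(
            [
                {"region": "cortex", "group": "OGD2h", "slice_id": f"o{i}",
                 "PI_pct": v}
                for i, v in enumerate([30.0, 40.0, 50.0])
            ]
            + [
                {"region": "cortex", "group": "Epo", "slice_id": "t0",
                 "PI_pct": 39.9},
                {"region": "cortex", "group": "Epo", "slice_id": "t1",
                 "PI_pct": 40.0},
            ]
        )
        out = dichotomize_protection(tbl)
        by_slice = out.set_index("slice_id")["protected"]
        assert bool(by_slice["t0"]) is True
        assert bool(by_slice["t1"]) is False
        assert (out["reference_median"] == 40.0).all()

    def test_missing_injury_rows_named(self):
        tbl = pd.DataFrame(
            [{"region": "thalamus", "group": "Epo", "slice_id": "t",
              "PI_pct": 10.0}]
        )
        with pytest.raises(ValueError, match="thalamus"):
            dichotomize_protection(tbl)


class TestMorphRegression:
    def test_exact_linear_relation(self):
        morph = pd.DataFrame({"region": list("abcdef"),
                              "d_area": [1.0, 2, 3, 4, 5, 6]})
        prot = pd.DataFrame(
            {"region": list("abcdef"), "relative_change": [2.0, 4, 6, 8, 10, 12]}
        )
        res = regress_morphchange_vs_protection(morph, prot, "d_area")
        assert res.estimate == pytest.approx(1.0)

    def test_null_r2_small(self):
        rng = np.random.default_rng(1)
        r2 = []
        for _ in range(200):
            morph = pd.DataFrame({"region": range(6), "d": rng.normal(size=6)})
            prot = pd.DataFrame(
                {"region": np.repeat(range(6), 10),
                 "relative_change": rng.normal(size=60)}
            )
            r2.append(
                regress_morphchange_vs_protection(morph, prot, "d").estimate
            )
        assert np.median(r2) < 0.05

    def test_too_few_levels_rejected(self):
        morph = pd.DataFrame({"region": ["a", "b"], "d": [1.0, 2.0]})
        prot = pd.DataFrame({"region": ["a", "b"], "relative_change": [1.0, 2.0]})
        with pytest.raises(ValueError):
            regress_morphchange_vs_protection(morph, prot, "d")


def _cells_2x2(rng, n=4000, p_m=0.2, p_f=0.4):
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    p = np.where(sex == "M", p_m, p_f)
    is5 = rng.random(n) < p
    return pd.DataFrame(
        {
            "sm": np.where(is5, 5, 1),
            "sex": sex,
            "region": "cortex",
            "group": "OGD2h",
        }
    )


class TestOddsContrasts:
    def test_sex_odds_match_closed_form(self, rng):
        cells = _cells_2x2(rng)
        res = sm_odds_contrasts(cells, modes=[5])
        sex_row = res[res["contrast"] == "sex: M vs F"].iloc[0]
        tab = pd.crosstab(cells["sex"], cells["sm"] == 5)
        a, b = tab.loc["M", True], tab.loc["M", False]
        c, d = tab.loc["F", True], tab.loc["F", False]
        assert sex_row["OR"] == pytest.approx((a * d) / (b * c), rel=1e-6)
        # truth (0.2/0.8)/(0.4/0.6) = 0.375 within the CI
        assert sex_row["ci_low"] < 0.375 < sex_row["ci_high"]

    def test_wald_ci_coverage_near_nominal(self):
        rng = np.random.default_rng(3)
        true_or = (0.2 / 0.8) / (0.4 / 0.6)
        cover = 0
        n_rep = 200
        for _ in range(n_rep):
            res = sm_odds_contrasts(_cells_2x2(rng, n=1000), modes=[5])
            row = res[res["contrast"] == "sex: M vs F"].iloc[0]
            cover += row["ci_low"] <= true_or <= row["ci_high"]
        assert 0.91 <= cover / n_rep <= 0.99

    def test_empty_design_cell_inestimable_not_fatal(self, rng):
        cells = pd.concat(
            [
                _cells_2x2(rng, n=400),
                pd.DataFrame(
                    {"sm": [5] * 5 + [1] * 5, "sex": "M",
                     "region": "thalamus", "group": "NC"}
                ),
            ],
            ignore_index=True,
        )
        res = sm_odds_contrasts(cells, modes=[5])
        # thalamus never sees Epo: that contrast must be flagged, not raised
        missing = res[res["contrast"].str.contains("thalamus")]
        assert len(missing) > 0


class TestSMShift:
    @pytest.fixture
    def prop_table(self):
        return pd.DataFrame(
            [
                {"region": "cortex", "group": "NC",
                 "p_sm1": 0.3, "p_sm2": 0.4, "p_sm3": 0.3},
                {"region": "cortex", "group": "OGD2h",
                 "p_sm1": 0.4, "p_sm2": 0.35, "p_sm3": 0.25},
            ]
        )

    def test_hand_built_shift(self, prop_table):
        out = sm_shift(prop_table, "OGD2h", "NC")
        row = out.iloc[0]
        assert row["d_p_sm1"] == pytest.approx(10.0)
        assert row["d_p_sm2"] == pytest.approx(-5.0)

    def test_shift_sums_to_zero(self, prop_table):
        out = sm_shift(prop_table, "OGD2h", "NC")
        assert out.filter(like="d_p_sm").sum(axis=1).abs().max() < 1e-9

    def test_identical_groups_zero_shift(self, prop_table):
        tbl = prop_table.copy()
        tbl.loc[1, ["p_sm1", "p_sm2", "p_sm3"]] = tbl.loc[
            0, ["p_sm1", "p_sm2", "p_sm3"]
        ]
        out = sm_shift(tbl, "OGD2h", "NC")
        assert out.filter(like="d_p_sm").abs().max().max() < 1e-12

    def test_missing_group_rejected(self, prop_table):
        with pytest.raises(ValueError, match="lacks group"):
            sm_shift(prop_table, "OGD2h", "Epo")


class TestAUROC:
    def test_monotone_transform_invariance(self, rng):
        y = rng.random(200) < 0.4
        x = rng.normal(size=200) + y
        assert auroc(y, x) == auroc(y, np.exp(3 * x))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="AUROC undefined"):
            auroc(np.ones(10, bool), np.arange(10))

    def test_against_closed_form_small_case(self):
        y = np.array([1, 1, 0, 0], bool)
        x = np.array([3.0, 1.0, 2.0, 1.0])
        # pairs: (3>2)=1, (3>1)=1, (1<2)=0, (1==1)=0.5 -> 2.5/4
        assert auroc(y, x) == pytest.approx(0.625)


class TestProtectionModels:
    def _frames(self, rng, n=500, effect=0.0):
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-effect * x))
        y = rng.random(n) < p
        shifts = pd.DataFrame({"region": range(n), "d_p_sm5": x})
        outcomes = pd.DataFrame(
            {"region": range(n), "slice_id": range(n), "protected": y}
        )
        return shifts, outcomes

    def test_null_predictor_auroc_half(self):
        rng = np.random.default_rng(8)
        aucs = [
            predict_protection_from_sm_shift(*self._frames(rng))[0]
            .iloc[0]["auroc"]
            for _ in range(30)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_perfect_separation_flagged(self):
        shifts = pd.DataFrame({"region": range(20),
                               "d_p_sm5": np.arange(20.0)})
        outcomes = pd.DataFrame(
            {"region": range(20), "slice_id": range(20),
             "protected": np.arange(20) >= 10}
        )
        res, _ = predict_protection_from_sm_shift(shifts, outcomes)
        row = res.iloc[0]
        assert row["auroc"] == 1.0
        assert "separation" in row["flags"]

    def test_single_class_outcome_rejected(self):
        shifts = pd.DataFrame({"region": [0, 1], "d_p_sm5": [0.0, 1.0]})
        outcomes = pd.DataFrame(
            {"region": [0, 1], "slice_id": [0, 1], "protected": [True, True]}
        )
        with pytest.raises(ValueError, match="AUROC undefined"):
            predict_protection_from_sm_shift(shifts, outcomes)

    def test_combined_model_reported(self, rng):
        shifts, outcomes = self._frames(rng, effect=1.0)
        shifts["d_p_sm1"] = rng.normal(size=len(shifts))
        res, roc = predict_protection_from_sm_shift(
            shifts, outcomes, combined=["d_p_sm1", "d_p_sm5"]
        )
        combined = res[res["model"].str.startswith("combined")]
        assert len(combined) == 2
        assert combined["auroc"].nunique() == 1
        assert not roc.empty

    def test_effect_recovered_with_correct_sign(self, rng):
        shifts, outcomes = self._frames(rng, effect=0.8)
        res, _ = predict_protection_from_sm_shift(shifts, outcomes)
        row = res.iloc[0]
        assert row["OR"] > 1
        assert row["ci_low"] > 1
        assert row["auroc"] > 0.6
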