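"""Normalized-error statistics: summaries, ANOVA, Tukey-Kramer, propagation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from phantomt1 import (
    BiasRecord,
    group_summary,
    normalized_error,
    per_sphere_pairwise,
    propagate_bias,
    two_way_anova,
)
from phantomt1.stats import records_frame


def make_frame(values_by_vendor, sphere=1, t1_nmr=2033.0, field=3.0, modality="VFA"):
    rows = []
    for vendor, vals in values_by_vendor.items():
        for s, v in enumerate(vals):
            rows.append({
                "sphere_index": sphere,
                "t1_measured_ms": t1_nmr * (1 + v / 100.0),
                "t1_nmr_ms": t1_nmr,
                "vendor": vendor,
                "field_tesla": field,
                "modality": modality,
                "system_index": s,
            })
    return records_frame(pd.DataFrame(rows))


class TestNormalizedError:
    @pytest.mark.parametrize("measured,ref,expected", [
        (2033.0, 2033.0, 0.0),
        (2200.0, 2000.0, 10.0),
        (1600.0, 2000.0, -20.0),
    ])
    def test_direct_arithmetic(self, measured, ref, expected):
        assert normalized_error(measured, ref) == pytest.approx(expected)

    @given(st.floats(10.0, 5000.0), st.floats(10.0, 5000.0), st.floats(0.01, 100.0))
    def test_scale_invariance(self, measured, ref, c):
        assert normalized_error(c * measured, c * ref) == pytest.approx(
            normalized_error(measured, ref), abs=1e-9
        )

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            normalized_error(100.0, 0.0)
        with pytest.raises(ValueError):
            BiasRecord(1, 100.0, -5.0, "A", 3.0, "IR")


class TestGroupSummary:
    def test_identical_values_have_zero_width_ci(self):
        df = make_frame({"A": [4.0, 4.0, 4.0]})
        s = group_summary(df)
        assert s["mean"].iloc[0] == pytest.approx(4.0)
        assert s["ci_low"].iloc[0] == pytest.approx(4.0)
        assert s["ci_high"].iloc[0] == pytest.approx(4.0)

    def test_two_point_interval_matches_textbook_t_formula(self):
        # values {0, 10}: mean 5, sd = 10/sqrt(2), half-width t_{.975,1} sd/sqrt(2)
        df = make_frame({"A": [0.0, 10.0]})
        s = group_summary(df)
        t_crit = 12.706204736174698  # 97.5th percentile of t with 1 df
        half = t_crit * (10.0 / np.sqrt(2.0)) / np.sqrt(2.0)
        assert s["mean"].iloc[0] == pytest.approx(5.0)
        assert s["ci_high"].iloc[0] - s["mean"].iloc[0] == pytest.approx(half, rel=1e-9)

    def test_translation_shifts_mean_not_width(self):
        a = group_summary(make_frame({"A": [1.0, 3.0, 7.0]}))
        b = group_summary(make_frame({"A": [6.0, 8.0, 12.0]}))
        assert b["mean"].iloc[0] - a["mean"].iloc[0] == pytest.approx(5.0)
        assert (b["ci_high"] - b["ci_low"]).iloc[0] == pytest.approx(
            (a["ci_high"] - a["ci_low"]).iloc[0], rel=1e-9
        )

    def test_singleton_group_flagged(self):
        s = group_summary(make_frame({"A": [2.0]}))
        assert bool(s["singleton"].iloc[0])
        assert np.isnan(s["ci_low"].iloc[0])


def balanced_two_way_oracle(frame):
    """Textbook balanced two-way ANOVA interaction F and p via direct sums."""
    y = frame["normalized_error_pct"].to_numpy()
    a = frame["vendor"].to_numpy()
    b = frame["field_tesla"].to_numpy()
    al, bl = np.unique(a), np.unique(b)
    n = len(y) // (len(al) * len(bl))
    grand = y.mean()
    ss_a = n * len(bl) * sum((y[a == ai].mean() - grand) ** 2 for ai in al)
    ss_b = n * len(al) * sum((y[b == bi].mean() - grand) ** 2 for bi in bl)
    ss_cells = n * sum(
        (y[(a == ai) & (b == bi)].mean() - grand) ** 2 for ai in al for bi in bl
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(
        ((y[(a == ai) & (b == bi)] - y[(a == ai) & (b == bi)].mean()) ** 2).sum()
        for ai in al for bi in bl
    )
    df_ab = (len(al) - 1) * (len(bl) - 1)
    df_err = len(al) * len(bl) * (n - 1)
    f = (ss_ab / df_ab) / (ss_err / df_err)
    return f, sps.f.sf(f, df_ab, df_err)


class TestTwoWayAnova:
    def test_matches_hand_computation_on_small_balanced_design(self):
        rng = np.random.default_rng(3)
        rows = []
        for vendor in "AB":
            for field in (1.5, 3.0):
                for s in range(2):
                    rows.append({
                        "sphere_index": 1, "t1_nmr_ms": 1000.0,
                        "t1_measured_ms": 1000.0 + rng.normal(0, 40),
                        "vendor": vendor, "field_tesla": field,
                        "modality": "IR", "system_index": s,
                    })
        df = records_frame(pd.DataFrame(rows))
        p, table = two_way_anova(df)
        _, p_oracle = balanced_two_way_oracle(df)
        assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_detects_injected_interaction(self):
        rng = np.random.default_rng(10)
        reject = 0
        n_sim = 60
        for _ in range(n_sim):
            rows = []
            for vendor in "AB":
                for field in (1.5, 3.0):
                    inter = 10.0 if (vendor == "B") and (field == 3.0) else 0.0
                    for s in range(10):
                        rows.append({
                            "sphere_index": 1, "t1_nmr_ms": 1000.0,
                            "t1_measured_ms": 1000.0 * (1 + (inter + rng.normal(0, 3)) / 100),
                            "vendor": vendor, "field_tesla": field,
                            "modality": "IR", "system_index": s,
                        })
            p, _ = two_way_anova(pd.DataFrame(rows))
            reject += p < 0.05
        assert reject / n_sim > 0.9

    def test_single_level_factor_rejected(self):
        df = make_frame({"A": [1.0, 2.0]})
        with pytest.raises(ValueError, match="levels"):
            two_way_anova(df)


class TestPerSpherePairwise:
    def test_identical_groups_give_p_one(self):
        df = make_frame({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]})
        res = per_sphere_pairwise(df, 3.0, "VFA")
        assert res.pairwise["p_adj"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        assert not res.pairwise["reject"].iloc[0]

    def test_two_groups_reduce_to_one_way_anova(self):
        df = make_frame({"A": [0.0, 1.5, 2.5, 4.0], "B": [2.0, 3.5, 5.0, 6.0]})
        res = per_sphere_pairwise(df, 3.0, "VFA")
        p_anova = res.anova_p.iloc[0]
        p_tukey = res.pairwise["p_adj"].iloc[0]
        assert p_tukey == pytest.approx(p_anova, rel=1e-4)

    def test_offset_vendor_detected_null_pair_not(self):
        rng = np.random.default_rng(123)
        hits_offset, hits_null = 0, 0
        n_sim = 50
        for _ in range(n_sim):
            df = make_frame({
                "A": rng.normal(0, 2, 6), "B": rng.normal(0, 2, 6),
                "C": rng.normal(10, 2, 6),
            })
            res = per_sphere_pairwise(df, 3.0, "VFA")
            t = res.pairwise.set_index(["group1", "group2"])
            hits_offset += bool(t.loc[("A", "C"), "reject"] and t.loc[("B", "C"), "reject"])
            hits_null += bool(t.loc[("A", "B"), "reject"])
        assert hits_offset / n_sim > 0.95
        assert hits_null / n_sim <= 0.1

    def test_pairwise_p_symmetric_under_relabeling(self):
        rng = np.random.default_rng(5)
        vals = {v: rng.normal(v_off, 2, 5) for v, v_off in [("A", 0), ("B", 3), ("C", 5)]}
        res1 = per_sphere_pairwise(make_frame(vals), 3.0, "VFA")
        swapped = {"A": vals["C"], "B": vals["B"], "C": vals["A"]}
        res2 = per_sphere_pairwise(make_frame(swapped), 3.0, "VFA")
        assert np.allclose(
            np.sort(res1.pairwise["p_adj"]), np.sort(res2.pairwise["p_adj"]), rtol=1e-9
        )

    def test_familywise_null_rate_controlled(self):
        rng = np.random.default_rng(77)
        n_sim, any_reject = 200, 0
        for _ in range(n_sim):
            df = make_frame({v: rng.normal(0, 2, 5) for v in "ABC"})
            res = per_sphere_pairwise(df, 3.0, "VFA")
            any_reject += bool(res.pairwise["reject"].any())
        # familywise error of the HSD family stays near alpha
        assert any_reject / n_sim <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_sim)

    def test_requires_two_vendors(self):
        with pytest.raises(ValueError, match="2 vendors"):
            per_sphere_pairwise(make_frame({"A": [1.0, 2.0]}), 3.0, "VFA")


class TestPropagateBias:
    def test_zero_bias_zero_dispersion_is_identity(self):
        assert propagate_bias(1355.0, 187.0, 0.0, 0.0) == (1168.0, 1542.0)

    def test_low_grade_glioma_example_direct_arithmetic(self):
        lo, hi = propagate_bias(1355.0, 187.0, -15.0, 10.0)
        assert lo == pytest.approx((1 - 0.25) * 1168.0)
        assert hi == pytest.approx((1 - 0.05) * 1542.0)

    def test_tissue_separation_ir_vs_biased_vfa(self):
        """IR-level bias keeps LGG/GBM T1 ranges separable; a -15% VFA vendor
        bias with 10% dispersion makes them overlap."""
        lgg, gbm = (1355.0, 187.0), (1863.0, 70.0)
        for bias in (2.0, 10.0):  # IR-style biases, 7% dispersion
            lgg_rng = propagate_bias(*lgg, bias, 7.0)
            gbm_rng = propagate_bias(*gbm, bias, 7.0)
            assert lgg_rng[1] < gbm_rng[0]
        lgg_rng = propagate_bias(*lgg, -15.0, 10.0)
        gbm_rng = propagate_bias(*gbm, -15.0, 10.0)
        assert lgg_rng[1] > gbm_rng[0]  # ranges overlap

    @given(st.floats(0.0, 30.0), st.floats(0.0, 30.0), st.floats(-30.0, 30.0))
    def test_widening_dispersion_never_narrows_range(self, d1, d2, bias):
        lo1, hi1 = propagate_bias(1000.0, 100.0, bias, min(d1, d2))
        lo2, hi2 = propagate_bias(1000.0, 100.0, bias, max(d1, d2))
        assert lo2 <= lo1 + 1e-9 and hi2 >= hi1 - 1e-9

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            propagate_bias(-10.0, 5.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            propagate_bias(1000.0, 100.0, 0.0, -1.0)
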