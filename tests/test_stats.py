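"""Group statistics: BH-FDR, t-maps, intensity values, symptom correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from msfnc import (
    attach_scores,
    bh_fdr,
    group_diff,
    intensity_values,
    make_ground_truth,
    sample_cohort,
    symptom_correlation,
)


def bh_oracle(p):
    """Literal Benjamini-Hochberg: sort, m*p/i, cumulative min from the top."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


class TestBhFdr:
    def test_hand_computed_case(self):
        """p = (.01,.02,.03,.04) all adjust to .04."""
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_fdr(np.ones(10)), 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        """Exact agreement with the sort-and-cummin construction."""
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 101)
        p = rng.random(n)
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), atol=1e-12)

    def test_q_at_least_p(self):
        rng = np.random.default_rng(99)
        p = rng.random(50)
        assert (bh_fdr(p) >= p - 1e-12).all()

    def test_nonfinite_fatal(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.1, np.nan]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        hnp.arrays(
            float,
            hnp.array_shapes(min_dims=1, max_dims=1, min_side=1, max_side=100),
            elements=st.floats(0.0, 1.0),
        )
    )
    def test_property_oracle_monotone_bounded(self, p):
        """For any p-vector: q matches the oracle, lies in [p, 1], and is
        monotone in the p-ordering."""
        q = bh_fdr(p)
        np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestIntensity:
    def test_positive_t_small_q(self):
        """t > 0 (higher in controls), q = 0.01 gives intensity +2."""
        assert intensity_values(np.array([3.0]), np.array([0.01]))[0] == pytest.approx(2.0)

    def test_negative_t_flips_sign(self):
        assert intensity_values(np.array([-3.0]), np.array([0.01]))[0] == pytest.approx(-2.0)

    def test_q_one_gives_zero(self):
        assert intensity_values(np.array([2.0]), np.array([1.0]))[0] == 0.0

    def test_q_floor_keeps_finite(self):
        assert np.isfinite(intensity_values(np.array([1.0]), np.array([0.0]))[0])


class TestGroupDiff:
    def _null_features(self, n=40, f=30, seed=0):
        rng = np.random.default_rng(seed)
        feats = pd.DataFrame(rng.standard_normal((n, f)))
        feats.columns = [f"f{i}" for i in range(f)]
        groups = np.array(["TC"] * (n // 2) + ["SZ"] * (n // 2))
        return feats, groups

    def test_direction_convention(self):
        """Higher values in SZ give negative t (TC - SZ) and negative
        intensity."""
        rng = np.random.default_rng(1)
        x = rng.standard_normal((60, 2))
        x[30:, 0] += 3.0       # SZ increase on feature 0
        feats = pd.DataFrame(x, columns=["up_in_sz", "null"])
        groups = np.array(["TC"] * 30 + ["SZ"] * 30)
        res = group_diff(feats, groups)
        assert res.loc["up_in_sz", "t"] < 0
        assert res.loc["up_in_sz", "intensity"] < 0

    def test_permuted_labels_control_false_positives(self):
        """Mean fraction of q < 0.05 under label permutation stays <= 0.05."""
        feats, groups = self._null_features(seed=2)
        rng = np.random.default_rng(3)
        fracs = []
        for _ in range(200):
            perm = rng.permutation(len(groups))
            res = group_diff(feats, groups[perm])
            fracs.append((res["q"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05

    def test_q_never_below_p(self):
        feats, groups = self._null_features(seed=4)
        res = group_diff(feats, groups)
        assert (res["q"] >= res["p"] - 1e-12).all()

    def test_single_group_fatal(self):
        feats, _ = self._null_features()
        with pytest.raises(ValueError):
            group_diff(feats, np.array(["TC"] * len(feats)))

    def test_welch_differs_for_unbalanced_groups(self):
        rng = np.random.default_rng(5)
        x = np.vstack([rng.normal(0, 1, (10, 5)), rng.normal(0, 4, (40, 5))])
        feats = pd.DataFrame(x, columns=list("abcde"))
        groups = np.array(["TC"] * 10 + ["SZ"] * 40)
        res_w = group_diff(feats, groups, welch=True)
        res_s = group_diff(feats, groups, welch=False)
        assert not np.allclose(res_w["p"], res_s["p"])


class TestSymptomCorrelation:
    def test_noise_free_driver_perfectly_correlated(self):
        _, gt = make_ground_truth(seed=21, score_noise_sd=0.0)
        c = sample_cohort(gt, n_tc=2, n_sz=30, T=60, seed=22, render_volumes=False)
        mf = attach_scores(gt, c.true_fnc, c.manifest, seed=23)
        mtab = mf.table.set_index("subject_id")
        sz_ids = mtab.index[mtab["group"] == "SZ"]
        res = symptom_correlation(
            c.true_fnc.loc[sz_ids], mtab.loc[sz_ids],
            scales=("panss_positive",),
        )
        driver = gt.pair_label(gt.score_pairs_pos[0])
        r = res.loc[res["feature"] == driver, "r"].iloc[0]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)

    def test_null_coupling_near_zero(self):
        _, gt = make_ground_truth(seed=24, beta_pos=0.0, beta_neg=0.0)
        n = 80
        c = sample_cohort(gt, n_tc=2, n_sz=n, T=60, seed=25, render_volumes=False)
        mf = attach_scores(gt, c.true_fnc, c.manifest, seed=26)
        mtab = mf.table.set_index("subject_id")
        sz_ids = mtab.index[mtab["group"] == "SZ"]
        res = symptom_correlation(c.true_fnc.loc[sz_ids], mtab.loc[sz_ids])
        assert res.groupby("scale")["r"].apply(lambda r: np.abs(r).mean()).max() < 3 / np.sqrt(n)

    def test_missing_scores_dropped_pairwise(self):
        rng = np.random.default_rng(27)
        feats = pd.DataFrame(rng.standard_normal((20, 3)),
                             index=[f"s{i}" for i in range(20)])
        feats.columns = ["a", "b", "c"]
        scores = pd.DataFrame(
            {"panss_total": rng.normal(40, 5, 20)}, index=feats.index
        )
        scores.iloc[:5, 0] = np.nan
        res = symptom_correlation(feats, scores, scales=("panss_total",))
        assert (res["n"] == 15).all()

    def test_zero_variance_score_fatal(self):
        feats = pd.DataFrame(np.random.default_rng(28).standard_normal((10, 2)))
        scores = pd.DataFrame({"panss_total": np.full(10, 30.0)}, index=feats.index)
        with pytest.raises(ValueError, match="zero variance"):
            symptom_correlation(feats, scores, scales=("panss_total",))

    def test_total_correlation_bracketed_by_components(self):
        """With independent subscales, r(feature, total) lies between the
        component correlations (Monte-Carlo check)."""
        rng = np.random.default_rng(29)
        n = 2000
        f = rng.standard_normal(n)
        pos = 0.6 * f + rng.standard_normal(n)
        neg = rng.standard_normal(n)           # independent of f
        total = pos + neg
        r_pos = np.corrcoef(f, pos)[0, 1]
        r_neg = np.corrcoef(f, neg)[0, 1]
        r_tot = np.corrcoef(f, total)[0, 1]
        assert min(r_pos, r_neg) - 0.05 <= r_tot <= max(r_pos, r_neg) + 0.05


def test_group_diff_power_on_planted_pairs(template_gt):
    """Planted delta-z = 0.6 pairs reach q < 0.05; null pairs stay quiet."""
    from conftest import pair_column
    from msfnc import sample_cohort as sc

    _, gt = template_gt
    c = sc(gt, n_tc=30, n_sz=30, T=135, snr=10.0, seed=31, render_volumes=False)
    res = group_diff(c.true_fnc, c.manifest.groups)
    planted = [gt.pair_label(p) for p in gt.diff_pairs]
    assert (res.loc[planted, "q"] < 0.05).all()
    null_feats = res.drop(index=planted)
    assert (null_feats["q"] < 0.05).mean() <= 0.05
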