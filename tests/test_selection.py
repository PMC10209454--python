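"""ReliefF scoring and the multi-round selection protocol."""

from math import ceil

import numpy as np
import pandas as pd
import pytest

from msfnc import common_features, multiround_select, relieff


def relieff_oracle(x, y, k):
    """Literal-definition ReliefF: explicit loops, Manhattan distances."""
    x = np.asarray(x, float)
    y = np.asarray(y)
    n, f = x.shape
    lo, hi = x.min(0), x.max(0)
    rng = np.where(hi > lo, hi - lo, 1.0)
    xn = (x - lo) / rng
    classes, counts = np.unique(y, return_counts=True)
    prior = dict(zip(classes, counts / n))
    w = np.zeros(f)
    for i in range(n):
        d = np.array([np.abs(xn[i] - xn[j]).sum() if j != i else np.inf
                      for j in range(n)])
        same = [j for j in range(n) if y[j] == y[i] and j != i]
        hits = sorted(same, key=lambda j: d[j])[:k]
        for h in hits:
            w -= np.abs(xn[i] - xn[h])
        for c in classes:
            if c == y[i]:
                continue
            other = [j for j in range(n) if y[j] == c]
            misses = sorted(other, key=lambda j: d[j])[:k]
            for m in misses:
                w += prior[c] / (1 - prior[y[i]]) * np.abs(xn[i] - xn[m])
    return w / (n * k)


class TestRelieff:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_literal_definition_oracle(self, seed):
        """Exact agreement with the O(n^2) textbook construction."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 51))
        f = int(rng.integers(2, 11))
        x = rng.random((n, f))
        y = rng.choice(["TC", "SZ"], size=n)
        while min((y == "TC").sum(), (y == "SZ").sum()) < 6:
            y = rng.choice(["TC", "SZ"], size=n)
        np.testing.assert_allclose(
            relieff(x, y, k=5), relieff_oracle(x, y, k=5), atol=1e-12
        )

    def test_label_copy_feature_ranks_first(self):
        rng = np.random.default_rng(10)
        n = 60
        y = np.array(["TC"] * 30 + ["SZ"] * 30)
        x = rng.random((n, 6))
        x[:, 2] = (y == "SZ").astype(float)        # feature 2 encodes the class
        w = relieff(x, y, k=10)
        assert np.argmax(w) == 2
        assert w[2] > 0

    def test_pure_noise_weights_near_zero(self):
        """Irrelevant features average to ~0 weight across many draws."""
        means = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.random((60, 10))
            y = np.array(["TC"] * 30 + ["SZ"] * 30)
            means.append(relieff(x, y, k=10).mean())
        assert abs(np.mean(means)) < 0.02

    def test_duplicated_feature_equal_weight(self):
        rng = np.random.default_rng(11)
        x = rng.random((40, 4))
        x[:, 3] = x[:, 0]
        y = np.array(["TC"] * 20 + ["SZ"] * 20)
        w = relieff(x, y, k=5)
        assert w[0] == pytest.approx(w[3], abs=1e-12)

    def test_k_too_large_fatal(self):
        x = np.random.default_rng(12).random((10, 3))
        y = np.array(["TC"] * 5 + ["SZ"] * 5)
        with pytest.raises(ValueError, match="k="):
            relieff(x, y, k=5)


class TestMultiround:
    def _features(self, n=40, f=20, seed=0):
        rng = np.random.default_rng(seed)
        table = pd.DataFrame(
            rng.random((n, f)), columns=[f"f{i:03d}" for i in range(f)]
        )
        y = np.array(["TC"] * (n // 2) + ["SZ"] * (n // 2))
        return table, y

    def test_retained_count_is_ceil_70pct(self):
        """8001 features retain ceil(0.70 * 8001) = 5601."""
        rng = np.random.default_rng(1)
        table = pd.DataFrame(
            rng.random((30, 8001)),
            columns=[f"f{i:04d}" for i in range(8001)],
        )
        y = np.array(["TC"] * 15 + ["SZ"] * 15)
        wt = multiround_select(table, y, rounds=2, k=5, seed=2)
        assert len(wt.retained_features()) == 5601 == ceil(0.70 * 8001)

    def test_degenerate_protocol_equals_single_call(self):
        table, y = self._features(seed=3)
        wt = multiround_select(table, y, rounds=1, frac=1.0, k=5, seed=4)
        direct = relieff(table, y, k=5)
        np.testing.assert_allclose(wt.table["avg_weight"], direct, atol=1e-12)

    def test_deterministic_under_master_seed(self):
        table, y = self._features(seed=5)
        a = multiround_select(table, y, rounds=3, k=5, seed=6)
        b = multiround_select(table, y, rounds=3, k=5, seed=6)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_ranks_are_permutation(self):
        table, y = self._features(seed=7)
        wt = multiround_select(table, y, rounds=2, k=5, seed=8)
        assert sorted(wt.table["rank"]) == list(range(1, len(table.columns) + 1))

    def test_planted_features_retained(self, tc_cohort):
        """All planted discriminative pairs land inside the top-70% set."""
        gt = tc_cohort.ground_truth
        table = tc_cohort.timecourse_features(include_coarse=False)
        wt = multiround_select(table, tc_cohort.manifest.groups, rounds=10, k=10, seed=9)
        retained = set(wt.retained_features())
        from conftest import pair_column
        for pair in gt.diff_pairs:
            assert pair_column(table, gt.pair_label(pair)) in retained

    def test_relevance_contract_on_planted_cohort(self, tc_cohort):
        """Planted features score positive; null features hover near zero."""
        gt = tc_cohort.ground_truth
        table = tc_cohort.timecourse_features(include_coarse=False)
        w = relieff(table, tc_cohort.manifest.groups, k=10)
        from conftest import pair_column
        planted = [
            list(table.columns).index(pair_column(table, gt.pair_label(p)))
            for p in gt.diff_pairs
        ]
        null = [i for i in range(table.shape[1]) if i not in planted]
        assert w[planted].min() > 0
        assert w[planted].mean() > np.abs(w[null]).mean()


class TestCommonFeatures:
    def _table(self, weights, seed=0):
        n = len(weights)
        rng = np.random.default_rng(seed)
        table = pd.DataFrame(
            rng.random((30, n)), columns=[f"f{i:03d}" for i in range(n)]
        )
        y = np.array(["TC"] * 15 + ["SZ"] * 15)
        wt = multiround_select(table, y, rounds=1, frac=1.0, k=5, seed=seed)
        return wt

    def test_self_intersection_full(self):
        wt = self._table(range(20), seed=1)
        out = common_features(wt, wt, j=8)
        assert len(out) == 8
        assert (out["weight_a"] == out["weight_b"]).all()
        assert out["weight_a"].max() <= 1.0 and out["weight_a"].min() >= 0.0

    def test_disjoint_top_sets_warn_empty(self):
        a = self._table(range(20), seed=2)
        b = self._table(range(20), seed=3)
        # doctor the rankings so the two top-3 sets cannot overlap
        n = len(a.table)
        a.table["rank"] = np.arange(1, n + 1)
        b.table["rank"] = np.roll(np.arange(1, n + 1), 3)
        for t in (a, b):
            t.table["retained"] = t.table["rank"] <= int(np.ceil(0.7 * n))
        assert not set(a.top_features(3)) & set(b.top_features(3))
        with pytest.warns(UserWarning, match="no overlapping"):
            out = common_features(a, b, j=3)
        assert out.empty

    def test_label_mismatch_fatal(self):
        a = self._table(range(10), seed=4)
        b = self._table(range(12), seed=5)
        with pytest.raises(ValueError, match="label spaces"):
            common_features(a, b, j=3)

    def test_replicated_planted_pairs_overlap(self, template_gt):
        """Two cohorts sharing ground truth recover overlapping top sets."""
        from msfnc import sample_cohort
        from conftest import pair_column

        _, gt = template_gt
        tables = []
        for seed in (41, 42):
            c = sample_cohort(gt, n_tc=30, n_sz=30, T=135, seed=seed,
                              render_volumes=False)
            t = c.timecourse_features(include_coarse=False)
            tables.append(
                (t, multiround_select(t, c.manifest.groups, rounds=5, k=10, seed=seed))
            )
        out = common_features(tables[0][1], tables[1][1], j=8)
        planted = {pair_column(tables[0][0], gt.pair_label(p)) for p in gt.diff_pairs}
        assert len(planted & set(out["feature"])) >= 4
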