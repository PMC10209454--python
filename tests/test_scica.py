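"""Constrained ICA: whitening, one-unit extraction, time courses, recovery."""

import numpy as np
import pytest

from msfnc import (
    backproject_timecourse,
    extract_component,
    extract_subject,
    whiten_spatial,
    zscore_voxels,
)
from msfnc.io import BoldScan
from msfnc.scica import RankDeficiencyError, joint_timecourses


def _zs(v):
    return (v - v.mean()) / v.std()


class TestWhitening:
    def test_gram_is_identity(self, three_source_mixture):
        data, _, _ = three_source_mixture
        scan = BoldScan("s", data, tr=2.0)
        z, _ = whiten_spatial(scan, K=3)
        gram = z @ z.T / z.shape[1]
        np.testing.assert_allclose(gram, np.eye(3), atol=1e-8)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-8)

    def test_full_rank_reconstruction_lossless(self, three_source_mixture):
        data, _, _ = three_source_mixture
        scan = BoldScan("s", data, tr=2.0)
        z, d = whiten_spatial(scan, K=3)
        y = data.T - data.T.mean(axis=1, keepdims=True)
        assert np.linalg.norm(d @ z - y) / np.linalg.norm(y) < 1e-9

    def test_explained_variance_matches_eigendecomposition(self):
        """Energy captured by K components equals the top-K eigenvalue sum."""
        rng = np.random.default_rng(7)
        data = rng.standard_normal((300, 40))
        scan = BoldScan("s", data, tr=2.0)
        k = 5
        z, d = whiten_spatial(scan, k)
        captured = np.sum((d @ z) ** 2) / z.shape[1]
        y = data.T - data.T.mean(axis=1, keepdims=True)
        eigvals = np.sort(np.linalg.eigvalsh(y @ y.T / y.shape[1]))[::-1]
        assert captured == pytest.approx(eigvals[:k].sum(), rel=1e-10)

    def test_rank_deficiency_fatal(self, three_source_mixture):
        data, _, _ = three_source_mixture
        scan = BoldScan("s", data, tr=2.0)
        with pytest.raises(RankDeficiencyError, match="rank"):
            whiten_spatial(scan, K=10)


class TestExtractComponent:
    def test_recovers_planted_source(self, three_source_mixture):
        data, sources, _ = three_source_mixture
        scan = BoldScan("s", data, tr=2.0)
        z, _ = whiten_spatial(scan, K=3)
        for k in range(3):
            _, comp, diag = extract_component(z, sources[k], lam=0.5)
            assert abs(np.corrcoef(comp, sources[k])[0, 1]) > 0.99
            assert diag.converged

    def test_orthogonal_reference_warns_low_similarity(self, three_source_mixture):
        data, sources, _ = three_source_mixture
        scan = BoldScan("s", data, tr=2.0)
        z, _ = whiten_spatial(scan, K=3)
        rng = np.random.default_rng(8)
        ref = rng.standard_normal(data.shape[0])
        ref -= z.T @ (z @ ref) / z.shape[1]      # remove in-span part
        with pytest.warns(UserWarning, match="orthogonal"):
            _, _, diag = extract_component(z, ref, lam=0.5)
        assert abs(diag.reference_similarity) < 0.2

    def test_constraint_dominated_limit_returns_projection(self, three_source_mixture):
        data, sources, _ = three_source_mixture
        scan = BoldScan("s", data, tr=2.0)
        z, _ = whiten_spatial(scan, K=3)
        ref = sources[0]
        _, comp, _ = extract_component(z, ref, lam=0.999999)
        proj = z.T @ (z @ _zs(ref)) / z.shape[1]
        assert abs(np.corrcoef(comp, proj)[0, 1]) > 0.999

    def test_objective_trace_monotone(self, small_cohort, template_gt):
        """The safeguarded iteration never decreases the blended objective."""
        template, _ = template_gt
        scan = zscore_voxels(small_cohort.scans[0])
        z, _ = whiten_spatial(scan, K=10)
        for i in template.order_indices("fine")[:4]:
            _, _, diag = extract_component(z, template.maps[i])
            trace = np.asarray(diag.objective_trace)
            assert np.all(np.diff(trace) >= -1e-10)

    def test_deterministic(self, three_source_mixture):
        data, sources, _ = three_source_mixture
        scan = BoldScan("s", data, tr=2.0)
        z, _ = whiten_spatial(scan, K=3)
        w1, m1, _ = extract_component(z, sources[1])
        w2, m2, _ = extract_component(z, sources[1])
        np.testing.assert_allclose(m1, m2, atol=1e-12)
        np.testing.assert_allclose(w1, w2, atol=1e-12)


class TestTimecourses:
    def test_single_source_backprojection(self):
        rng = np.random.default_rng(9)
        s = rng.laplace(size=400)
        a = rng.standard_normal(50)
        scan = BoldScan("s", np.outer(s, a), tr=2.0)
        rec = backproject_timecourse(scan, s)
        assert abs(np.corrcoef(rec, a)[0, 1]) > 0.999

    def test_orthogonal_map_gives_zero_series(self):
        data = np.zeros((4, 6))
        data[0] = np.arange(6, dtype=float)
        scan = BoldScan("s", data, tr=2.0)
        rec = backproject_timecourse(scan, np.array([0.0, 1.0, 0.0, 0.0]))
        np.testing.assert_array_equal(rec, 0.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(10)
        data = rng.standard_normal((30, 20))
        scan = BoldScan("s", data, tr=2.0)
        m = rng.standard_normal(30)
        np.testing.assert_allclose(
            backproject_timecourse(scan, m),
            backproject_timecourse(scan, 10 * m),
            atol=1e-12,
        )

    def test_zero_map_fatal(self):
        scan = BoldScan("s", np.ones((3, 5)), tr=2.0)
        with pytest.raises(ValueError, match="zero-norm"):
            backproject_timecourse(scan, np.zeros(3))

    def test_joint_reduces_to_backprojection_for_one_map(self):
        rng = np.random.default_rng(11)
        data = rng.standard_normal((40, 25))
        scan = BoldScan("s", data, tr=2.0)
        m = rng.standard_normal(40)
        np.testing.assert_allclose(
            joint_timecourses(scan, m[None, :])[:, 0],
            backproject_timecourse(scan, m),
            atol=1e-10,
        )


class TestExtractSubject:
    def test_component_counts_per_order(self, small_cohort, template_gt):
        template, _ = template_gt
        scan = zscore_voxels(small_cohort.scans[0])
        res = extract_subject(scan, template)
        assert res.maps.shape[0] == 15
        assert res.timecourses.shape == (scan.n_volumes, 15)
        assert [o for o in res.orders].count("coarse") == 5
        assert [o for o in res.orders].count("fine") == 10

    def test_deterministic_given_input(self, small_cohort, template_gt):
        template, _ = template_gt
        scan = zscore_voxels(small_cohort.scans[0])
        a = extract_subject(scan, template)
        b = extract_subject(scan, template)
        np.testing.assert_allclose(a.maps, b.maps, atol=1e-12)
        np.testing.assert_allclose(a.timecourses, b.timecourses, atol=1e-12)

    def test_similarity_nonnegative_sign_convention(self, small_cohort, template_gt):
        template, _ = template_gt
        scan = zscore_voxels(small_cohort.scans[1])
        res = extract_subject(scan, template)
        assert all(d.reference_similarity >= 0 for d in res.diagnostics)

    def test_lambda_sweep_similarity_nondecreasing(self, small_cohort, template_gt):
        """Mean reference similarity rises (on average) with the constraint
        weight."""
        template, _ = template_gt
        scan = zscore_voxels(small_cohort.scans[2])
        sims = [
            extract_subject(scan, template, lam=lam).mean_similarity()
            for lam in (0.1, 0.5, 0.9)
        ]
        assert sims[0] <= sims[1] + 1e-6 <= sims[2] + 2e-6

    def test_high_snr_recovery(self, small_cohort, template_gt):
        """Planted maps and courses recovered with mean |rho| >= 0.95."""
        template, _ = template_gt
        map_cors, tc_cors = [], []
        for scan in small_cohort.scans[:2]:
            res = extract_subject(zscore_voxels(scan), template)
            truth_maps = small_cohort.subject_fine_maps[scan.subject_id]
            truth_tcs = small_cohort.fine_tcs[scan.subject_id]
            for k, i in enumerate(template.order_indices("fine")):
                map_cors.append(abs(np.corrcoef(res.maps[i], truth_maps[k])[0, 1]))
                tc_cors.append(
                    abs(np.corrcoef(res.timecourses[:, i], truth_tcs[:, k])[0, 1])
                )
        assert np.mean(map_cors) >= 0.95
        assert np.mean(tc_cors) >= 0.95
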