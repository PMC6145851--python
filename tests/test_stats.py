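import numpy as np
import pytest
from scipy import stats as sps

from dyntopo import (
    CohortProfiles,
    TaskDesign,
    bin_anova_2x2,
    bootstrap_corr_ci,
    dunn_clark_z,
    fdr_bh,
    permutation_corr_test,
    pupil_topology_correlation,
    task_glm,
)
from oracles import fdr_bh_oracle


class TestFdr:
    def test_worked_example(self):
        mask, thresh = fdr_bh(np.array([0.001, 0.02, 0.03, 0.5]), q=0.05)
        assert mask.sum() == 3
        assert thresh == pytest.approx(0.03)

    def test_all_ones_no_rejections_and_empty_input(self):
        mask, thresh = fdr_bh(np.ones(10))
        assert not mask.any() and thresh == 0.0
        mask, _ = fdr_bh(np.array([]))
        assert mask.size == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_threshold_scan(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            mask, _ = fdr_bh(p, q=0.05)
            np.testing.assert_array_equal(mask, fdr_bh_oracle(p, 0.05))

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=30)
        perm = rng.permutation(30)
        mask, _ = fdr_bh(p)
        mask_p, _ = fdr_bh(p[perm])
        np.testing.assert_array_equal(mask[perm], mask_p)


class TestBinAnova:
    def _profiles(self, occ):
        return CohortProfiles(
            occupancy=occ, subjects=tuple(f"s{i}" for i in range(occ.shape[0]))
        )

    def test_identical_cells_give_zero_f(self):
        base = np.random.default_rng(0).uniform(size=(8, 1, 1, 5, 5))
        occ = np.tile(base, (1, 2, 2, 1, 1))
        amap = bin_anova_2x2(self._profiles(occ))
        np.testing.assert_allclose(amap.statistic, 0.0)
        assert not amap.significant.any()

    def test_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(1)
        occ = rng.uniform(size=(10, 2, 2, 4, 4))
        amap = bin_anova_2x2(self._profiles(occ))
        d = (occ[:, 1, 1] - occ[:, 1, 0]) - (occ[:, 0, 1] - occ[:, 0, 0])
        t_ref, p_ref = sps.ttest_1samp(d.reshape(10, -1), 0.0, axis=0)
        np.testing.assert_allclose(
            amap.statistic.ravel(), t_ref**2, atol=1e-9
        )
        np.testing.assert_allclose(amap.pvalues.ravel(), p_ref, atol=1e-12)

    def test_incomplete_design_names_subjects(self):
        occ = np.random.default_rng(2).uniform(size=(4, 2, 2, 3, 3))
        occ[2, 1, 0] = np.nan
        with pytest.raises(ValueError, match="s2"):
            self._profiles(occ)


class TestPupilCorrelation:
    def test_identical_series_gives_rho_one(self):
        rng = np.random.default_rng(0)
        series = rng.standard_normal(50)
        bins = np.column_stack([series, rng.standard_normal(50)])
        subj = [(series.copy()) for _ in range(3)]
        rho, _ = pupil_topology_correlation(subj, [bins] * 3, kernel=None)
        np.testing.assert_allclose(rho[:, 0], 1.0)

    def test_excluded_subjects_skipped(self):
        rng = np.random.default_rng(1)
        pup = [rng.standard_normal(40), None, rng.standard_normal(40)]
        bins = [rng.standard_normal((40, 3)) for _ in range(3)]
        rho, smap = pupil_topology_correlation(pup, bins, kernel=None)
        assert rho.shape[0] == 2
        assert smap.extra["n_dropped"] == 1

    def test_coupled_signal_detected_at_group_level(self):
        rng = np.random.default_rng(2)
        pups, bins = [], []
        for s in range(8):
            latent = rng.standard_normal(120).cumsum()
            pups.append(latent + 0.3 * rng.standard_normal(120))
            coupled = latent[:, None] + rng.standard_normal((120, 4))
            uncoupled = rng.standard_normal((120, 4))
            bins.append(np.concatenate([coupled, uncoupled], axis=1))
        rho, smap = pupil_topology_correlation(pups, bins, kernel=None)
        assert smap.significant[:4].all()
        assert rho[:, :4].mean() > 0.5

    def test_independent_pupil_rarely_significant(self):
        hits = []
        for s in range(40):
            rng = np.random.default_rng(100 + s)
            pups = [rng.standard_normal(80) for _ in range(8)]
            bins = [rng.standard_normal((80, 10)) for _ in range(8)]
            _, smap = pupil_topology_correlation(pups, bins, kernel=None)
            hits.append(smap.significant.mean())
        assert np.mean(hits) <= 0.07


def _nback_design(tr=2.0, reps=2, block_s=30.0, gap_s=10.0):
    blocks = []
    onset = gap_s
    for _ in range(reps):
        for c in ("0-back", "1-back", "2-back", "3-back"):
            blocks.append((c, onset, block_s))
            onset += block_s + gap_s
    return TaskDesign(blocks=tuple(blocks), tr=tr), onset


class TestTaskGlm:
    def setup_method(self):
        self.design, total_s = _nback_design()
        self.n_frames = int(total_s / 2.0) + 10
        w = 15
        n_deriv = self.n_frames - 1
        self.w = w
        self.centers = np.arange(w // 2, n_deriv - w + w // 2 + 1)

    def _noise_free_response(self, cond):
        from dyntopo.stats import _design_on_windows

        x = _design_on_windows(
            self.design, self.n_frames, self.centers, self.w, True, [cond]
        )
        return x[:, 0]

    def test_noise_free_regressor_recovers_unit_beta(self):
        y = self._noise_free_response("2-back")[:, None]
        res = task_glm(
            y, self.design, self.n_frames, self.centers, self.w, convolve=True
        )
        betas = dict(zip(res.columns, res.betas[:, 0]))
        assert betas["2-back"] == pytest.approx(1.0, abs=1e-8)
        for c in ("0-back", "1-back", "3-back"):
            assert abs(betas[c]) < 1e-8

    def test_f_matches_full_vs_reduced_rss_oracle(self):
        rng = np.random.default_rng(3)
        y = rng.standard_normal((len(self.centers), 6))
        res = task_glm(y, self.design, self.n_frames, self.centers, self.w)
        from dyntopo.stats import _design_on_windows

        conds = ["0-back", "1-back", "2-back", "3-back"]
        x = np.column_stack([
            _design_on_windows(self.design, self.n_frames, self.centers, self.w, True, conds),
            np.ones(len(self.centers)),
        ])
        # oracle: restricted model imposing the load contrast c'beta = 0
        from scipy.linalg import null_space

        loads = np.arange(4.0) - 1.5
        c = np.concatenate([loads, [0.0]])
        basis = null_space(c[None, :])  # columns span {b : c'b = 0}
        for j in range(6):
            beta_full, *_ = np.linalg.lstsq(x, y[:, j], rcond=None)
            rss_full = np.sum((y[:, j] - x @ beta_full) ** 2)
            xr = x @ basis
            beta_red, *_ = np.linalg.lstsq(xr, y[:, j], rcond=None)
            rss_red = np.sum((y[:, j] - xr @ beta_red) ** 2)
            dof = x.shape[0] - x.shape[1]
            f_oracle = (rss_red - rss_full) / (rss_full / dof)
            assert res.f_load.statistic[j] == pytest.approx(f_oracle, abs=1e-8)

    def test_inverted_u_vs_linear_profiles(self):
        """Main contrast fires for an inverted-U response; load contrast for linear."""
        from dyntopo.stats import _design_on_windows

        conds = ["0-back", "1-back", "2-back", "3-back"]
        x = _design_on_windows(
            self.design, self.n_frames, self.centers, self.w, True, conds
        )
        rng = np.random.default_rng(4)
        inv_u = x @ np.array([0.0, 0.25, 0.4, 0.25])
        linear = x @ np.array([0.0, 0.15, 0.3, 0.45])
        hits_main = hits_load = 0
        n_rep = 20
        for k in range(n_rep):
            noise = 0.03 * rng.standard_normal((len(self.centers), 2))
            y = np.column_stack([inv_u, linear]) + noise
            res = task_glm(y, self.design, self.n_frames, self.centers, self.w)
            hits_main += res.f_main.pvalues[0] < 0.05
            hits_load += res.f_load.statistic[1] > res.f_load.statistic[0]
        assert hits_main >= 0.8 * n_rep
        assert hits_load >= 0.8 * n_rep

    def test_rank_deficient_design_names_columns(self):
        y = np.random.default_rng(5).standard_normal((len(self.centers), 2))
        dup = np.ones((len(self.centers), 1))  # duplicates the intercept
        with pytest.raises(ValueError, match="collinear"):
            task_glm(y, self.design, self.n_frames, self.centers, self.w, nuisance=dup)

    def test_missing_conditions_rejected(self):
        design = TaskDesign(blocks=(("1-back", 10.0, 30.0),), tr=2.0)
        y = np.zeros((len(self.centers), 2))
        with pytest.raises(ValueError, match="0-back"):
            task_glm(y, design, self.n_frames, self.centers, self.w)


class TestPermutationCorr:
    def test_identical_vectors_minimal_p(self):
        x = np.random.default_rng(0).standard_normal(20)
        r, p = permutation_corr_test(x, x, n_perm=500, seed=1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 501)

    def test_seeded_determinism_and_constant_error(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(15), rng.standard_normal(15)
        assert permutation_corr_test(x, y, 200, seed=3) == permutation_corr_test(
            x, y, 200, seed=3
        )
        with pytest.raises(ValueError, match="constant"):
            permutation_corr_test(x, np.ones(15))


class TestBootstrapCorr:
    def test_identical_vectors_degenerate_ci(self):
        x = np.random.default_rng(0).standard_normal(30)
        lo, hi = bootstrap_corr_ci(x, x, n_boot=200, seed=0)
        assert lo == pytest.approx(1.0) and hi == pytest.approx(1.0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        assert bootstrap_corr_ci(x, y, seed=9) == bootstrap_corr_ci(x, y, seed=9)


class TestDunnClark:
    def test_equal_correlations_give_zero(self):
        z, p = dunn_clark_z(0.4, 0.4, 100, 100)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_reduces_to_independent_z(self):
        z, _ = dunn_clark_z(0.6, 0.3, 120, 80)
        expected = (np.arctanh(0.6) - np.arctanh(0.3)) / np.sqrt(
            1 / 117 + 1 / 77
        )
        assert z == pytest.approx(expected)

    def test_dependency_widens_then_matches_permutation_reference(self):
        # positive estimator dependency shrinks the variance of the difference
        z_ind, _ = dunn_clark_z(0.5, 0.2, 60, 60)
        z_dep, _ = dunn_clark_z(0.5, 0.2, 60, 60, r_cross=0.5)
        assert abs(z_dep) > abs(z_ind)
        # independent-sample case: p matches a two-sample permutation reference
        rng = np.random.default_rng(0)
        n = 60
        cov1 = [[1, 0.55], [0.55, 1]]
        cov2 = [[1, 0.15], [0.15, 1]]
        a = rng.multivariate_normal([0, 0], cov1, n)
        b = rng.multivariate_normal([0, 0], cov2, n)
        r1 = np.corrcoef(a.T)[0, 1]
        r2 = np.corrcoef(b.T)[0, 1]
        _, p_test = dunn_clark_z(r1, r2, n, n)
        pooled = np.vstack([a, b])
        diffs = []
        for _ in range(2000):
            idx = rng.permutation(2 * n)
            g1, g2 = pooled[idx[:n]], pooled[idx[n:]]
            diffs.append(
                np.arctanh(np.corrcoef(g1.T)[0, 1])
                - np.arctanh(np.corrcoef(g2.T)[0, 1])
            )
        obs = np.arctanh(r1) - np.arctanh(r2)
        p_perm = np.mean(np.abs(diffs) >= abs(obs))
        assert p_test == pytest.approx(p_perm, abs=0.02)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="\\|r\\|"):
            dunn_clark_z(1.0, 0.5, 50, 50)
        with pytest.raises(ValueError, match="n >= 4"):
            dunn_clark_z(0.2, 0.1, 3, 50)
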