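import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import linrelax as lr
from linrelax.errors import CollinearityError, ValidationError


def random_instance(seed, n=10, grid=None):
    """Random small fitting instance as (maps, mask, y_map)."""
    rng = np.random.default_rng(seed)
    grid = grid or (n, 1, 1)
    mt = rng.uniform(0.5, 2.5, grid)
    r2s = rng.uniform(10, 50, grid)
    y = rng.normal(0.8, 0.2, grid)
    mask = np.ones(grid, bool)
    return mt, r2s, y, mask


class TestMask:
    def test_printed_rule_on_toy_probability_table(self):
        # (gm, wm, csf) -> included?
        table = [
            ((0.6, 0.2, 0.3), True),    # GM above threshold
            ((0.3, 0.3, 0.4), False),   # neither GM nor WM above 0.5
            ((0.2, 0.7, 0.1), True),    # WM above threshold
            ((0.6, 0.1, 0.6), False),   # CSF too likely
            ((0.5, 0.5, 0.0), False),   # thresholds are strict inequalities
        ]
        gm = np.array([[row[0][0] for row in table]])
        wm = np.array([[row[0][1] for row in table]])
        csf = np.array([[row[0][2] for row in table]])
        mask = lr.make_mask(gm, wm, csf)
        assert list(mask[0]) == [row[1] for row in table]

    def test_loose_threshold_mask_is_superset(self):
        rng = np.random.default_rng(0)
        probs = rng.dirichlet([1, 1, 1], size=1000).reshape(10, 10, 10, 3)
        gm, wm, csf = probs[..., 0], probs[..., 1], probs[..., 2]
        strict = lr.make_mask(gm, wm, csf, 0.5, 0.5)
        loose = lr.make_mask(gm, wm, csf, 0.3, 0.7)
        assert np.all(loose[strict])
        assert loose.sum() > strict.sum()

    def test_threshold_validation(self):
        p = np.ones((2, 2, 2)) * 0.5
        with pytest.raises(ValidationError):
            lr.make_mask(p, p, p, gmwm_threshold=1.5)
        with pytest.raises(ValidationError):
            lr.make_mask(p * 3, p, p)  # probabilities out of [0, 1]


class TestDesignMatrix:
    def test_construction_five_voxels(self):
        mt, r2s, _, _ = random_instance(1, n=5)
        mask = np.ones((5, 1, 1), bool)
        m = lr.build_design_matrix(mt, r2s, mask)
        assert m.X.shape == (5, 3)
        assert np.all(m.X[:, 0] == 1.0)
        assert np.array_equal(m.X[:, 1], mt.ravel())
        assert m.column_names == ("intercept", "mt_sat", "r2s")

    def test_invalid_voxel_dropped_with_count(self):
        mt, r2s, _, mask = random_instance(2, n=5)
        r2s[2, 0, 0] = np.nan
        m = lr.build_design_matrix(mt, r2s, mask)
        assert m.X.shape[0] == 4
        assert m.n_dropped == 1

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            lr.build_design_matrix(np.ones((3, 3, 3)), np.ones((4, 4, 4)),
                                   np.ones((3, 3, 3), bool))

    def test_voxel_ordering_does_not_change_beta(self):
        """OLS is permutation invariant: shuffling rows leaves beta fixed."""
        mt, r2s, y, mask = random_instance(3, n=50)
        m = lr.build_design_matrix(mt, r2s, mask)
        fit = lr.fit_linear_model(y, m)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.X.shape[0])
        m_perm = lr.ModelMatrix(X=m.X[perm], index=m.index[perm],
                                grid_shape=m.grid_shape,
                                column_names=m.column_names)
        fit_perm = lr.fit_linear_model(y, m_perm)
        assert np.allclose(fit.beta, fit_perm.beta, rtol=1e-12)


class TestFit:
    def test_exact_interpolation_of_generating_model(self):
        beta_true = np.array([0.3, 0.4, 0.002])
        mt, r2s, _, mask = random_instance(4, n=4)
        y = beta_true[0] + beta_true[1] * mt + beta_true[2] * r2s
        m = lr.build_design_matrix(mt, r2s, mask)
        fit = lr.fit_linear_model(y, m)
        assert np.allclose(fit.beta, beta_true, rtol=1e-10)
        assert np.nanmax(np.abs(fit.residual_map)) < 1e-12
        assert fit.pearson == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_normal_equations_oracle(self, seed):
        """QR solution equals the explicitly formed normal-equations
        solution on random 10-voxel instances."""
        mt, r2s, y, mask = random_instance(seed)
        m = lr.build_design_matrix(mt, r2s, mask)
        fit = lr.fit_linear_model(y, m)
        oracle = np.linalg.solve(m.X.T @ m.X, m.X.T @ y.ravel())
        assert np.allclose(fit.beta, oracle, rtol=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_residuals_orthogonal_to_design(self, seed):
        mt, r2s, y, mask = random_instance(seed, n=40)
        m = lr.build_design_matrix(mt, r2s, mask)
        fit = lr.fit_linear_model(y, m)
        resid = fit.residual_map.ravel()[m.index]
        scale = np.linalg.norm(m.X, axis=0) * np.linalg.norm(resid) + 1e-300
        assert np.all(np.abs(m.X.T @ resid) / scale < 1e-8)
        # with an intercept, residuals sum to ~0
        assert abs(resid.sum()) / (np.abs(resid).sum() + 1e-300) < 1e-8

    def test_collinear_design_raises_naming_columns(self):
        rng = np.random.default_rng(0)
        mt = rng.uniform(0.5, 2.5, (20, 1, 1))
        r2s = 3.0 * mt  # exactly collinear with MT
        mask = np.ones((20, 1, 1), bool)
        m = lr.build_design_matrix(mt, r2s, mask)
        with pytest.raises(CollinearityError, match="mt_sat"):
            lr.fit_linear_model(rng.normal(size=(20, 1, 1)), m)

    def test_invalid_r1_rows_dropped(self):
        mt, r2s, y, mask = random_instance(5, n=20)
        y[3, 0, 0] = np.nan
        m = lr.build_design_matrix(mt, r2s, mask)
        fit = lr.fit_linear_model(y, m)
        assert fit.n_voxels == 19

    def test_too_few_voxels_rejected(self):
        mt, r2s, y, mask = random_instance(6, n=2)
        m = lr.build_design_matrix(mt, r2s, mask)
        with pytest.raises(ValidationError):
            lr.fit_linear_model(y, m)


class TestSynthesize:
    def test_intercept_only_beta(self):
        mt, r2s, _, mask = random_instance(7, n=6)
        m = lr.build_design_matrix(mt, r2s, mask)
        synth = lr.synthesize_r1(m, [1.0, 0.0, 0.0])
        assert np.allclose(synth[mask], 1.0)

    def test_linear_combination_hand_arithmetic(self):
        """Single-subject-style coefficients at MT = 1 p.u., R2* = 20 s^-1."""
        beta = (0.2692, 0.3979, 0.0011)
        mt = np.full((1, 1, 1), 1.0)
        r2s = np.full((1, 1, 1), 20.0)
        m = lr.build_design_matrix(mt, r2s, np.ones((1, 1, 1), bool))
        synth = lr.synthesize_r1(m, beta)
        assert synth[0, 0, 0] == pytest.approx(0.6891, abs=1e-12)

    def test_synthesize_then_refit_is_fixed_point(self):
        beta = np.array([0.25, 0.41, 0.003])
        mt, r2s, _, mask = random_instance(8, n=30)
        m = lr.build_design_matrix(mt, r2s, mask)
        synth = lr.synthesize_r1(m, beta)
        refit = lr.fit_linear_model(synth, m)
        assert np.allclose(refit.beta, beta, rtol=1e-10)

    def test_unmasked_voxels_invalid(self):
        mt, r2s, _, _ = random_instance(9, n=4, grid=(2, 2, 1))
        mask = np.zeros((2, 2, 1), bool)
        mask[0, 0, 0] = mask[1, 1, 0] = True
        mask[0, 1, 0] = True
        m = lr.build_design_matrix(mt, r2s, mask)
        synth = lr.synthesize_r1(m, [1.0, 0.0, 0.0])
        assert np.isnan(synth[1, 0, 0])


class TestEvaluate:
    def test_identity_gives_perfect_agreement(self):
        rng = np.random.default_rng(0)
        r1 = rng.uniform(0.5, 1.2, (5, 5, 5))
        mask = np.ones((5, 5, 5), bool)
        rep = lr.evaluate_fit(r1, r1, mask)
        assert rep.pearson == pytest.approx(1.0)
        assert rep.bias_mean_pct == pytest.approx(0.0, abs=1e-12)
        assert rep.bias_sd_pct == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_toy(self):
        rng = np.random.default_rng(1)
        r1 = rng.uniform(0.5, 1.2, (4, 4, 4))
        rep = lr.evaluate_fit(r1, -r1, np.ones_like(r1, bool))
        assert rep.pearson == pytest.approx(-1.0)

    def test_zero_variance_flagged_degenerate(self):
        r1 = np.full((3, 3, 3), 0.9)
        rep = lr.evaluate_fit(r1, r1 * 0 + 0.8, np.ones_like(r1, bool))
        assert rep.degenerate and np.isnan(rep.pearson)

    def test_per_class_bias_zero_when_generative_model_fitted(self):
        """Noiseless data generated by the fitted model leaves every class's
        residual mean at numerical zero."""
        beta = np.array(lr.REFERENCE_BETA)
        mt, r2s, _, mask = random_instance(10, n=200)
        labels = (np.arange(200) % 3).reshape(200, 1, 1)
        y = beta[0] + beta[1] * mt + beta[2] * r2s
        m = lr.build_design_matrix(mt, r2s, mask)
        fit = lr.fit_linear_model(y, m)
        synth = lr.synthesize_r1(m, fit.beta)
        rep = lr.evaluate_fit(y, synth, mask, labels, ("a", "b", "c"))
        for name, (mean, sd, n) in rep.per_class.items():
            assert abs(mean) < 1e-9
            assert n > 0

    def test_sign_convention_positive_when_model_lower(self):
        meas = np.full((2, 2, 2), 1.0)
        synth = np.full((2, 2, 2), 0.9)
        rep = lr.evaluate_fit(meas, synth, np.ones((2, 2, 2), bool))
        assert rep.bias_mean_pct == pytest.approx(10.0)


class TestDerivedQuantities:
    def test_free_water_t1(self):
        assert round(lr.free_water_t1(0.2677), 3) == 3.736
        assert lr.free_water_t1(1.0) == 1.0
        assert lr.free_water_t1(0.5) == 2.0
        with pytest.raises(ValidationError):
            lr.free_water_t1(0.0)

    def test_macromolecular_relaxivity(self):
        assert lr.macromolecular_relaxivity(0.4, 2.0, 0.2) == pytest.approx(4.0)
        half = lr.macromolecular_relaxivity(0.4, 2.0, 0.4)
        assert half == pytest.approx(2.0)
        with pytest.raises(ValidationError):
            lr.macromolecular_relaxivity(0.4, 2.0, 0.0)

    def test_relaxivity_order_of_magnitude_for_white_matter(self):
        """With the reference MT coefficient and plausible literature WM
        values (MT ~ 2 p.u., bound fraction ~ 0.2-0.3), the implied
        relaxivity lands in the low-single-digit s^-1 range."""
        val = lr.macromolecular_relaxivity(0.3971, 2.0, 0.25)
        assert 1.0 < val < 10.0


class TestNoiseBehavior:
    def test_mean_beta_recovery_under_noise(self):
        """OLS recovers the generating coefficients on average (5 seeded
        replicates, 2e4 voxels, noise sd 0.05 s^-1)."""
        mean_beta = lr.mean_recovered_beta(lr.REFERENCE_BETA, n_replicates=5,
                                           n_voxels=20_000, noise_sd=0.05,
                                           seed=123)
        ref = np.array(lr.REFERENCE_BETA)
        assert abs(mean_beta[0] / ref[0] - 1) < 0.01
        assert abs(mean_beta[1] / ref[1] - 1) < 0.01
        assert abs(mean_beta[2] / ref[2] - 1) < 0.10

    def test_pearson_degrades_monotonically_with_noise(self):
        """Mean Pearson over seeded replicates decreases as the R1 noise
        grows (4-point noise grid)."""
        noise_grid = [0.01, 0.05, 0.15, 0.4]
        means = []
        for noise in noise_grid:
            vals = []
            for seed in range(3):
                rng = np.random.default_rng(1000 + seed)
                grid = (5000, 1, 1)
                mt = rng.uniform(0.5, 2.5, grid)
                r2s = rng.uniform(10, 50, grid)
                b = lr.REFERENCE_BETA
                y = b[0] + b[1] * mt + b[2] * r2s + rng.normal(0, noise, grid)
                m = lr.build_design_matrix(mt, r2s, np.ones(grid, bool))
                vals.append(lr.fit_linear_model(y, m).pearson)
            means.append(np.mean(vals))
        assert np.all(np.diff(means) < 0)
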