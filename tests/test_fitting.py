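"""Rate-law parameter estimation: recovery, identifiability, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from hcdkin import (
    KineticParameters,
    PingPongRateLaw,
    VelocityDesign,
    bootstrap_ci,
    fit_rate_law,
    generate_velocity_dataset,
    profile_likelihood,
    velocity_uM,
)

TRUTH = (1490.0, 27.0, 20.0, 22.0)  # k_bim, k_nadph, km_nadph_uM, k_i_mM


def _xy(df):
    return df[["nadph_uM", "s7hk_uM"]].to_numpy(), df["v_uM_per_s"].to_numpy()


@pytest.fixture(scope="module")
def noiseless_extended(reported_params):
    df = generate_velocity_dataset(
        VelocityDesign(extended=True, cv=0.0, floor_uM_s=0.0),
        reported_params,
        seed=0,
    )
    return df


@pytest.fixture(scope="module")
def fitted_seed42(noisy_dataset_seed42):
    est = PingPongRateLaw(e_total_nM=99.0, random_state=42)
    X, y = _xy(noisy_dataset_seed42)
    return est.fit(X, y), X, y


class TestNoiselessRecovery:
    def test_exact_recovery(self, noiseless_extended):
        result = fit_rate_law(noiseless_extended, e_total_nM=99.0)
        p = result.params
        for est, true in zip(
            (p.k_bim_per_mM_s, p.k_nadph_per_s, p.km_nadph_uM, p.k_i_mM), TRUTH
        ):
            assert est == pytest.approx(true, rel=1e-3)

    def test_recovery_at_an_arbitrary_parameter_point(self):
        truth = KineticParameters.from_assay_units(50.0, 300.0, 8.0, 45.0, 5.0)
        df = generate_velocity_dataset(
            VelocityDesign(extended=True, cv=0.0, floor_uM_s=0.0, e_total_nM=50.0),
            truth, seed=1,
        )
        p = fit_rate_law(df, e_total_nM=50.0).params
        assert p.k_bim_per_mM_s == pytest.approx(300.0, rel=1e-3)
        assert p.k_nadph_per_s == pytest.approx(8.0, rel=1e-3)
        assert p.km_nadph_uM == pytest.approx(45.0, rel=1e-3)
        assert p.k_i_mM == pytest.approx(5.0, rel=1e-3)


class TestNoisyRecovery:
    def test_seed42_recovery_within_tolerance(self, fitted_seed42):
        """Default noisy extended design: k_bim, k_cat, Km within 10%,
        K_i within 25% of the generating values."""
        est, _, _ = fitted_seed42
        p = est.params_
        assert p.k_bim_per_mM_s == pytest.approx(TRUTH[0], rel=0.10)
        assert p.k_nadph_per_s == pytest.approx(TRUTH[1], rel=0.10)
        assert p.km_nadph_uM == pytest.approx(TRUTH[2], rel=0.10)
        assert p.k_i_mM == pytest.approx(TRUTH[3], rel=0.25)
        assert est.ki_identifiable_

    def test_bias_and_rmse_over_seeds(self, reported_params):
        """Across 50 seeds, |bias| < 5% and RMSE < 15% for the three
        well-identified parameters."""
        design = VelocityDesign(extended=True)
        rel = {0: [], 1: [], 2: []}
        for seed in range(50):
            df = generate_velocity_dataset(design, reported_params, seed=seed)
            est = PingPongRateLaw(e_total_nM=99.0, n_starts=2, random_state=seed)
            est.fit(*_xy(df))
            p = est.params_
            for i, val in enumerate((p.k_bim_per_mM_s, p.k_nadph_per_s, p.km_nadph_uM)):
                rel[i].append(val / TRUTH[i] - 1.0)
        for i in rel:
            errs = np.asarray(rel[i])
            assert abs(errs.mean()) < 0.05
            assert np.sqrt((errs**2).mean()) < 0.15

    def test_self_consistency(self, fitted_seed42):
        """Refitting noiseless data generated at the fitted parameters
        reproduces them."""
        est, _, _ = fitted_seed42
        p = est.params_
        df = generate_velocity_dataset(
            VelocityDesign(extended=True, cv=0.0, floor_uM_s=0.0), p, seed=3
        )
        p2 = fit_rate_law(df, e_total_nM=99.0).params
        assert p2.k_bim_per_mM_s == pytest.approx(p.k_bim_per_mM_s, rel=1e-3)
        assert p2.k_i_mM == pytest.approx(p.k_i_mM, rel=1e-3)

    def test_objective_invariant_to_row_order(self, noisy_dataset_seed42):
        X, y = _xy(noisy_dataset_seed42)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(y))
        a = PingPongRateLaw(random_state=0).fit(X, y)
        b = PingPongRateLaw(random_state=0).fit(X[perm], y[perm])
        assert a.objective_ == pytest.approx(b.objective_, rel=1e-8)


class TestEstimatorContract:
    def test_rank_deficient_design_rejected(self):
        X = np.array([[160.0, 60.0], [80.0, 60.0], [40.0, 60.0]])
        y = np.array([1.0, 0.8, 0.5])
        with pytest.raises(ValueError, match="rank-deficient"):
            PingPongRateLaw().fit(X, y)

    def test_get_set_params_and_clone(self):
        est = PingPongRateLaw(e_total_nM=50.0, n_starts=3)
        cloned = clone(est)
        assert cloned.get_params()["e_total_nM"] == 50.0
        cloned.set_params(weighting="absolute")
        assert cloned.weighting == "absolute"

    def test_predict_matches_rate_law(self, fitted_seed42):
        est, X, _ = fitted_seed42
        pred = est.predict(X[:10])
        direct = velocity_uM(est.params_, X[:10, 0], X[:10, 1])
        assert np.allclose(pred, direct)

    def test_bad_inputs_rejected(self):
        est = PingPongRateLaw()
        with pytest.raises(ValueError):
            est.fit(np.ones((4, 3)), np.ones(4))
        with pytest.raises(ValueError):
            est.fit(np.full((4, 2), -1.0), np.ones(4))


class TestProfileLikelihood:
    def test_ki_flat_on_narrow_design(self, reported_params):
        """The 5–150 µM design cannot constrain K_i = 22 mM: the profile
        stays flat within one objective unit over 1–1000 mM."""
        df = generate_velocity_dataset(
            VelocityDesign(extended=False), reported_params, seed=7
        )
        X, y = _xy(df)
        est = PingPongRateLaw(random_state=7).fit(X, y)
        prof = profile_likelihood(X, y, est, "k_i_mM", np.geomspace(1.0, 1000.0, 7))
        assert prof["objective"].max() - prof["objective"].min() < 1.0
        assert not est.ki_identifiable_

    def test_ki_minimum_on_extended_design(self, fitted_seed42):
        est, X, y = fitted_seed42
        grid = np.geomspace(2.0, 200.0, 9)
        prof = profile_likelihood(X, y, est, "k_i_mM", grid)
        best = grid[prof["objective"].idxmin()]
        assert 10.0 < best < 50.0
        assert prof["objective"].max() - prof["objective"].min() > 10.0

    def test_profile_at_fitted_value_reproduces_objective(self, fitted_seed42):
        est, X, y = fitted_seed42
        prof = profile_likelihood(X, y, est, "k_nadph_per_s",
                                  [est.params_.k_nadph_per_s])
        assert prof["objective"].iloc[0] == pytest.approx(est.objective_, rel=1e-6)

    def test_nonpositive_grid_rejected(self, fitted_seed42):
        est, X, y = fitted_seed42
        with pytest.raises(ValueError):
            profile_likelihood(X, y, est, "k_i_mM", [0.0, 1.0])


class TestBootstrap:
    def test_deterministic_given_seed(self, fitted_seed42):
        est, X, y = fitted_seed42
        ci1 = bootstrap_ci(X, y, est, n_boot=100, seed=5)
        ci2 = bootstrap_ci(X, y, est, n_boot=100, seed=5)
        pd.testing.assert_frame_equal(ci1, ci2)

    def test_intervals_cover_generating_parameters(self, fitted_seed42):
        est, X, y = fitted_seed42
        ci = bootstrap_ci(X, y, est, n_boot=150, seed=5).set_index("parameter")
        for name, true in zip(
            ("k_bim_per_mM_s", "k_nadph_per_s", "km_nadph_uM", "k_i_mM"), TRUTH
        ):
            assert ci.loc[name, "lower"] <= true <= ci.loc[name, "upper"]

    def test_zero_noise_intervals_collapse(self, noiseless_extended):
        X, y = _xy(noiseless_extended)
        est = PingPongRateLaw().fit(X, y)
        ci = bootstrap_ci(X, y, est, n_boot=100, seed=1).set_index("parameter")
        width = ci["upper"] - ci["lower"]
        assert (width / ci["upper"] < 1e-6).all()

    def test_small_n_boot_rejected(self, fitted_seed42):
        est, X, y = fitted_seed42
        with pytest.raises(ValueError):
            bootstrap_ci(X, y, est, n_boot=10)
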