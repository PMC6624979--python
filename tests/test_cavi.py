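"""Variational inference: initialization, conjugate updates, fit behaviour."""

import copy

import numpy as np
import pytest

from giscreen import Priors, SimConfig, fit, initialize, simulate_screen
from giscreen.cavi import update_gaussian_factor, update_tau_factor
from giscreen.tau_prior import TauPrior, estimate_tau_empirical

from .conftest import make_design, make_lfc


def _flat_tau(lfc, alpha=1.0, beta=1.0):
    shape = lfc.D.shape
    return TauPrior(np.full(shape, alpha), np.full(shape, beta), "empirical")


def _state(design, lfc, priors=None, tau=None):
    priors = priors or Priors()
    tau = tau or _flat_tau(lfc)
    return initialize(lfc, design, priors, tau), priors, tau


class TestInitialize:
    def test_gene_effect_is_median_of_control_paired_constructs(self):
        design = make_design(
            [("c1", "A_1", "N_1", "A", "NC"),
             ("c2", "A_2", "N_1", "A", "NC"),
             ("c3", "A_3", "N_2", "A", "NC"),
             ("c4", "N_1", "N_2", "NC", "NC")],
            controls={"NC"},
        )
        D = np.array([-1.0, -0.4, -0.6, 0.0])
        lfc = make_lfc(design, D[:, None, None].repeat(2, axis=2))
        state, _, _ = _state(design, lfc)
        assert state.y_mean[state.idx.genes.index("A"), 0] == pytest.approx(-0.6)

    def test_no_control_fallback_uses_all_constructs(self):
        design = make_design(
            [("c1", "A_1", "B_1", "A", "B"), ("c2", "A_2", "C_1", "A", "C")]
        )
        D = np.array([-2.0, -1.0])
        lfc = make_lfc(design, D[:, None, None].repeat(2, axis=2))
        state, _, _ = _state(design, lfc)
        assert state.y_mean[state.idx.genes.index("A"), 0] == pytest.approx(-1.5)

    def test_guide_effects_start_at_prior_mean(self, small_sim):
        tau = estimate_tau_empirical(small_sim.lfc)
        state = initialize(small_sim.lfc, small_sim.design, Priors(), tau)
        assert np.all(state.x_mean == 1.0)
        assert np.all(state.x_var == 1.0)
        assert np.all(state.s_mean == 0.0)
        assert np.all(state.s_var == 10.0)


class TestGaussianUpdates:
    """Single-observation problems with all other factors frozen at point values."""

    def _single_obs(self, D_value, y_other=0.0):
        design = make_design([("c1", "A_1", "N_1", "A", "NC")], n_reps=1)
        lfc = make_lfc(design, np.array([[[D_value]]]))
        return design, lfc

    def test_matches_closed_form_posterior(self):
        # D=-2, coefficient c: E=1, Var=0, remainder 0, E[tau]=1, prior N(0,10)
        # -> posterior var 1/(0.1+1) = 0.9091, mean = var * (1 * -2) = -1.818
        design, lfc = self._single_obs(-2.0)
        state, priors, _ = _state(design, lfc)
        state.x_mean[:] = [1.0, 0.0]  # A_1 coefficient 1; N_1 zeroed -> remainder 0
        state.x_var[:] = 0.0
        state.xp_mean[:] = 0.0
        state.xp_var[:] = 0.0
        mean, var = update_gaussian_factor(("y", "A"), state, lfc, priors)
        assert var[0] == pytest.approx(1.0 / 1.1, abs=1e-12)
        assert mean[0] == pytest.approx(-2.0 / 1.1, abs=1e-12)

    @pytest.mark.parametrize("moment_mode", ["plugin", "full"])
    def test_modes_agree_when_other_factors_frozen(self, moment_mode):
        design, lfc = self._single_obs(-2.0)
        state, priors, _ = _state(design, lfc)
        state.x_mean[:] = [1.0, 0.0]
        state.x_var[:] = 0.0
        state.xp_mean[:] = 0.0
        state.xp_var[:] = 0.0
        mean, var = update_gaussian_factor(("y", "A"), state, lfc, priors, moment_mode)
        assert mean[0] == pytest.approx(-2.0 / 1.1, abs=1e-10)

    def test_zero_coefficient_returns_prior(self):
        # if the pair-combination coefficient s is identically 0, the pair
        # activity factor receives no evidence and keeps its prior
        design, lfc = self._single_obs(-2.0)
        state, priors, _ = _state(design, lfc)
        state.s_mean[:] = 0.0
        state.s_var[:] = 0.0
        mean, var = update_gaussian_factor(("x_pair", "c1"), state, lfc, priors)
        assert mean == pytest.approx(priors.mu_x)
        assert var == pytest.approx(priors.sigma_x2)

    def test_infinite_precision_limit_recovers_exact_solution(self):
        # E[tau] -> large, Var[c]=0  => posterior mean -> (D - E[m]) / E[c]
        design, lfc = self._single_obs(-2.0)
        tau = _flat_tau(lfc, alpha=1e12, beta=1.0)
        state, priors, _ = _state(design, lfc, tau=tau)
        state.x_mean[:] = [0.5, 0.0]
        state.x_var[:] = 0.0
        state.xp_mean[:] = 0.0
        state.xp_var[:] = 0.0
        mean, _ = update_gaussian_factor(("y", "A"), state, lfc, priors)
        assert mean[0] == pytest.approx(-2.0 / 0.5, rel=1e-6)


class TestTauUpdate:
    def _frozen_state(self, D_value):
        design = make_design([("c1", "A_1", "N_1", "A", "NC")], n_reps=1)
        lfc = make_lfc(design, np.array([[[D_value]]]))
        state, priors, tau = _state(design, lfc, tau=_flat_tau(lfc, 1.0, 0.5))
        # zero all means/vars -> E[mu]=0, Var[mu]=0
        for name in ("x_mean", "x_var", "xp_mean", "xp_var", "y_mean", "y_var",
                     "s_mean", "s_var"):
            getattr(state, name)[:] = 0.0
        return design, lfc, state, tau

    def test_zero_residual_keeps_rate(self):
        design, lfc, state, tau = self._frozen_state(0.0)
        shape, rate = update_tau_factor("c1", "s1", state, lfc, tau)
        assert shape == pytest.approx(1.5)
        assert rate == pytest.approx(0.5)

    def test_unit_residual_plugin_arithmetic(self):
        # alpha=1, beta=0.5, residual 1, Var[mu]=0 -> (1.5, 1.0), E[tau]=1.5
        design, lfc, state, tau = self._frozen_state(1.0)
        shape, rate = update_tau_factor("c1", "s1", state, lfc, tau)
        assert (shape, rate) == (pytest.approx(1.5), pytest.approx(1.0))
        assert shape / rate == pytest.approx(1.5)

    def test_product_variance_identity(self):
        # one product with means (1, -1), variances (0.1, 0.2):
        # Var = E[a^2]E[b^2] - E[a]^2 E[b]^2 = 1.1 * 1.2 - 1 = 0.32
        design, lfc, state, tau = self._frozen_state(-1.0)
        gi = state.idx.guides.index("A_1")
        state.x_mean[gi], state.x_var[gi] = 1.0, 0.1
        ga = state.idx.genes.index("A")
        state.y_mean[ga, 0], state.y_var[ga, 0] = -1.0, 0.2
        shape, rate = update_tau_factor("c1", "s1", state, lfc, tau)
        # E[mu] = -1, residual 0, so rate = beta + 0.5 * Var[mu] = 0.5 + 0.16
        assert rate == pytest.approx(0.5 + 0.5 * 0.32, abs=1e-12)


class TestFit:
    def test_noiseless_recovery_with_pinned_guide_activity(self):
        cfg = SimConfig(
            n_genes=10, guides_per_gene=2, n_controls=2, n_samples=3,
            x_sd=0.0, noise_sd=1e-6, n_lethal=0, essential_fraction=0.3, seed=3,
        )
        sim = simulate_screen(cfg)
        tau = _flat_tau(sim.lfc, 1.0, 0.25)
        post, diag = fit(sim.lfc, sim.design, Priors(sigma_x2=1e-6), tau, max_iter=100)
        y_true = sim.truth_y.loc[post.idx.genes].to_numpy()
        assert np.abs(post.y_mean - y_true).max() < 1e-2

    def test_repeated_fits_bit_identical(self, small_sim):
        post1, _ = fit(small_sim.lfc, small_sim.design)
        post2, _ = fit(small_sim.lfc, small_sim.design)
        np.testing.assert_array_equal(post1.y_mean, post2.y_mean)
        np.testing.assert_array_equal(post1.s_mean, post2.s_mean)
        np.testing.assert_array_equal(post1.tau_rate, post2.tau_rate)

    def test_infinite_tolerance_single_sweep(self, small_sim):
        post, diag = fit(small_sim.lfc, small_sim.design, tol=np.inf)
        assert diag.n_iter == 1
        assert diag.converged  # any finite MAE is below an infinite tolerance

    def test_construct_order_permutation_invariance(self, small_sim):
        post1, _ = fit(small_sim.lfc, small_sim.design)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(small_sim.design.construct_ids))
        design2 = copy.deepcopy(small_sim.design)
        object.__setattr__(design2, "constructs", small_sim.design.constructs.iloc[perm])
        lfc2 = make_lfc(design2, small_sim.lfc.D_rep[perm])
        post2, _ = fit(lfc2, design2)
        np.testing.assert_allclose(post1.y_mean, post2.y_mean, atol=1e-8)
        np.testing.assert_allclose(post1.s_mean, post2.s_mean, atol=1e-8)
        np.testing.assert_allclose(
            post1.xp_table().loc[small_sim.design.construct_ids, "mean"].to_numpy(),
            post2.xp_table().loc[small_sim.design.construct_ids, "mean"].to_numpy(),
            atol=1e-8,
        )

    def test_nan_input_aborts_with_diagnostics(self, small_sim):
        lfc = copy.deepcopy(small_sim.lfc)
        lfc.D.iloc[0, 0] = np.nan
        with pytest.raises(FloatingPointError, match="sweep"):
            fit(lfc, small_sim.design)

    def test_mae_trace_nonnegative_and_finite(self, small_sim):
        _, diag = fit(small_sim.lfc, small_sim.design)
        trace = np.asarray(diag.mae_trace)
        assert np.all(trace >= 0) and np.all(np.isfinite(trace))

    def test_few_samples_warns_about_guide_prior(self):
        sim = simulate_screen(
            SimConfig(n_genes=6, guides_per_gene=2, n_controls=2, n_samples=2,
                      n_lethal=0, seed=4)
        )
        with pytest.warns(UserWarning, match="sigma_x"):
            fit(sim.lfc, sim.design, max_iter=2)
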