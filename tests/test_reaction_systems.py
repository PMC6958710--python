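"""Model construction: parameters, reactions, propensities, mean-field drift."""

import numpy as np
import pytest

from redqueen import ModelParams, PopulationState, build_model, ode_rhs
from redqueen._kernels import fill_rates
from redqueen.reaction_systems import MODEL_NAMES


class TestModelParams:
    def test_interaction_rate_derived_from_base_rate_and_capacity(self):
        p = ModelParams(b_H=6.0, K=100.0, lam0=4.0)
        assert p.lam == pytest.approx(0.04)
        assert p.comp_rate == pytest.approx(0.06)

    def test_capacity_derived_from_competition(self):
        p = ModelParams(b_H=6.0, comp_rate=0.01)
        assert p.K == pytest.approx(600.0)

    def test_explicit_interaction_rate_wins(self):
        p = ModelParams(lam=0.5)
        assert p.lam == 0.5

    def test_inconsistent_interaction_rates_rejected(self):
        with pytest.raises(ValueError, match="inconsistent interaction"):
            ModelParams(lam=0.5, lam0=4.0, K=100.0)

    def test_inconsistent_regulation_rejected(self):
        with pytest.raises(ValueError, match="inconsistent regulation"):
            ModelParams(b_H=6.0, K=100.0, comp_rate=0.5)

    def test_zero_competition_with_capacity_allowed(self):
        # K may scale lam0 while the competition channel is off
        p = ModelParams(b_H=0.4, K=500.0, lam0=4.0, comp_rate=0.0)
        assert p.comp_rate == 0.0 and p.lam == pytest.approx(0.008)

    @pytest.mark.parametrize("bad", [{"w_H": 1.2}, {"w_P": -0.1}, {"alpha": 0, "beta": 1}])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)


class TestBuildModel:
    def test_ecoevoplus_reaction_count(self, fig1):
        system = build_model("EcoEvoPlus", 2, fig1["params"])
        assert system.n_reactions == 10  # birth, par death, 2 interactions, competition x2

    def test_mutation_adds_four_channels_per_genotype(self, fig4):
        system = build_model("EcoEvoPlus", 5, fig4["params"], with_mutation=True)
        assert system.n_reactions == 25 + 20

    def test_unknown_model_rejected(self, fig1):
        with pytest.raises(ValueError, match="unknown model"):
            build_model("SuperEvo", 2, fig1["params"])

    def test_game_models_are_two_type_only(self, fig1):
        with pytest.raises(ValueError, match="exactly 2"):
            build_model("EvoPlus", 3, fig1["params"])

    def test_mutation_unsupported_for_constant_size_models(self, fig1):
        with pytest.raises(ValueError, match="mutation"):
            build_model("Evo", 2, fig1["params"], with_mutation=True)

    def test_constant_size_stoichiometry_sums_to_zero(self, fig1):
        for name in ("Evo", "EvoPlus"):
            system = build_model(name, 2, fig1["params"])
            assert np.all(system.delta_H.sum(axis=1) == 0)
            assert np.all(system.delta_P.sum(axis=1) == 0)

    def test_mutation_reactions_conserve_totals(self, fig4):
        system = build_model("EcoEvo", 5, fig4["params"], with_mutation=True)
        mut = [r for r in system.reactions if r.label.startswith("mut")]
        assert len(mut) == 20
        for r in mut:
            assert r.delta_H.sum() == 0 and r.delta_P.sum() == 0


class TestPropensities:
    def test_matched_interaction_rates(self, fig1):
        # lam = 4/100; H_i * P_i = 25*75 -> 75 per genotype
        system = build_model("EcoEvo", 2, fig1["params"])
        a = system.propensities(PopulationState(H=[25, 25], P=[75, 75]))
        assert a[4:8] == pytest.approx([75.0, 75.0, 75.0, 75.0])

    def test_moran_host_channels_match_discrete_step(self, default_params):
        system = build_model("EvoPlus", 2, default_params)
        a = system.propensities(PopulationState(H=[5, 5], P=[8, 2]))
        assert a[:2] == pytest.approx([0.2, 0.3])

    def test_hybrid_rates_balance_at_symmetric_state(self):
        params = ModelParams(w_H=1.0, w_P=1.0)
        system = build_model("Hybrid", 2, params)
        a = system.propensities(PopulationState(H=[1, 1], P=[1, 1]))
        # order: host deaths, host births, parasite births, parasite deaths
        assert a[0:2] == pytest.approx([0.5, 0.5])
        assert a[2:4] == pytest.approx([0.5, 0.5])

    def test_empty_parasites_leave_only_host_channels(self, fig1):
        system = build_model("EcoEvo", 2, fig1["params"])
        a = system.propensities(PopulationState(H=[10, 10], P=[0, 0]))
        assert np.all(a[2:] == 0.0)
        assert np.all(a[:2] > 0.0)

    def test_all_zero_state_has_zero_rates(self, fig1):
        for name in MODEL_NAMES:
            system = build_model(name, 2, fig1["params"])
            a = system.propensities(PopulationState(H=[0, 0], P=[0, 0]))
            assert np.all(a == 0.0)

    def test_negative_counts_rejected(self, fig1):
        system = build_model("EcoEvo", 2, fig1["params"])
        state = PopulationState(H=[1, 1], P=[1, 1])
        state.H[0] = -1  # corrupt after validation
        with pytest.raises(ValueError, match="negative"):
            system.propensities(state)

    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_compiled_kernel_matches_reference_rates(self, name, fig4, rng):
        """The numba kernel and the Python closures give identical rate vectors."""
        for n in [2] if name in ("Evo", "EvoPlus") else [2, 5]:
            for mut in [False] if name in ("Evo", "EvoPlus") else [False, True]:
                params = fig4["params"] if mut else fig4["params"].evolve(mut_H=0, mut_P=0)
                system = build_model(name, n, params, with_mutation=mut)
                for _ in range(10):
                    state = PopulationState(H=rng.integers(0, 40, n), P=rng.integers(0, 60, n))
                    rates = np.zeros(system.n_reactions)
                    m = fill_rates(
                        system.model_code, state.H, state.P, params.kernel_vector(), mut, rates
                    )
                    assert m == system.n_reactions
                    np.testing.assert_allclose(rates, system.propensities(state), atol=1e-12)


class TestMeanFieldDrift:
    """The expected per-time drift of each reaction system equals its ODE limit."""

    @pytest.mark.parametrize("name", ["EcoEvo", "EcoEvoPlus"])
    def test_ecological_drift_equals_lotka_volterra_rhs(self, name, fig1, rng):
        params = fig1["params"]
        system = build_model(name, 2, params)
        for _ in range(10):
            state = PopulationState(H=rng.integers(1, 80, 2), P=rng.integers(1, 200, 2))
            dH, dP = system.drift(state)
            rhs = ode_rhs(name, np.concatenate([state.H, state.P]).astype(float), params, 2)
            np.testing.assert_allclose(np.concatenate([dH, dP]), rhs, rtol=1e-8, atol=1e-10)

    def test_hybrid_frequency_drift_equals_replicator_rhs(self, default_params, rng):
        system = build_model("Hybrid", 2, default_params)
        for _ in range(10):
            state = PopulationState(H=rng.integers(1, 50, 2), P=rng.integers(1, 50, 2))
            dH, dP = system.drift(state)
            # dh = (dH - h dN_H)/N_H with dN_H = 0 in expectation
            assert dH.sum() == pytest.approx(0.0, abs=1e-12)
            assert dP.sum() == pytest.approx(0.0, abs=1e-12)
            y = np.concatenate([state.h, state.p])
            rhs = ode_rhs("Evo", y, default_params, 2)  # plain replicator
            np.testing.assert_allclose(dH / state.N_H, rhs[:2], rtol=1e-8, atol=1e-12)
            np.testing.assert_allclose(dP / state.N_P, rhs[2:], rtol=1e-8, atol=1e-12)

    def test_moran_drift_is_time_rescaled_adjusted_replicator(self, default_params, rng):
        system = build_model("EvoPlus", 2, default_params)
        for _ in range(10):
            state = PopulationState(H=rng.integers(1, 50, 2), P=rng.integers(1, 50, 2))
            dH, dP = system.drift(state)
            y = np.concatenate([state.h, state.p])
            rhs = ode_rhs("EvoPlus", y, default_params, 2)
            np.testing.assert_allclose(dH, rhs[:2], rtol=1e-8, atol=1e-12)
            np.testing.assert_allclose(dP, rhs[2:], rtol=1e-8, atol=1e-12)

    def test_pairwise_drift_is_time_rescaled_replicator(self, default_params, rng):
        # pairwise-comparison rates carry a 1/(w (alpha - beta)) clock factor
        system = build_model("Evo", 2, default_params)
        span_H = default_params.w_H * (default_params.alpha - default_params.beta)
        span_P = default_params.w_P * (default_params.alpha - default_params.beta)
        for _ in range(10):
            state = PopulationState(H=rng.integers(1, 50, 2), P=rng.integers(1, 50, 2))
            dH, dP = system.drift(state)
            y = np.concatenate([state.h, state.p])
            rhs = ode_rhs("Evo", y, default_params, 2)
            np.testing.assert_allclose(dH * span_H, rhs[:2], rtol=1e-8, atol=1e-12)
            np.testing.assert_allclose(dP * span_P, rhs[2:], rtol=1e-8, atol=1e-12)

    def test_host_only_drift_vanishes_at_carrying_capacity(self, fig1):
        params = fig1["params"]
        system = build_model("EcoEvoPlus", 2, params)
        state = PopulationState(H=[50, 50], P=[0, 0])  # N_H = K = 100
        dH, _ = system.drift(state)
        assert dH.sum() == pytest.approx(0.0, abs=1e-9)
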