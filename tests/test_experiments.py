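"""Extinction ensembles, size sweeps, diversity decay, mutation regime."""

import numpy as np
import pytest

from redqueen import (
    ModelParams,
    PopulationState,
    StopCondition,
    diversity_time_series,
    equal_split,
    exact_mean_extinction_time,
    extinction_ensemble,
    fit_exponential_decay,
    mutation_regime_run,
    population_size_sweep,
)
from redqueen.experiments import DiversitySeries


class TestEqualSplit:
    def test_divisible_totals(self):
        s = equal_split(50, 150, 2)
        assert list(s.H) == [25, 25] and list(s.P) == [75, 75]

    def test_remainder_goes_to_low_indices(self):
        s = equal_split(11, 7, 3)
        assert list(s.H) == [4, 4, 3] and list(s.P) == [3, 2, 2]
        assert s.N_H == 11 and s.N_P == 7


class TestExtinctionEnsemble:
    def test_neutral_discrete_ensemble_matches_exact_solver(self):
        params = ModelParams(w_H=0.0, w_P=0.0)
        tau = exact_mean_extinction_time("dtEvo", params, 6, 6)[3, 3]
        summary = extinction_ensemble(
            "dtEvo", 2, params, equal_split(6, 6, 2), 4000, 5, StopCondition(event_max=10**7)
        )
        assert summary.censored == 0
        assert abs(summary.mean - tau) < 3 * summary.sem

    def test_single_replicate_reduces_to_one_record(self, fig1):
        summary = extinction_ensemble(
            "EcoEvoPlus",
            2,
            fig1["params"],
            equal_split(50, 150, 2),
            1,
            3,
            StopCondition(t_max=1e6),
        )
        assert summary.n_reps == 1 and len(summary.records) == 1
        assert summary.times[0] == summary.records[0].time == summary.mean

    def test_master_seed_reproduces_all_replicates(self, fig1):
        args = ("EcoEvoPlus", 2, fig1["params"], equal_split(50, 150, 2), 50, 77,
                StopCondition(t_max=1e6))
        a = extinction_ensemble(*args)
        b = extinction_ensemble(*args)
        np.testing.assert_array_equal(a.times, b.times)

    def test_missing_genotype_rejected(self, fig1):
        init = PopulationState(H=[50, 0], P=[75, 75])
        with pytest.raises(ValueError, match="present"):
            extinction_ensemble(
                "EcoEvo", 2, fig1["params"], init, 5, 1, StopCondition(t_max=10.0)
            )

    def test_censoring_monotone_in_time_cap(self, fig1):
        """Raising t_max never lowers a replicate's recorded time."""
        init = equal_split(50, 150, 2)
        short = extinction_ensemble(
            "EcoEvoPlus", 2, fig1["params"], init, 40, 13, StopCondition(t_max=2.0)
        )
        long = extinction_ensemble(
            "EcoEvoPlus", 2, fig1["params"], init, 40, 13, StopCondition(t_max=1e6)
        )
        for r_short, r_long in zip(short.records, long.records):
            assert r_long.time >= r_short.time - 1e-12
            if not r_short.censored:
                assert r_long.time == r_short.time

    def test_tidy_frame_one_row_per_replicate(self, fig1):
        summary = extinction_ensemble(
            "dtEvoPlus", 2, fig1["params"], equal_split(6, 6, 2), 10, 2,
            StopCondition(event_max=10**6),
        )
        frame = summary.to_frame()
        assert len(frame) == 10
        assert {"extinction_time", "extinct_species", "censored", "w_H"} <= set(frame.columns)


class TestPopulationSizeSweep:
    def test_matched_targets_for_both_ecological_models(self, fig3):
        """EcoEvoPlus at b_H and EcoEvo at b_H/2 target the same N_P."""
        base = fig3["params"]
        stop = StopCondition(t_max=1e5, n_max=10**7)
        res = population_size_sweep(
            {"EcoEvoPlus": ("b_H", [0.8]), "EcoEvo": ("b_H", [0.4])},
            base,
            fig3["N_H"],
            5,
            3,
            stop,
        )
        targets = res.table.set_index("model").target_N_P
        assert targets["EcoEvoPlus"] == pytest.approx(100.0)
        assert targets["EcoEvo"] == pytest.approx(100.0)

    def test_constant_size_target_is_configured_size(self, fig3):
        res = population_size_sweep(
            {"Evo": ("N_P", [40])}, fig3["params"], fig3["N_H"], 5, 9,
            StopCondition(t_max=1e8, event_max=10**8),
        )
        row = res.table.iloc[0]
        assert row.target_N_P == 40 and row.init_N_P == 40 and row.init_N_H == 250

    def test_infeasible_point_flagged_not_dropped(self, fig3):
        # b_H so small the parasite equilibrium is negative under competition
        res = population_size_sweep(
            {"EcoEvoPlus": ("b_H", [0.0008])}, fig3["params"], fig3["N_H"], 5, 4,
            StopCondition(t_max=100.0),
        )
        row = res.table.iloc[0]
        assert not row.feasible and np.isnan(row.target_N_P)


@pytest.fixture(scope="module")
def decay_setup():
    params = ModelParams(b_H=6.0, d_P=1.0, K=1000.0, lam0=40.0)
    init = equal_split(500, 1500, 20)
    grid = np.linspace(0.0, 60.0, 121)[1:]
    return diversity_time_series(
        "EcoEvoPlus", 20, params, 30, 21, grid, init, keep_replicates=True, n_max=10**7
    )


class TestDiversity:
    def test_initial_diversity_is_full(self, decay_setup):
        # first grid point is just past t=0; losses this early are rare
        assert decay_setup.mean_host[0] > 19.0
        assert decay_setup.mean_parasite[0] > 19.0

    def test_per_replicate_series_non_increasing_without_mutation(self, decay_setup):
        assert np.all(np.diff(decay_setup.per_replicate_host, axis=1) <= 0)
        assert np.all(np.diff(decay_setup.per_replicate_parasite, axis=1) <= 0)

    def test_diversity_bounded_by_genotype_count(self, decay_setup):
        for d in (decay_setup.mean_host, decay_setup.mean_parasite):
            assert np.all((d >= 0) & (d <= 20))

    def test_decay_is_log_linear(self, decay_setup):
        rate, r2 = fit_exponential_decay(decay_setup)
        assert rate > 0
        assert r2 >= 0.9


class TestDecayFit:
    def test_exact_exponential_recovered(self):
        t = np.linspace(0, 30, 100)
        D = 20 * np.exp(-0.1 * t)
        series = DiversitySeries(times=t, mean_host=D, mean_parasite=D)
        rate, r2 = fit_exponential_decay(series)
        assert rate == pytest.approx(0.1, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_constant_series_has_zero_rate(self):
        t = np.linspace(0, 10, 20)
        D = np.full_like(t, 5.0)
        series = DiversitySeries(times=t, mean_host=D, mean_parasite=D)
        rate, r2 = fit_exponential_decay(series)
        assert rate == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_window_rejected(self):
        t = np.linspace(0, 10, 20)
        series = DiversitySeries(times=t, mean_host=np.full_like(t, 1.0),
                                 mean_parasite=np.full_like(t, 1.0))
        with pytest.raises(ValueError, match="degenerate"):
            fit_exponential_decay(series)

    def test_matches_direct_search_refit(self, rng):
        """Independent oracle: brute-force minimisation of the same objective."""
        t = np.linspace(0, 20, 50)
        D = 20 * np.exp(-0.23 * t) * np.exp(rng.normal(0, 0.02, t.size))
        series = DiversitySeries(times=t, mean_host=D, mean_parasite=D)
        window = (0.0, 20.0)
        rate, _ = fit_exponential_decay(series, window=window)
        mask = (t >= 0) & (t < 20) & (D > 1)
        x, y = t[mask], np.log(D[mask])

        def sse(r, c):
            resid = y - (c - r * x)
            return resid @ resid

        from scipy.optimize import minimize

        best = minimize(lambda v: sse(*v), x0=[0.1, 3.0], method="Nelder-Mead",
                        options={"xatol": 1e-10, "fatol": 1e-14})
        assert rate == pytest.approx(best.x[0], abs=1e-6)


class TestMutationRegime:
    def test_zero_mutation_rates_never_revive(self, fig4):
        params = fig4["params"].evolve(mut_H=0.0, mut_P=0.0)
        _, revivals = mutation_regime_run(params, 3, t_max=20.0, n=5)
        assert len(revivals) == 0

    def test_revivals_logged_with_mutation(self, fig4):
        traj, revivals = mutation_regime_run(fig4["params"], 11, t_max=60.0, n=5)
        assert len(revivals) > 0
        assert {"time", "species", "genotype"} == set(revivals.columns)
        # a revival means the genotype was absent just before
        assert revivals.time.is_monotonic_increasing

    def test_default_initial_state_is_equilibrium(self, fig4):
        traj, _ = mutation_regime_run(fig4["params"], 1, t_max=1.0, n=5)
        assert traj.H.shape[1] == 5
        # totals start near (300, 900)
        assert abs(traj.H.sum(axis=1)[0] - 300) < 60
        assert abs(traj.P.sum(axis=1)[0] - 900) < 180
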