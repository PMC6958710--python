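"""Extinction-time experiments: ensembles, size sweeps, diversity decay.

The central statistic throughout is the *extinction time*: the first
time any genotype from the initial standing variation is lost from
either the host or the parasite population.  It measures how long the
stochastic Red Queen oscillations survive genetic drift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .deterministic import interior_fixed_point
from .discrete_time import DT_MODELS, simulate_discrete
from .reaction_systems import MODEL_NAMES, ModelParams, build_model
from .ssa import StopCondition, Trajectory, simulate_ct
from .state import ExtinctionRecord, PopulationState

__all__ = [
    "EnsembleSummary",
    "extinction_ensemble",
    "SweepResult",
    "population_size_sweep",
    "DiversitySeries",
    "diversity_time_series",
    "fit_exponential_decay",
    "mutation_regime_run",
    "equal_split",
]


def equal_split(N_H: int, N_P: int, n: int, t: float = 0.0) -> PopulationState:
    """Initial state with each species split equally across ``n`` genotypes.

    Remainders (when a total is not divisible by ``n``) go to the
    lowest genotype indices, one individual each.
    """
    def split(total):
        base, rem = divmod(int(total), n)
        return np.array([base + (1 if i < rem else 0) for i in range(n)], dtype=np.int64)

    return PopulationState(H=split(N_H), P=split(N_P), t=t)


@dataclass
class EnsembleSummary:
    """Per-replicate extinction times of a seeded simulation ensemble.

    The mean/median/SEM cover uncensored replicates only; the censored
    count is reported alongside (``n_reps = len(times) + censored``).
    """

    model: str
    params: ModelParams
    n_reps: int
    seed: int
    times: np.ndarray  # uncensored extinction times
    censored: int
    records: list[ExtinctionRecord] = field(default_factory=list, repr=False)

    @property
    def usable(self) -> bool:
        return self.times.size > 0

    @property
    def mean(self) -> float:
        return float(self.times.mean()) if self.usable else math.nan

    @property
    def median(self) -> float:
        return float(np.median(self.times)) if self.usable else math.nan

    @property
    def std(self) -> float:
        return float(self.times.std(ddof=1)) if self.times.size > 1 else math.nan

    @property
    def sem(self) -> float:
        return self.std / math.sqrt(self.times.size) if self.times.size > 1 else math.nan

    def histogram(self, bins: int = 30) -> tuple[np.ndarray, np.ndarray]:
        return np.histogram(self.times, bins=bins)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per replicate."""
        rows = []
        for r, rec in enumerate(self.records):
            rows.append(
                {
                    "model": self.model,
                    "replicate": r,
                    "master_seed": self.seed,
                    "extinction_time": rec.time,
                    "extinct_species": rec.species,
                    "extinct_genotype": rec.genotype,
                    "censored": rec.censored,
                    **{k: v for k, v in self.params.as_dict().items() if v is not None},
                }
            )
        return pd.DataFrame(rows)


def _master_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(int(seed))


def extinction_ensemble(
    model: str,
    n: int,
    params: ModelParams,
    init: PopulationState,
    n_reps: int,
    seed,
    stop: StopCondition,
) -> EnsembleSummary:
    """Replicate extinction times for one model and parameter set.

    Replicate ``r`` runs on an independent child stream of the master
    seed, so ensembles are reproducible and order-independent.  Works
    for both the discrete-time (``dtEvoPlus``/``dtEvo``, time in
    steps) and the continuous-time models.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if np.any(init.H == 0) or np.any(init.P == 0):
        raise ValueError("all genotypes must be present initially")
    ss = _master_sequence(seed)
    children = ss.spawn(n_reps)
    records: list[ExtinctionRecord] = []

    if model in DT_MODELS:
        if not math.isfinite(stop.event_max) and not math.isfinite(stop.t_max):
            raise ValueError("discrete-time ensembles need a finite step cap")
        cap = min(stop.event_max, stop.t_max)
        for child in children:
            _, rec = simulate_discrete(model, init, params, child, int(cap))
            records.append(rec)
    elif model in MODEL_NAMES:
        system = build_model(model, n, params, with_mutation=params.mut_H > 0 or params.mut_P > 0)
        for child in children:
            _, rec = simulate_ct(system, init, stop, child)
            records.append(rec)
    else:
        raise ValueError(f"unknown model {model!r}")

    times = np.array([r.time for r in records if not r.censored])
    censored = sum(r.censored for r in records)
    master = int(ss.entropy) if isinstance(ss.entropy, int) else -1
    return EnsembleSummary(
        model=model,
        params=params,
        n_reps=n_reps,
        seed=master,
        times=times,
        censored=censored,
        records=records,
    )


@dataclass
class SweepResult:
    """Mean extinction times across a population-size sweep."""

    table: pd.DataFrame
    summaries: dict = field(default_factory=dict, repr=False)

    def mean_time(self, model: str, target_N_P: float) -> float:
        t = self.table
        row = t[(t.model == model) & (np.isclose(t.target_N_P, target_N_P))]
        return float(row.mean_extinction_time.iloc[0])


def population_size_sweep(
    sweep: dict[str, tuple[str, Sequence[float]]],
    base_params: ModelParams,
    N_H: int,
    n_reps: int,
    seed,
    stop: StopCondition,
) -> SweepResult:
    """Extinction-time curves against the (target) parasite population size.

    ``sweep`` maps each model to its declared axis: ``("N_P", values)``
    for the constant-size models (host size fixed at ``N_H``) or
    ``("b_H", values)`` for the ecological ones, whose target ``N_P``
    is computed from the interior-equilibrium formula rather than
    assumed, and whose initial state is the rounded equilibrium.
    Infeasible sweep points are flagged (``feasible = False``), never
    silently dropped.
    """
    ss = _master_sequence(seed)
    rows = []
    summaries: dict[tuple[str, float], EnsembleSummary] = {}
    cells = [(m, v) for m, (axis, values) in sweep.items() for v in values]
    children = ss.spawn(len(cells))

    for (model, value), child in zip(cells, children):
        axis = sweep[model][0]
        row = {"model": model, "axis": axis, "axis_value": value, "n_reps": n_reps}
        if axis == "N_P":
            params = base_params
            init = equal_split(N_H, int(value), 2)
            row.update(target_N_P=float(value), feasible=True)
        elif axis == "b_H":
            comp = 0.0 if model == "EcoEvo" else None
            params = base_params.evolve(b_H=value, comp_rate=comp)
            try:
                fp = interior_fixed_point(model, params, 2)
            except ValueError:
                row.update(target_N_P=math.nan, feasible=False)
                rows.append(row)
                continue
            H0 = np.rint(fp[:2]).astype(np.int64)
            P0 = np.rint(fp[2:]).astype(np.int64)
            if np.any(H0 == 0) or np.any(P0 == 0):
                # equilibrium below one individual per genotype
                row.update(target_N_P=math.nan, feasible=False)
                rows.append(row)
                continue
            init = PopulationState(H=H0, P=P0)
            row.update(target_N_P=float(fp[2:].sum()), feasible=True)
        else:
            raise ValueError(f"unknown sweep axis {axis!r} (use 'N_P' or 'b_H')")

        summary = extinction_ensemble(model, 2, params, init, n_reps, child, stop)
        summaries[(model, row["target_N_P"])] = summary
        row.update(
            mean_extinction_time=summary.mean,
            median_extinction_time=summary.median,
            sem=summary.sem,
            censored=summary.censored,
            init_N_H=init.N_H,
            init_N_P=init.N_P,
            **{k: v for k, v in params.as_dict().items() if v is not None},
        )
        rows.append(row)
    return SweepResult(table=pd.DataFrame(rows), summaries=summaries)


@dataclass
class DiversitySeries:
    """Mean number of distinct genotypes per species over time."""

    times: np.ndarray
    mean_host: np.ndarray
    mean_parasite: np.ndarray
    n_reps: int = 1
    per_replicate_host: np.ndarray | None = None  # (n_reps, n_times)
    per_replicate_parasite: np.ndarray | None = None

    @property
    def mean_both(self) -> np.ndarray:
        return 0.5 * (self.mean_host + self.mean_parasite)


def diversity_time_series(
    model: str,
    n: int,
    params: ModelParams,
    n_reps: int,
    seed,
    t_grid: np.ndarray,
    init: PopulationState,
    keep_replicates: bool = False,
    n_max: float = math.inf,
) -> DiversitySeries:
    """Distinct-genotype counts on a time grid, averaged over replicates.

    Runs continue past genotype losses (no loss stopping) so the full
    decay of diversity is observed; counts are taken from event-exact
    states holding at each grid time.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"diversity series needs a continuous-time model, got {model!r}")
    t_grid = np.asarray(t_grid, dtype=float)
    system = build_model(model, n, params, with_mutation=params.mut_H > 0 or params.mut_P > 0)
    stop = StopCondition(t_max=float(t_grid[-1]), n_max=n_max, stop_on_genotype_loss=False)
    ss = _master_sequence(seed)
    div_H = np.zeros((n_reps, t_grid.size))
    div_P = np.zeros((n_reps, t_grid.size))
    for r, child in enumerate(ss.spawn(n_reps)):
        traj, _ = simulate_ct(system, init, stop, child, t_grid=t_grid)
        if traj.times.size != t_grid.size:  # population-cap stop truncated the grid
            raise RuntimeError("replicate stopped before covering the grid (raise n_max)")
        div_H[r] = (traj.H > 0).sum(axis=1)
        div_P[r] = (traj.P > 0).sum(axis=1)
    return DiversitySeries(
        times=t_grid,
        mean_host=div_H.mean(axis=0),
        mean_parasite=div_P.mean(axis=0),
        n_reps=n_reps,
        per_replicate_host=div_H if keep_replicates else None,
        per_replicate_parasite=div_P if keep_replicates else None,
    )


def fit_exponential_decay(
    series: DiversitySeries,
    species: str = "both",
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Least-squares decay rate of log mean diversity over a time window.

    ``window = None`` uses the decay phase: from ``t = 0`` up to (but
    excluding) the first time the mean diversity drops below 2, which
    cuts off the terminal single-genotype plateau.  Returns
    ``(rate, R^2)`` with ``rate > 0`` for decay.
    """
    D = {"host": series.mean_host, "parasite": series.mean_parasite, "both": series.mean_both}[
        species
    ]
    t = series.times
    if window is None:
        below = np.nonzero(D < 2.0)[0]
        hi = t[below[0]] if below.size else t[-1]
        window = (t[0], hi)
    mask = (t >= window[0]) & (t < window[1]) & (D > 1.0)
    if mask.sum() < 3:
        raise ValueError(f"degenerate fit window {window}: fewer than 3 usable points")
    x, y = t[mask], np.log(D[mask])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0.0 and ss_res < 1e-28 else 1.0 - ss_res / ss_tot
    return float(-slope), r2


def mutation_regime_run(
    params: ModelParams,
    seed,
    t_max: float,
    n: int = 5,
    model: str = "EcoEvoPlus",
    init: PopulationState | None = None,
    t_grid: np.ndarray | None = None,
    n_max: float = 10_000_000,
) -> tuple[Trajectory, pd.DataFrame]:
    """One long run with cyclic mutation, logging genotype revivals.

    A revival is any event in which a genotype count leaves zero.  The
    returned trajectory (recorded on ``t_grid``) supports stacked
    relative-abundance and total-abundance summaries; the revival log
    has columns ``time, species, genotype``.  With both mutation rates
    zero the conversion channels are inert and the log stays empty.
    """
    if init is None:
        fp = interior_fixed_point(model, params, n)
        init = PopulationState(
            H=np.rint(fp[:n]).astype(np.int64), P=np.rint(fp[n:]).astype(np.int64)
        )
    if t_grid is None:
        t_grid = np.linspace(0.0, t_max, 501)[1:]
    system = build_model(model, n, params, with_mutation=True)
    stop = StopCondition(t_max=t_max, n_max=n_max, stop_on_genotype_loss=False)
    traj, _ = simulate_ct(system, init, stop, seed, t_grid=t_grid)
    return traj, traj.revivals
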