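"""Exact stochastic simulation (direct-method Gillespie) of reaction systems.

The driver draws exponential waiting times with rate equal to the total
propensity and picks the reaction proportionally to its rate.  Built-in
models run through a compiled kernel; custom :class:`ReactionSystem`
objects (arbitrary Python propensity callables) use the pure-Python
reference loop, which implements the identical algorithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .reaction_systems import ReactionSystem
from .state import ExtinctionRecord, PopulationState

__all__ = ["StopCondition", "Trajectory", "gillespie_step", "simulate_ct"]

_REV_CAP = 200_000


@dataclass(frozen=True)
class StopCondition:
    """Stopping rules for a continuous-time run.

    At least one of the caps must be finite.  ``n_max`` guards against
    unbounded growth in the unregulated ecological model.
    ``stop_on_genotype_loss`` halts at the first genotype extinction
    (the paper-level statistic); switch it off to observe the full
    diversity decay.
    """

    t_max: float = math.inf
    event_max: float = math.inf
    n_max: float = math.inf
    stop_on_genotype_loss: bool = True

    def __post_init__(self) -> None:
        if not (
            math.isfinite(self.t_max)
            or math.isfinite(self.event_max)
            or math.isfinite(self.n_max)
        ):
            raise ValueError("at least one stopping cap must be finite")


@dataclass
class Trajectory:
    """States recorded on a fixed time grid (state holding *at* each grid time)."""

    times: np.ndarray
    H: np.ndarray  # (n_times, n)
    P: np.ndarray
    n_events: int = 0

    def to_frame(self) -> pd.DataFrame:
        n = self.H.shape[1]
        data = {"t": self.times}
        for i in range(n):
            data[f"H_{i + 1}"] = self.H[:, i]
        for i in range(n):
            data[f"P_{i + 1}"] = self.P[:, i]
        return pd.DataFrame(data)


def gillespie_step(rates: np.ndarray, rng: np.random.Generator) -> tuple[float, int]:
    """One direct-method step: exponential waiting time and reaction index.

    Returns ``(inf, -1)`` when all rates are zero (absorbing state); the
    caller stops.
    """
    rates = np.asarray(rates, dtype=float)
    total = rates.sum()
    if total <= 0.0:
        return math.inf, -1
    wait = rng.exponential(1.0 / total)
    k = int(np.searchsorted(np.cumsum(rates), rng.random() * total, side="right"))
    return wait, min(k, len(rates) - 1)


def _seed_to_kernel(seed) -> int:
    """Map any seed/SeedSequence to the 32-bit integer the kernels take."""
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1, dtype=np.uint32)[0])
    return int(np.random.SeedSequence(int(seed)).generate_state(1, dtype=np.uint32)[0])


def simulate_ct(
    system: ReactionSystem,
    init: PopulationState,
    stop: StopCondition,
    seed,
    t_grid: np.ndarray | None = None,
) -> tuple[Trajectory, ExtinctionRecord]:
    """Simulate a reaction system until a stopping rule fires.

    Parameters
    ----------
    system : ReactionSystem
        Built-in model (compiled fast path) or custom reaction set.
    init : PopulationState
        Initial genotype counts; copied, never mutated.
    stop : StopCondition
        Caps and the genotype-loss stopping flag.
    seed : int or numpy.random.SeedSequence
        Reproducibility contract: identical seed and inputs give an
        identical trajectory.
    t_grid : array, optional
        Recording grid (bounds memory on long runs).  Extinction
        detection always uses exact event states, independent of the
        grid.  ``None`` records nothing.

    Returns
    -------
    (Trajectory, ExtinctionRecord)
    """
    if init.n != system.n:
        raise ValueError("initial state dimension does not match the system")
    grid = np.asarray([] if t_grid is None else t_grid, dtype=float)
    if grid.size and (np.any(np.diff(grid) <= 0) or grid[0] < init.t):
        raise ValueError("t_grid must be strictly increasing and start at or after init.t")

    if system.model_code is not None:
        return _simulate_kernel(system, init, stop, seed, grid)
    return _simulate_py(system, init, stop, seed, grid)


def _record_from(status, t, sp, g, t0) -> ExtinctionRecord:
    if status == _kernels.STATUS_LOSS:
        return ExtinctionRecord(
            time=t - t0, species="host" if sp == 0 else "parasite", genotype=int(g)
        )
    return ExtinctionRecord(time=t - t0, censored=True)


def _simulate_kernel(system, init, stop, seed, grid):
    H = init.H.copy()
    P = init.P.copy()
    n = system.n
    rec_H = np.zeros((grid.size, n), dtype=np.int64)
    rec_P = np.zeros((grid.size, n), dtype=np.int64)
    rev_t = np.zeros(_REV_CAP)
    rev_sp = np.zeros(_REV_CAP, dtype=np.int64)
    rev_g = np.zeros(_REV_CAP, dtype=np.int64)
    event_max = stop.event_max if math.isfinite(stop.event_max) else 2**62
    n_max = stop.n_max if math.isfinite(stop.n_max) else 2**62
    status, t, sp, g, n_events, gi, n_rev = _kernels.ssa_run(
        system.model_code,
        H,
        P,
        system.params.kernel_vector(),
        system.with_mutation,
        system.delta_H,
        system.delta_P,
        float(init.t),
        float(stop.t_max),
        int(event_max),
        int(n_max),
        stop.stop_on_genotype_loss,
        grid,
        rec_H,
        rec_P,
        _REV_CAP,
        rev_t,
        rev_sp,
        rev_g,
        _seed_to_kernel(seed),
    )
    traj = Trajectory(times=grid[:gi], H=rec_H[:gi], P=rec_P[:gi], n_events=int(n_events))
    traj.revivals = pd.DataFrame(
        {
            "time": rev_t[:n_rev],
            "species": np.where(rev_sp[:n_rev] == 0, "host", "parasite"),
            "genotype": rev_g[:n_rev],
        }
    )
    return traj, _record_from(status, t, sp, g, init.t)


def _simulate_py(system, init, stop, seed, grid):
    """Reference Python driver (used for custom systems and as a kernel oracle)."""
    rng = np.random.default_rng(seed)
    state = init.copy()
    n = system.n
    rec_H, rec_P = [], []
    gi = 0
    n_events = 0
    revivals = []

    def lost() -> tuple[int, int]:
        for i in range(n):
            if state.H[i] == 0:
                return 0, i
        for i in range(n):
            if state.P[i] == 0:
                return 1, i
        return -1, -1

    def finish(status, t):
        nonlocal gi
        if status in (_kernels.STATUS_ABSORBED, _kernels.STATUS_T_MAX):
            while gi < grid.size:
                rec_H.append(state.H.copy())
                rec_P.append(state.P.copy())
                gi += 1
        traj = Trajectory(
            times=grid[:gi],
            H=np.array(rec_H, dtype=np.int64).reshape(gi, n),
            P=np.array(rec_P, dtype=np.int64).reshape(gi, n),
            n_events=n_events,
        )
        traj.revivals = pd.DataFrame(revivals, columns=["time", "species", "genotype"])
        return traj, _record_from(status, t, *lost(), init.t)

    if stop.stop_on_genotype_loss:
        sp, g = lost()
        if sp >= 0:
            return finish(_kernels.STATUS_LOSS, state.t)

    while True:
        rates = system.propensities(state)
        wait, k = gillespie_step(rates, rng)
        if k < 0:
            return finish(_kernels.STATUS_ABSORBED, state.t)
        tn = state.t + wait
        if tn > stop.t_max:
            return finish(_kernels.STATUS_T_MAX, stop.t_max)
        while gi < grid.size and grid[gi] < tn:
            rec_H.append(state.H.copy())
            rec_P.append(state.P.copy())
            gi += 1
        dH, dP = system.delta_H[k], system.delta_P[k]
        for i in np.nonzero(dH > 0)[0]:
            if state.H[i] == 0:
                revivals.append((tn, "host", i))
        for i in np.nonzero(dP > 0)[0]:
            if state.P[i] == 0:
                revivals.append((tn, "parasite", i))
        state.H += dH
        state.P += dP
        state.t = tn
        n_events += 1
        if np.any(state.H < 0) or np.any(state.P < 0):
            raise RuntimeError(f"state corruption: negative count after {system.reactions[k].label}")
        if stop.stop_on_genotype_loss and (np.any(state.H == 0) or np.any(state.P == 0)):
            return finish(_kernels.STATUS_LOSS, state.t)
        if n_events >= stop.event_max:
            return finish(_kernels.STATUS_EVENT_MAX, state.t)
        if state.H.sum() + state.P.sum() > stop.n_max:
            return finish(_kernels.STATUS_N_MAX, state.t)
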