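"""Discrete-time constant-size processes and exact extinction times.

Two birth-death processes for two genotypes per species, with host and
parasite updated simultaneously in every step (``dt = 1`` per paired
update, payoffs evaluated at the pre-step state):

``dtEvoPlus``
    Moran process: the probability of replacing a genotype-2 individual
    by a genotype-1 birth is ``x2 * x1 * f1 / f_mean`` — fitness is
    normalised by the population average (global competition).
``dtEvo``
    Pairwise-comparison process: the Moran factor ``f1 / f_mean`` is
    replaced by ``0.5 + 0.5 (f1 - f2) / (w (alpha - beta))`` — only the
    fitness difference of a sampled pair matters (local competition).

Because the two per-species updates are independent given the pre-step
state, the full transition kernel is the product of two tridiagonal
step distributions, and the mean time to the first genotype loss can be
computed exactly as the first-passage time of an absorbing Markov chain
(solving ``(I - Q) tau = 1`` over the transient states).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _kernels
from .reaction_systems import ModelParams, evo_replacement_rates
from .state import ExtinctionRecord, PopulationState

__all__ = [
    "DT_MODELS",
    "StepDistribution",
    "dt_step_distribution",
    "simulate_discrete",
    "exact_mean_extinction_time",
    "exact_table_to_frame",
]

DT_MODELS = ("dtEvoPlus", "dtEvo")

#: guard on the (N_H+1)*(N_P+1) state space of the exact solver
MAX_EXACT_STATES = 250_000


def _check_model(model: str) -> bool:
    if model not in DT_MODELS:
        raise ValueError(f"unknown discrete-time model {model!r}; choose from {DT_MODELS}")
    return model == "dtEvoPlus"


@dataclass(frozen=True)
class StepDistribution:
    """Per-step probabilities of the genotype-1 count change, per species.

    Each triple is ``(P(+1), P(0), P(-1))`` and sums to one; the
    remainder mass on 0 covers self-replacements, which consume a time
    step like any other reaction.
    """

    host: tuple[float, float, float]
    parasite: tuple[float, float, float]


def dt_step_distribution(
    model: str, state: PopulationState, params: ModelParams
) -> StepDistribution:
    """One-step change distribution for both species at the current state.

    Boundary states (a genotype at 0 or at the species total) are
    absorbing and yield the degenerate triple ``(0, 1, 0)``.
    """
    moran = _check_model(model)
    if state.n != 2:
        raise ValueError("discrete-time processes support exactly 2 genotypes")
    if state.N_H < 1 or state.N_P < 1:
        raise ValueError("both species must be non-empty")
    up_h, down_h, up_p, down_p = evo_replacement_rates(state, params, moran)
    return StepDistribution(
        host=(up_h, 1.0 - up_h - down_h, down_h),
        parasite=(up_p, 1.0 - up_p - down_p, down_p),
    )


def simulate_discrete(
    model: str,
    init: PopulationState,
    params: ModelParams,
    seed,
    max_steps: int,
    record: bool = False,
) -> tuple[np.ndarray | None, ExtinctionRecord]:
    """Run one discrete-time trajectory until the first genotype loss.

    Both species draw one change from the pre-step distribution in each
    step; population sizes are exactly conserved.  Returns the recorded
    ``(step, H1, P1)`` trajectory (when ``record``) and the extinction
    record in steps.  Reaching ``max_steps`` yields a censored record.
    """
    moran = _check_model(model)
    if init.n != 2:
        raise ValueError("discrete-time processes support exactly 2 genotypes")
    N_H, N_P = init.N_H, init.N_P

    if not record:
        steps, sp_, g, censored = _kernels.dt_run(
            moran,
            int(init.H[0]),
            N_H,
            int(init.P[0]),
            N_P,
            params.w_H,
            params.w_P,
            params.alpha,
            params.beta,
            int(max_steps),
            _dt_seed(seed),
        )
        return None, _dt_record(steps, sp_, g, censored)

    # pure-Python recording path (identical arithmetic via evo_replacement_rates)
    rng = np.random.default_rng(seed)
    H1, P1 = int(init.H[0]), int(init.P[0])
    traj = [(0, H1, P1)]
    step = 0
    while step < max_steps:
        sp_, g = _boundary(H1, N_H, P1, N_P)
        if sp_ >= 0:
            return np.array(traj), _dt_record(step, sp_, g, 0)
        state = PopulationState(H=[H1, N_H - H1], P=[P1, N_P - P1], t=step)
        up_h, down_h, up_p, down_p = evo_replacement_rates(state, params, moran)
        u = rng.random()
        if u < up_h:
            H1 += 1
        elif u < up_h + down_h:
            H1 -= 1
        u = rng.random()
        if u < up_p:
            P1 += 1
        elif u < up_p + down_p:
            P1 -= 1
        step += 1
        traj.append((step, H1, P1))
    sp_, g = _boundary(H1, N_H, P1, N_P)
    if sp_ >= 0:
        return np.array(traj), _dt_record(step, sp_, g, 0)
    return np.array(traj), _dt_record(step, -1, -1, 1)


def _dt_seed(seed) -> int:
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1, dtype=np.uint32)[0])
    return int(np.random.SeedSequence(int(seed)).generate_state(1, dtype=np.uint32)[0])


def _boundary(H1, N_H, P1, N_P):
    if H1 == 0:
        return 0, 0
    if H1 == N_H:
        return 0, 1
    if P1 == 0:
        return 1, 0
    if P1 == N_P:
        return 1, 1
    return -1, -1


def _dt_record(steps, sp_, g, censored) -> ExtinctionRecord:
    if censored:
        return ExtinctionRecord(time=float(steps), censored=True)
    return ExtinctionRecord(
        time=float(steps), species="host" if sp_ == 0 else "parasite", genotype=int(g)
    )


def _step_triples(model: str, params: ModelParams, N_H: int, N_P: int):
    """Vectorised (up, down) arrays over the full (H1, P1) grid."""
    moran = _check_model(model)
    a, b = params.alpha, params.beta
    h1 = (np.arange(N_H + 1) / N_H)[:, None]  # column: host axis
    p1 = (np.arange(N_P + 1) / N_P)[None, :]  # row: parasite axis
    h2, p2 = 1.0 - h1, 1.0 - p1

    piH1 = (a + b) - (a * p1 + b * p2)
    piH2 = (a + b) - (b * p1 + a * p2)
    fH1 = 1.0 - params.w_H + params.w_H * piH1
    fH2 = 1.0 - params.w_H + params.w_H * piH2
    piP1 = a * h1 + b * h2
    piP2 = b * h1 + a * h2
    fP1 = 1.0 - params.w_P + params.w_P * piP1
    fP2 = 1.0 - params.w_P + params.w_P * piP2

    prod_h = h1 * h2 * np.ones_like(p1)
    prod_p = p1 * p2 * np.ones_like(h1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if moran:
            fbar_h = h1 * fH1 + h2 * fH2
            up_h = prod_h * fH1 / fbar_h
            down_h = prod_h * fH2 / fbar_h
            fbar_p = p1 * fP1 + p2 * fP2
            up_p = prod_p * fP1 / fbar_p
            down_p = prod_p * fP2 / fbar_p
        else:
            span_h = params.w_H * (a - b)
            g_h = np.full_like(prod_h, 0.5) if span_h == 0 else 0.5 + 0.5 * (fH1 - fH2) / span_h
            up_h, down_h = prod_h * g_h, prod_h * (1.0 - g_h)
            span_p = params.w_P * (a - b)
            g_p = np.full_like(prod_p, 0.5) if span_p == 0 else 0.5 + 0.5 * (fP1 - fP2) / span_p
            up_p, down_p = prod_p * g_p, prod_p * (1.0 - g_p)
    # boundary states are absorbing; zero their outflow (also clears any 0/0)
    for arr in (up_h, down_h, up_p, down_p):
        arr[0, :] = arr[-1, :] = arr[:, 0] = arr[:, -1] = 0.0
        np.nan_to_num(arr, copy=False)
    return up_h, down_h, up_p, down_p


def exact_mean_extinction_time(
    model: str, params: ModelParams, N_H: int, N_P: int
) -> np.ndarray:
    """Exact expected first-loss times for every starting state.

    Builds the paired-update transition kernel as the product of the
    two per-species step distributions (at most 9 nonzeros per row) on
    the ``(N_H + 1) x (N_P + 1)`` grid of genotype-1 counts, marks
    states with a genotype at 0 or at the species total absorbing, and
    solves the first-passage system ``(I - Q) tau = 1`` over the
    transient (interior) states with a sparse direct solve.

    Returns the full table ``tau[H1, P1]`` (zero at absorbing states),
    indexed row-major in ``(H1, P1)``.
    """
    n_states = (N_H + 1) * (N_P + 1)
    if n_states > MAX_EXACT_STATES:
        raise ValueError(
            f"state space too large for the exact solver: {n_states} > {MAX_EXACT_STATES}"
        )
    up_h, down_h, up_p, down_p = _step_triples(model, params, N_H, N_P)
    stay_h = 1.0 - up_h - down_h
    stay_p = 1.0 - up_p - down_p

    # transient (interior) states, row-major in (H1, P1)
    Hi = np.arange(1, N_H)[:, None] * np.ones(N_P - 1, dtype=int)[None, :]
    Pi = np.ones(N_H - 1, dtype=int)[:, None] * np.arange(1, N_P)[None, :]
    Hi, Pi = Hi.ravel(), Pi.ravel()
    n_tr = Hi.size
    idx = -np.ones((N_H + 1, N_P + 1), dtype=np.int64)
    idx[Hi, Pi] = np.arange(n_tr)

    host_moves = [(+1, up_h), (0, stay_h), (-1, down_h)]
    par_moves = [(+1, up_p), (0, stay_p), (-1, down_p)]
    rows, cols, vals = [], [], []
    for dh, ph in host_moves:
        for dp, pp in par_moves:
            prob = ph[Hi, Pi] * pp[Hi, Pi]
            tH, tP = Hi + dh, Pi + dp
            tgt = idx[tH, tP]
            keep = (tgt >= 0) & (prob > 0)
            rows.append(np.arange(n_tr)[keep])
            cols.append(tgt[keep])
            vals.append(prob[keep])
    Q = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_tr, n_tr),
    )
    A = sp.identity(n_tr, format="csr") - Q
    tau_tr = spla.spsolve(A.tocsc(), np.ones(n_tr))
    if not np.all(np.isfinite(tau_tr)) or np.any(tau_tr <= 0):
        raise RuntimeError("first-passage solve failed: non-finite or non-positive times")

    tau = np.zeros((N_H + 1, N_P + 1))
    tau[Hi, Pi] = tau_tr
    return tau


def exact_table_to_frame(
    model: str, params: ModelParams, N_H: int, N_P: int, tau: np.ndarray
) -> pd.DataFrame:
    """Tidy long-format table of the exact expected first-loss times."""
    H1, P1 = np.meshgrid(np.arange(N_H + 1), np.arange(N_P + 1), indexing="ij")
    return pd.DataFrame(
        {
            "model": model,
            "N_H": N_H,
            "N_P": N_P,
            "w_H": params.w_H,
            "w_P": params.w_P,
            "start_H1": H1.ravel(),
            "start_P1": P1.ravel(),
            "expected_time": tau.ravel(),
        }
    )
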