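"""Deterministic (infinite-population) limits of the five models.

* ``Evo`` and ``Hybrid`` -> the two-population replicator dynamics
  (neutrally stable interior fixed point, closed orbits).
* ``EvoPlus`` -> the adjusted replicator dynamics, i.e. the replicator
  selection term divided by the mean fitness (globally attracting
  interior fixed point, damped oscillations -> stasis).
* ``EcoEvo`` -> two-species Lotka-Volterra dynamics per matched
  genotype pair (neutral centre).
* ``EcoEvoPlus`` -> Lotka-Volterra with logistic host regulation
  (attracting interior fixed point).

The right-hand sides are written with the selection-intensity-bearing
fitness ``f = 1 - w + w pi`` (not the raw payoff), matching the stated
limits of the stochastic processes whose rates contain ``w``.
Frequency models evolve ``y = (h_1..h_n, p_1..p_n)`` on the product of
two simplices; ecological models evolve absolute abundances
``y = (H_1..H_n, P_1..P_n)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.integrate import solve_ivp

from .reaction_systems import MODEL_NAMES, ModelParams

__all__ = [
    "FREQUENCY_MODELS",
    "ECOLOGICAL_MODELS",
    "ode_rhs",
    "integrate_ode",
    "interior_fixed_point",
    "classify_fixed_point",
    "orbit_return",
    "DeterministicTrajectory",
    "StabilityReport",
]

FREQUENCY_MODELS = ("EvoPlus", "Evo", "Hybrid")
ECOLOGICAL_MODELS = ("EcoEvo", "EcoEvoPlus")


def _check_model(model: str) -> None:
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}; choose from {MODEL_NAMES}")


def model_kind(model: str) -> str:
    _check_model(model)
    return "frequency" if model in FREQUENCY_MODELS else "abundance"


def ode_rhs(model: str, y: np.ndarray, params: ModelParams, n: int) -> np.ndarray:
    """Right-hand side of the deterministic limit at state ``y``.

    Frequency models return replicator-type derivatives that sum to
    zero per species on the simplex; ecological models return
    Lotka-Volterra abundance derivatives.
    """
    _check_model(model)
    y = np.asarray(y, dtype=float)
    if y.shape != (2 * n,):
        raise ValueError(f"state must have length 2n = {2 * n}")
    a, b = params.alpha, params.beta

    if model in FREQUENCY_MODELS:
        h, p = y[:n], y[n:]
        # payoffs written with explicit sums so the rhs is smooth off the
        # simplex (adaptive integrator stages need not sum exactly to 1)
        pi_P = b * h.sum() + (a - b) * h
        pi_H = (a + b) - (b * p.sum() + (a - b) * p)
        f_H = 1.0 - params.w_H + params.w_H * pi_H
        f_P = 1.0 - params.w_P + params.w_P * pi_P
        fbar_H = h @ f_H
        fbar_P = p @ f_P
        dh = h * (f_H - fbar_H)
        dp = p * (f_P - fbar_P)
        if model == "EvoPlus":
            if fbar_H <= 0 or fbar_P <= 0:
                raise ValueError("adjusted replicator needs positive mean fitness")
            dh = dh / fbar_H
            dp = dp / fbar_P
        return np.concatenate([dh, dp])

    lam = params.lam
    comp = params.comp_rate if model == "EcoEvoPlus" else 0.0
    if lam is None:
        raise ValueError("ecological models need an interaction rate lam")
    H, P = y[:n], y[n:]
    dH = H * (params.b_H - (comp or 0.0) * H.sum() - lam * P)
    dP = P * (lam * H - params.d_P)
    return np.concatenate([dH, dP])


@dataclass
class DeterministicTrajectory:
    """ODE solution sampled on a time grid."""

    model: str
    n: int
    times: np.ndarray
    y: np.ndarray  # (n_times, 2n)

    @property
    def kind(self) -> str:
        return model_kind(self.model)

    @property
    def host(self) -> np.ndarray:
        return self.y[:, : self.n]

    @property
    def parasite(self) -> np.ndarray:
        return self.y[:, self.n :]

    def to_frame(self) -> pd.DataFrame:
        prefix = ("h", "p") if self.kind == "frequency" else ("H", "P")
        data = {"t": self.times, "model": self.model, "kind": self.kind}
        for i in range(self.n):
            data[f"{prefix[0]}_{i + 1}"] = self.host[:, i]
        for i in range(self.n):
            data[f"{prefix[1]}_{i + 1}"] = self.parasite[:, i]
        return pd.DataFrame(data)


def integrate_ode(
    model: str,
    init: np.ndarray,
    params: ModelParams,
    t_grid: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "DOP853",
) -> DeterministicTrajectory:
    """Adaptively integrate the deterministic limit over ``t_grid``."""
    init = np.asarray(init, dtype=float)
    n = init.size // 2
    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(
        lambda t, y: ode_rhs(model, y, params, n),
        (t_grid[0], t_grid[-1]),
        init,
        t_eval=t_grid,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message} (last t={sol.t[-1]})")
    return DeterministicTrajectory(model=model, n=n, times=sol.t, y=sol.y.T)


def interior_fixed_point(model: str, params: ModelParams, n: int) -> np.ndarray:
    """The interior coexistence fixed point.

    Frequency models: the uniform point ``1/n`` per genotype (symmetric
    matching alleles).  Ecological models: ``H_i* = d_P / lam`` and
    ``P_i* = (b_H - comp_rate * n * H_i*) / lam`` per genotype.
    """
    _check_model(model)
    if model in FREQUENCY_MODELS:
        fp = np.full(2 * n, 1.0 / n)
    else:
        lam = params.lam
        if lam is None or lam <= 0 or params.d_P <= 0 or params.b_H <= 0:
            raise ValueError("ecological equilibrium needs lam, d_P, b_H > 0")
        comp = params.comp_rate if model == "EcoEvoPlus" else 0.0
        H_star = params.d_P / lam
        P_star = (params.b_H - (comp or 0.0) * n * H_star) / lam
        if P_star <= 0:
            raise ValueError(
                f"infeasible equilibrium: P* = {P_star} <= 0 (b_H too small for n={n})"
            )
        fp = np.concatenate([np.full(n, H_star), np.full(n, P_star)])
    resid = np.abs(ode_rhs(model, fp, params, n)).max()
    if resid > 1e-10:
        raise RuntimeError(f"fixed-point residual {resid} exceeds 1e-10")
    return fp


@dataclass
class StabilityReport:
    """Stability of the interior fixed point.

    ``method`` records how the call was decided: ``"linear"`` when the
    Jacobian spectrum alone was decisive, ``"orbit"`` when the
    spectrally neutral oscillation mode had to be disambiguated by the
    per-period contraction of a test orbit (``shrink_ratio`` is the
    distance-to-fixed-point ratio across one oscillation period).
    """

    model: str
    fixed_point: np.ndarray
    eigenvalues: np.ndarray
    classification: str  # attracting | neutral | repelling
    tol: float
    method: str = "linear"
    shrink_ratio: float | None = None
    inconclusive: bool = False


def _jacobian(model, y0, params, n, step):
    m = y0.size
    J = np.empty((m, m))
    for j in range(m):
        e = np.zeros(m)
        e[j] = step
        J[:, j] = (ode_rhs(model, y0 + e, params, n) - ode_rhs(model, y0 - e, params, n)) / (
            2 * step
        )
    return J


def classify_fixed_point(
    model: str,
    params: ModelParams,
    n: int,
    tol: float = 1e-8,
    orbit_tol: float = 1e-4,
    delta: float = 0.1,
) -> StabilityReport:
    """Classify the interior fixed point as attracting, neutral or repelling.

    The numerical Jacobian (restricted, for frequency models, to the
    tangent space of the two simplices) decides the easy cases: largest
    real part below ``-tol`` is attracting, above ``tol`` repelling.
    In these models, however, the genotype-composition (oscillation)
    mode is *linearly* neutral in every case — the damping that
    separates the global-competition (+) models from the neutral ones
    is a nonlinear effect.  A spectrally neutral point is therefore
    disambiguated by integrating a test orbit perturbed by ``delta``
    (relative) along the composition mode and measuring the ratio of
    distances to the fixed point across one oscillation period:
    contraction beyond ``orbit_tol`` is attracting, expansion
    repelling, anything within is neutral.  The report is flagged
    inconclusive when halving the finite-difference step moves the
    decisive real part by more than ``tol``.
    """
    fp = interior_fixed_point(model, params, n)
    scale = max(1.0, float(np.abs(fp).max()))
    step = 1e-6 * scale

    def max_re(step_):
        J = _jacobian(model, fp, params, n, step_)
        if model in FREQUENCY_MODELS:
            C = np.zeros((2, 2 * n))
            C[0, :n] = 1.0
            C[1, n:] = 1.0
            T = scipy.linalg.null_space(C)
            J = T.T @ J @ T
        ev = np.linalg.eigvals(J)
        return ev, float(ev.real.max())

    ev, mre = max_re(step)
    _, mre2 = max_re(step / 2)
    inconclusive = abs(mre - mre2) > tol
    if mre < -tol:
        return StabilityReport(model, fp, ev, "attracting", tol, "linear", None, inconclusive)
    if mre > tol:
        return StabilityReport(model, fp, ev, "repelling", tol, "linear", None, inconclusive)

    u = np.zeros(2 * n)
    u[0], u[1] = 1.0, -1.0
    y0 = fp + delta * fp[0] * u / np.sqrt(2.0)
    r0 = float(np.linalg.norm(y0 - fp))
    _, y_T = _section_return(model, y0, params, n)
    ratio = float(np.linalg.norm(y_T - fp)) / r0
    if ratio < 1.0 - orbit_tol:
        cls = "attracting"
    elif ratio > 1.0 + orbit_tol:
        cls = "repelling"
    else:
        cls = "neutral"
    return StabilityReport(model, fp, ev, cls, tol, "orbit", ratio, inconclusive)


def orbit_return(
    model: str,
    init: np.ndarray,
    params: ModelParams,
    t_max: float = 500.0,
    rtol: float = 1e-12,
    atol: float = 1e-14,
) -> tuple[float, float]:
    """First Poincare-section return of an orbit.

    The section is the fastest-moving state coordinate crossing its
    initial value in the initial direction; the first such return
    closes one full period.  Returns ``(period, distance to the
    initial state at return)``.  Raises if the dynamics start exactly
    at rest (no section definable) or the orbit does not return within
    ``t_max``.
    """
    init = np.asarray(init, dtype=float)
    n = init.size // 2
    T, y_T = _section_return(model, init, params, n, t_max, rtol, atol)
    return T, float(np.linalg.norm(y_T - init))


def _section_return(model, y0, params, n, t_max=500.0, rtol=1e-12, atol=1e-14):
    d0 = ode_rhs(model, y0, params, n)
    j = int(np.argmax(np.abs(d0)))
    if d0[j] == 0.0:
        raise ValueError("Poincare section undefined: dynamics start at rest")

    def section(t, y):
        return y[j] - y0[j]

    # non-terminal: the solver may report a spurious event at t ~ 0
    # (the orbit starts exactly on the section), filtered out below
    section.direction = 1.0 if d0[j] > 0 else -1.0
    sol = solve_ivp(
        lambda t, y: ode_rhs(model, y, params, n),
        (0.0, t_max),
        y0,
        events=section,
        method="DOP853",
        rtol=rtol,
        atol=atol,
    )
    returns = [(float(t), y) for t, y in zip(sol.t_events[0], sol.y_events[0]) if t > 1e-6]
    if not returns:
        raise RuntimeError(f"orbit did not return to the section within t_max={t_max}")
    return returns[0]
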