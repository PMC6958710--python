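"""Continuous-time model definitions as reaction systems.

Five individual-based host-parasite models, all built on the same
matching-allele game but differing in how population size is regulated:

``EvoPlus``
    Moran-type replacement within each species (birth proportional to
    fitness normalised by the population mean fitness — global
    intraspecific competition).  Population sizes are strictly constant.
``Evo``
    Pairwise-comparison replacement: the reproducing genotype is decided
    by the fitness *difference* of a sampled pair, not the population
    mean.  Sizes strictly constant.
``Hybrid``
    Explicit birth/death reactions whose per-capita host death and
    parasite birth rates come from the game, with the opposing rates
    dynamically balanced so each species' total birth and death rates
    are equal at every state.  Sizes constant in expectation only.
``EcoEvo``
    Lotka-Volterra-type independent reactions: host birth at ``b_H``,
    parasite death at ``d_P``, and matched host-parasite encounters
    that kill the host or reproduce the parasite at rate ``lam`` each.
    Sizes unconstrained.
``EcoEvoPlus``
    EcoEvo plus intraspecific host competition at rate ``comp_rate``,
    giving logistic host regulation with carrying capacity
    ``K = b_H / comp_rate``.

Optional cyclic nearest-neighbour mutation (genotype ``i`` converts to
``i +- 1 mod n`` at rate ``mut/2`` each) is available for the ecological
and Hybrid models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

from .interactions import build_matching_matrix, fitness_from_payoff, host_payoffs, parasite_payoffs
from .state import PopulationState

__all__ = [
    "ModelParams",
    "Reaction",
    "ReactionSystem",
    "build_model",
    "MODEL_NAMES",
    "MODEL_CODES",
]

#: canonical continuous-time model names
MODEL_NAMES = ("EvoPlus", "Evo", "Hybrid", "EcoEvo", "EcoEvoPlus")

#: integer codes shared with the compiled simulation kernels
MODEL_CODES = {"EvoPlus": 1, "Evo": 2, "Hybrid": 3, "EcoEvo": 4, "EcoEvoPlus": 5}

_REL_TOL = 1e-9


@dataclass(frozen=True)
class ModelParams:
    """All model rates and intensities.

    Parameters
    ----------
    w_H, w_P : float
        Host and parasite selection intensities in [0, 1].
    alpha, beta : float
        Matching-allele payoffs (match / mismatch), ``alpha >= beta``.
    b_H : float
        Host per-capita birth rate (ecological models).
    d_P : float
        Parasite per-capita death rate (ecological models).
    lam : float, optional
        Host-parasite interaction rate per pair.  May instead be derived
        as ``lam0 / K``.
    lam0 : float, optional
        Base interaction rate; with a carrying capacity ``K`` set,
        ``lam = lam0 / K``.
    comp_rate : float, optional
        Intraspecific host competition rate per host pair.  Derived as
        ``b_H / K`` when left unset and ``K`` is given.
    K : float, optional
        Host carrying capacity ``b_H / comp_rate``.
    mut_H, mut_P : float
        Genotype conversion (mutation) rates per capita.

    Note the source models use the same symbol for the competition and
    mutation rates; they are distinct parameters here.
    """

    w_H: float = 0.5
    w_P: float = 1.0
    alpha: float = 1.0
    beta: float = 0.0
    b_H: float = 6.0
    d_P: float = 1.0
    lam: float | None = None
    lam0: float | None = None
    comp_rate: float | None = None
    K: float | None = None
    mut_H: float = 0.0
    mut_P: float = 0.0

    def __post_init__(self) -> None:
        for name in ("w_H", "w_P"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.alpha < self.beta:
            raise ValueError(f"alpha ({self.alpha}) must be >= beta ({self.beta})")
        for name in ("b_H", "d_P", "mut_H", "mut_P"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        # resolve derived parameters; explicit values win but must be consistent
        lam = self.lam
        if lam is None and self.lam0 is not None and self.K:
            lam = self.lam0 / self.K
        comp = self.comp_rate
        K = self.K
        if comp is None and K:
            comp = self.b_H / K
        if K is None and comp:
            K = self.b_H / comp
        if lam is not None and lam < 0:
            raise ValueError("lam must be >= 0")
        if comp is not None and comp < 0:
            raise ValueError("comp_rate must be >= 0")
        if (
            self.lam is not None
            and self.lam0 is not None
            and self.K
            and abs(self.lam - self.lam0 / self.K) > _REL_TOL * max(1.0, self.lam)
        ):
            raise ValueError(
                f"inconsistent interaction rates: lam={self.lam} but lam0/K={self.lam0 / self.K}"
            )
        # K only regulates the host when competition is active; comp_rate=0
        # (EcoEvo) may legitimately coexist with a K used to scale lam0
        if (
            self.comp_rate is not None
            and self.comp_rate > 0
            and self.K
            and abs(self.K * self.comp_rate - self.b_H) > _REL_TOL * max(1.0, self.b_H)
        ):
            raise ValueError(
                f"inconsistent regulation: K*comp_rate={self.K * self.comp_rate} != b_H={self.b_H}"
            )
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "comp_rate", comp)
        object.__setattr__(self, "K", K)

    def evolve(self, **changes) -> "ModelParams":
        """Copy with fields replaced (derived fields re-resolved)."""
        d = self.as_dict()
        d.update(changes)
        return ModelParams(**d)

    def as_dict(self) -> dict:
        return {
            "w_H": self.w_H,
            "w_P": self.w_P,
            "alpha": self.alpha,
            "beta": self.beta,
            "b_H": self.b_H,
            "d_P": self.d_P,
            "lam": self.lam,
            "lam0": self.lam0,
            "comp_rate": self.comp_rate,
            "K": self.K,
            "mut_H": self.mut_H,
            "mut_P": self.mut_P,
        }

    def kernel_vector(self) -> np.ndarray:
        """Pack the rates used by the compiled kernels into a flat array."""
        return np.array(
            [
                self.w_H,
                self.w_P,
                self.alpha,
                self.beta,
                self.b_H,
                self.d_P,
                self.lam if self.lam is not None else 0.0,
                self.comp_rate if self.comp_rate is not None else 0.0,
                self.mut_H,
                self.mut_P,
            ],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class Reaction:
    """One microscopic event: stoichiometry plus a state-dependent rate."""

    label: str
    delta_H: np.ndarray
    delta_P: np.ndarray
    propensity: Callable[[PopulationState], float]


@dataclass
class ReactionSystem:
    """An ordered reaction set defining a continuous-time Markov jump process.

    Reaction order is deterministic given ``(model, n, with_mutation)``
    so that seeded simulations are reproducible.  ``model_code`` is set
    for the five built-in models (enabling the compiled fast path) and
    ``None`` for custom systems.
    """

    name: str
    n: int
    reactions: list[Reaction]
    params: ModelParams | None = None
    model_code: int | None = None
    with_mutation: bool = False
    conserves_sizes: bool = False

    def __post_init__(self) -> None:
        self.delta_H = np.array([r.delta_H for r in self.reactions], dtype=np.int64)
        self.delta_P = np.array([r.delta_P for r in self.reactions], dtype=np.int64)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def propensities(self, state: PopulationState) -> np.ndarray:
        """Evaluate all reaction rates at ``state`` (reference Python path)."""
        if state.n != self.n:
            raise ValueError(f"state has {state.n} genotypes, system expects {self.n}")
        if np.any(state.H < 0) or np.any(state.P < 0):
            raise ValueError("corrupted state: negative genotype count")
        return np.array([r.propensity(state) for r in self.reactions], dtype=float)

    def drift(self, state: PopulationState) -> tuple[np.ndarray, np.ndarray]:
        """Mean-field drift ``(dH/dt, dP/dt)`` = sum of rate * stoichiometry."""
        a = self.propensities(state)
        return a @ self.delta_H, a @ self.delta_P


def _unit(n: int, i: int, sign: int) -> np.ndarray:
    v = np.zeros(n, dtype=np.int64)
    v[i] = sign
    return v


def _zero(n: int) -> np.ndarray:
    return np.zeros(n, dtype=np.int64)


def evo_replacement_rates(state: PopulationState, params: ModelParams, moran: bool) -> np.ndarray:
    """The four Evo(+) replacement rates [H1<-2, H2<-1, P1<-2, P2<-1].

    ``moran=True`` gives the Moran normalisation ``f_i / f_mean`` (EvoPlus);
    ``moran=False`` the pairwise-comparison form
    ``0.5 + 0.5 (f_i - f_j) / (w (alpha - beta))`` (Evo).  Used both as
    one-step transition weights by the discrete-time processes and as
    reaction rates by the continuous-time ones.
    """
    A = build_matching_matrix(2, params.alpha, params.beta)
    rates = np.zeros(4)
    if state.N_H == 0 or state.N_P == 0:
        return rates
    h, p = state.h, state.p
    for block, (x, w, payoff_of) in enumerate(
        [(h, params.w_H, lambda: host_payoffs(p, A)), (p, params.w_P, lambda: parasite_payoffs(h, A))]
    ):
        prod = x[0] * x[1]
        if prod == 0.0:
            continue
        f = fitness_from_payoff(payoff_of(), w)
        if moran:
            fbar = x @ f
            up, down = prod * f[0] / fbar, prod * f[1] / fbar
        else:
            span = w * (params.alpha - params.beta)
            g = 0.5 if span == 0.0 else 0.5 + 0.5 * (f[0] - f[1]) / span
            up, down = prod * g, prod * (1.0 - g)
        rates[2 * block] = up
        rates[2 * block + 1] = down
    return rates


def hybrid_per_capita(state: PopulationState, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Hybrid per-capita host death rates ``d_H,i`` and parasite birth rates ``b_P,i``.

    ``d_H,i = 1 - w_H + w_H (sum_j A_ij P_j) / N_P`` — a host dies faster
    when matching parasites are common; symmetrically the parasite is born
    faster when matching hosts are common.
    """
    a, b = params.alpha, params.beta
    N_H, N_P = state.N_H, state.N_P
    if N_P > 0:
        match_H = (b * N_P + (a - b) * state.P) / N_P
    else:
        match_H = np.zeros(state.n)
    if N_H > 0:
        match_P = (b * N_H + (a - b) * state.H) / N_H
    else:
        match_P = np.zeros(state.n)
    d_H = 1.0 - params.w_H + params.w_H * match_H
    b_P = 1.0 - params.w_P + params.w_P * match_P
    return d_H, b_P


def _mutation_reactions(n: int, params: ModelParams) -> list[Reaction]:
    out: list[Reaction] = []
    for species, rate in (("H", params.mut_H), ("P", params.mut_P)):
        for step in (+1, -1):
            for i in range(n):
                j = (i + step) % n
                dH = _unit(n, i, -1) + _unit(n, j, +1) if species == "H" else _zero(n)
                dP = _unit(n, i, -1) + _unit(n, j, +1) if species == "P" else _zero(n)

                def prop(state, i=i, rate=rate, species=species):
                    x = state.H if species == "H" else state.P
                    return 0.5 * rate * x[i]

                out.append(Reaction(f"mut_{species}{i + 1}->{species}{j + 1}", dH, dP, prop))
    return out


def build_model(
    name: str, n: int, params: ModelParams, with_mutation: bool = False
) -> ReactionSystem:
    """Build one of the five continuous-time models as a reaction system.

    ``n`` is the genotype count per species; the constant-size game
    models (``Evo``, ``EvoPlus``) support ``n = 2`` only and no
    mutation.  Reaction ordering is fixed and documented per model.
    """
    if name not in MODEL_NAMES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    if n < 2:
        raise ValueError(f"need at least 2 genotypes, got n={n}")
    reactions: list[Reaction] = []
    conserves = False

    if name in ("EvoPlus", "Evo"):
        if n != 2:
            raise ValueError(f"{name} supports exactly 2 genotypes, got n={n}")
        if with_mutation:
            raise ValueError(f"mutation is not supported for the constant-size {name} model")
        moran = name == "EvoPlus"
        deltas = [
            ("host_repl_1<-2", np.array([1, -1]), _zero(2)),
            ("host_repl_2<-1", np.array([-1, 1]), _zero(2)),
            ("par_repl_1<-2", _zero(2), np.array([1, -1])),
            ("par_repl_2<-1", _zero(2), np.array([-1, 1])),
        ]
        for k, (label, dH, dP) in enumerate(deltas):
            def prop(state, k=k, moran=moran):
                return evo_replacement_rates(state, params, moran)[k]

            reactions.append(Reaction(label, dH.astype(np.int64), dP.astype(np.int64), prop))
        conserves = True

    elif name == "Hybrid":
        def d_host(state, i):
            return state.H[i] * hybrid_per_capita(state, params)[0][i]

        def b_host(state, i):
            if state.N_H == 0:
                return 0.0
            d_H, _ = hybrid_per_capita(state, params)
            return state.H[i] * float(state.H @ d_H) / state.N_H

        def b_par(state, i):
            return state.P[i] * hybrid_per_capita(state, params)[1][i]

        def d_par(state, i):
            if state.N_P == 0:
                return 0.0
            _, b_P = hybrid_per_capita(state, params)
            return state.P[i] * float(state.P @ b_P) / state.N_P

        for i in range(n):
            reactions.append(
                Reaction(f"host_death_{i + 1}", _unit(n, i, -1), _zero(n), lambda s, i=i: d_host(s, i))
            )
        for i in range(n):
            reactions.append(
                Reaction(f"host_birth_{i + 1}", _unit(n, i, +1), _zero(n), lambda s, i=i: b_host(s, i))
            )
        for i in range(n):
            reactions.append(
                Reaction(f"par_birth_{i + 1}", _zero(n), _unit(n, i, +1), lambda s, i=i: b_par(s, i))
            )
        for i in range(n):
            reactions.append(
                Reaction(f"par_death_{i + 1}", _zero(n), _unit(n, i, -1), lambda s, i=i: d_par(s, i))
            )

    elif name in ("EcoEvo", "EcoEvoPlus"):
        lam = params.lam
        if lam is None:
            raise ValueError("ecological models need an interaction rate lam (or lam0 with K)")
        for i in range(n):
            reactions.append(
                Reaction(
                    f"host_birth_{i + 1}",
                    _unit(n, i, +1),
                    _zero(n),
                    lambda s, i=i: params.b_H * s.H[i],
                )
            )
        for i in range(n):
            reactions.append(
                Reaction(
                    f"par_death_{i + 1}",
                    _zero(n),
                    _unit(n, i, -1),
                    lambda s, i=i: params.d_P * s.P[i],
                )
            )
        for i in range(n):
            reactions.append(
                Reaction(
                    f"match_host_death_{i + 1}",
                    _unit(n, i, -1),
                    _zero(n),
                    lambda s, i=i: lam * s.H[i] * s.P[i],
                )
            )
        for i in range(n):
            reactions.append(
                Reaction(
                    f"match_par_birth_{i + 1}",
                    _zero(n),
                    _unit(n, i, +1),
                    lambda s, i=i: lam * s.H[i] * s.P[i],
                )
            )
        if name == "EcoEvoPlus":
            comp = params.comp_rate
            if not comp:
                raise ValueError("EcoEvoPlus needs comp_rate > 0 (or K with b_H)")
            for i in range(n):
                reactions.append(
                    Reaction(
                        f"comp_death_{i + 1}",
                        _unit(n, i, -1),
                        _zero(n),
                        lambda s, i=i: comp * s.H[i] * s.H.sum(),
                    )
                )

    if with_mutation:
        if name in ("EvoPlus", "Evo"):  # pragma: no cover - guarded above
            raise ValueError("mutation unsupported for constant-size models")
        reactions.extend(_mutation_reactions(n, params))

    return ReactionSystem(
        name=name,
        n=n,
        reactions=reactions,
        params=params,
        model_code=MODEL_CODES[name],
        with_mutation=with_mutation,
        conserves_sizes=conserves,
    )
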