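"""Matching-allele interactions, payoffs and fitness.

All five host-parasite models share the same symmetric matching-allele
game: a parasite of genotype *i* gains ``alpha`` from encountering a host
of the same genotype and ``beta`` from any other genotype.  Hosts lose
what parasites gain (zero-sum), so the host payoff is the complement
``(alpha + beta) - sum_j A[i, j] * p_j``, which keeps fitness values in
``[1 - w, 1 + w*(alpha+beta)]`` and reduces, for two genotypes with
``alpha=1, beta=0``, to the familiar ``pi_H1 = p_2``.

Payoffs are mapped to reproductive fitness through the selection
intensity ``w``: ``f = 1 - w + w * pi``; ``w = 0`` is neutral evolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InteractionMatrix",
    "build_matching_matrix",
    "parasite_payoffs",
    "host_payoffs",
    "fitness_from_payoff",
    "check_frequencies",
]

#: tolerance on frequency-vector normalisation
FREQ_TOL = 1e-12


@dataclass(frozen=True)
class InteractionMatrix:
    """Matching-allele payoff matrix: ``alpha`` on the diagonal, ``beta`` off it."""

    n: int
    alpha: float
    beta: float

    @property
    def entries(self) -> np.ndarray:
        A = np.full((self.n, self.n), self.beta, dtype=float)
        np.fill_diagonal(A, self.alpha)
        return A


def build_matching_matrix(n: int, alpha: float, beta: float) -> InteractionMatrix:
    """Build an ``n``-genotype matching-allele interaction matrix.

    Parameters
    ----------
    n : int
        Number of genotypes per species (>= 2).
    alpha : float
        Payoff of a matching host-parasite pair (gain for the parasite,
        loss for the host).
    beta : float
        Payoff of a mismatching pair.  Must satisfy ``alpha >= beta`` so
        that the pairwise-comparison normalisation ``alpha - beta`` is
        non-negative.
    """
    if n < 2:
        raise ValueError(f"need at least 2 genotypes, got n={n}")
    if alpha < beta:
        raise ValueError(f"alpha ({alpha}) must be >= beta ({beta})")
    return InteractionMatrix(n=int(n), alpha=float(alpha), beta=float(beta))


def check_frequencies(x: np.ndarray, name: str = "frequencies") -> np.ndarray:
    """Validate a relative-abundance vector (entries in [0,1], sum 1)."""
    x = np.asarray(x, dtype=float)
    if np.any(x < -FREQ_TOL) or np.any(x > 1 + FREQ_TOL):
        raise ValueError(f"{name} must lie in [0, 1]: {x}")
    if abs(x.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} must sum to 1, got {x.sum()!r}")
    return x


def parasite_payoffs(h: np.ndarray, A: InteractionMatrix) -> np.ndarray:
    """Per-genotype parasite payoff ``pi_P,i = sum_j A[i,j] h_j``.

    ``h`` are the host genotype frequencies: a parasite genotype does well
    when the hosts it matches are common.
    """
    h = check_frequencies(h, "host frequencies")
    if h.shape[0] != A.n:
        raise ValueError(f"dimension mismatch: {h.shape[0]} frequencies vs n={A.n}")
    # A @ h with the matching-allele structure: beta + (alpha - beta) * h_i
    return A.beta + (A.alpha - A.beta) * h


def host_payoffs(p: np.ndarray, A: InteractionMatrix) -> np.ndarray:
    """Per-genotype host payoff, zero-sum complement of the parasite's.

    ``pi_H,i = (alpha + beta) - sum_j A[i,j] p_j``: a host genotype does
    poorly when the parasites matching it are common.  For ``alpha=1,
    beta=0`` and two genotypes this is ``pi_H1 = p_2``.
    """
    p = check_frequencies(p, "parasite frequencies")
    if p.shape[0] != A.n:
        raise ValueError(f"dimension mismatch: {p.shape[0]} frequencies vs n={A.n}")
    return (A.alpha + A.beta) - (A.beta + (A.alpha - A.beta) * p)


def fitness_from_payoff(pi: np.ndarray, w: float) -> np.ndarray:
    """Map payoffs to fitness: ``f_i = 1 - w + w * pi_i``.

    ``w`` in [0, 1] is the selection intensity; ``w = 0`` gives neutral
    (all-ones) fitness.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"selection intensity w must be in [0, 1], got {w}")
    return 1.0 - w + w * np.asarray(pi, dtype=float)
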