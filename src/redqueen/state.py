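"""Shared state containers for the stochastic processes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PopulationState", "ExtinctionRecord"]


@dataclass
class PopulationState:
    """Integer genotype abundances of host and parasite at time ``t``.

    ``H[i]`` and ``P[i]`` count individuals of genotype ``i``; ``N_H``
    and ``N_P`` are the species totals.
    """

    H: np.ndarray
    P: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=np.int64)
        self.P = np.asarray(self.P, dtype=np.int64)
        if self.H.ndim != 1 or self.P.ndim != 1:
            raise ValueError("H and P must be 1-D count vectors")
        if self.H.shape != self.P.shape:
            raise ValueError("host and parasite must have the same genotype count")
        if np.any(self.H < 0) or np.any(self.P < 0):
            raise ValueError("genotype counts must be non-negative")

    @property
    def n(self) -> int:
        return self.H.shape[0]

    @property
    def N_H(self) -> int:
        return int(self.H.sum())

    @property
    def N_P(self) -> int:
        return int(self.P.sum())

    @property
    def h(self) -> np.ndarray:
        """Host genotype frequencies (requires N_H > 0)."""
        return self.H / self.H.sum()

    @property
    def p(self) -> np.ndarray:
        """Parasite genotype frequencies (requires N_P > 0)."""
        return self.P / self.P.sum()

    def copy(self) -> "PopulationState":
        return PopulationState(self.H.copy(), self.P.copy(), self.t)


@dataclass(frozen=True)
class ExtinctionRecord:
    """First loss of a genotype from either species.

    ``time`` is in model time units (steps for the discrete-time
    processes).  ``censored`` records that a stopping cap was reached
    before any genotype was lost; censored records carry the cap time
    and no species/genotype index.
    """

    time: float
    species: str | None = None  # "host" | "parasite"
    genotype: int | None = None
    censored: bool = False

    def __post_init__(self) -> None:
        if self.censored:
            if self.species is not None or self.genotype is not None:
                raise ValueError("censored records carry no species/genotype")
        else:
            if self.species not in ("host", "parasite"):
                raise ValueError(f"species must be 'host' or 'parasite', got {self.species!r}")
            if self.genotype is None or self.genotype < 0:
                raise ValueError("uncensored records need a genotype index")
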