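"""Reversible nucleotide substitution models (JC69, K80, HKY85, GTR).

Rate matrices are normalized to one expected substitution per unit
branch length.  Transition probabilities are computed from the
eigendecomposition of the symmetrized rate matrix; discrete-gamma rate
heterogeneity uses k mean-category rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

BASES = "ACGT"

# IUPAC ambiguity codes -> compatible state vectors; gaps fully missing
AMBIGUITY: dict[str, tuple[float, float, float, float]] = {}
_iupac = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT", "?": "ACGT", ".": "ACGT", "X": "ACGT",
}
for code, states in _iupac.items():
    AMBIGUITY[code] = tuple(1.0 if b in states else 0.0 for b in BASES)


def _gamma_category_rates(alpha: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability categories of Gamma(alpha, alpha)."""
    cuts = gamma_dist.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha)
    edges = np.concatenate([[0.0], cuts, [np.inf]])
    # E[X | a < X < b] for Gamma(alpha, 1/alpha) via the incomplete gamma fn
    upper = gammainc(alpha + 1, edges[1:] * alpha)
    lower = gammainc(alpha + 1, edges[:-1] * alpha)
    rates = (upper - lower) * k
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """A time-reversible 4-state model with optional gamma heterogeneity."""

    family: str
    freqs: np.ndarray
    exchangeabilities: np.ndarray  # 6 upper-triangle entries AC,AG,AT,CG,CT,GT
    gamma_alpha: Optional[float] = None
    gamma_categories: int = 4
    _eig: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.exchangeabilities = np.asarray(self.exchangeabilities, float)
        if self.freqs.shape != (4,) or not np.all(self.freqs > 0):
            raise ValueError("frequencies must be 4 strictly positive values")
        if abs(self.freqs.sum() - 1.0) > 1e-8:
            raise ValueError("frequencies must sum to 1")
        if self.exchangeabilities.shape != (6,) or np.any(
                self.exchangeabilities <= 0):
            raise ValueError("exchangeabilities must be 6 positive values")
        if self.gamma_alpha is not None and self.gamma_alpha <= 0:
            raise ValueError("gamma shape must be positive")

    # ------------------------------------------------------------------
    @classmethod
    def jc69(cls, **kw) -> "SubstitutionModel":
        return cls("JC69", np.full(4, 0.25), np.ones(6), **kw)

    @classmethod
    def k80(cls, kappa: float = 2.0, **kw) -> "SubstitutionModel":
        ex = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        return cls("K80", np.full(4, 0.25), ex, **kw)

    @classmethod
    def hky85(cls, freqs, kappa: float = 2.0, **kw) -> "SubstitutionModel":
        ex = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        return cls("HKY85", np.asarray(freqs, float), ex, **kw)

    @classmethod
    def gtr(cls, freqs, exchangeabilities, **kw) -> "SubstitutionModel":
        return cls("GTR", np.asarray(freqs, float),
                   np.asarray(exchangeabilities, float), **kw)

    # ------------------------------------------------------------------
    def rate_matrix(self) -> np.ndarray:
        """Normalized rate matrix Q (rows sum to 0, mean rate 1)."""
        s = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        s[iu] = self.exchangeabilities
        s += s.T
        q = s * self.freqs[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.dot(self.freqs, np.diag(q))
        return q / mu

    def _eigendecomposition(self):
        if self._eig is None:
            q = self.rate_matrix()
            sq = np.sqrt(self.freqs)
            sym = (sq[:, None] * q) / sq[None, :]
            vals, vecs = np.linalg.eigh((sym + sym.T) / 2.0)
            left = vecs.T * sq[None, :]       # rows: v^T diag(sqrt pi)
            right = vecs / sq[:, None]        # diag(1/sqrt pi) v
            object.__setattr__(self, "_eig", (vals, right, left))
        return self._eig

    def jc_probabilities(self, t: float) -> tuple[float, float]:
        """JC69 closed form: (P[same], P[different]) at distance t."""
        e = np.exp(-4.0 * t / 3.0)
        return 0.25 + 0.75 * e, 0.25 - 0.25 * e

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        if self.family == "JC69":
            same, diff = self.jc_probabilities(t)
            p = np.full((4, 4), diff)
            np.fill_diagonal(p, same)
            return p
        vals, right, left = self._eigendecomposition()
        p = (right * np.exp(vals * t)[None, :]) @ left
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=1, keepdims=True)

    def category_rates(self) -> np.ndarray:
        if self.gamma_alpha is None:
            return np.ones(1)
        return _gamma_category_rates(self.gamma_alpha, self.gamma_categories)

    def n_free_parameters(self) -> int:
        base = {"JC69": 0, "K80": 1, "HKY85": 4, "GTR": 8}[self.family]
        return base + (1 if self.gamma_alpha is not None else 0)
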