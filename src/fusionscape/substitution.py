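"""HKY85 substitution model: rate matrix, transition probabilities, gamma rates.

The HKY model allows unequal base frequencies and a transition/transversion
rate ratio kappa; rate heterogeneity across sites is approximated by a
discrete gamma with equal-probability categories (category rate = mean of its
quantile bin, normalized to mean 1).  Bases are encoded A=0, C=1, G=2, T=3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_PURINES = (0, 2)  # A, G
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


@dataclass(frozen=True)
class HkyParams:
    """Parameters of the HKY85 model.

    kappa is the transition/transversion *rate* ratio; ``gamma_shape=None``
    means rate homogeneity across sites.
    """

    kappa: float = 4.0
    base_freqs: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    gamma_shape: float | None = None
    n_rate_categories: int = 4

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.shape != (4,) or np.any(freqs < 0):
            raise ValueError("base_freqs must be 4 nonnegative values")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("base_freqs must sum to 1 within 1e-9")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        if self.n_rate_categories < 1:
            raise ValueError("need at least one rate category")

    @property
    def freqs(self) -> np.ndarray:
        return np.asarray(self.base_freqs, dtype=float)

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None or np.isinf(self.gamma_shape):
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_rate_categories)


def discrete_gamma_rates(shape: float, ncat: int) -> np.ndarray:
    """Equal-probability discrete gamma category rates, normalized to mean 1.

    Category rate = conditional mean of a Gamma(shape, mean 1) variable within
    its quantile bin.
    """
    if ncat == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.linspace(0, 1, ncat + 1), a=shape, scale=1.0 / shape)
    # E[X * 1{X < c}] for X ~ Gamma(a, scale=1/a) equals P(a+1, a*c) since E[X]=1
    mass = gammainc(shape + 1, shape * edges)
    mass[0], mass[-1] = 0.0, 1.0
    rates = np.diff(mass) * ncat
    return rates / rates.mean()


def hky_rate_matrix(kappa: float, freqs: np.ndarray) -> np.ndarray:
    """HKY instantaneous rate matrix, scaled to one expected substitution/site."""
    freqs = np.asarray(freqs, dtype=float)
    q = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            rate = freqs[j]
            if (i in _PURINES) == (j in _PURINES):  # transition
                rate *= kappa
            q[i, j] = rate
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -(freqs * np.diag(q)).sum()
    return q / mean_rate


def hky_eigen(kappa: float, freqs: np.ndarray):
    """Eigendecomposition of the HKY rate matrix via the GTR symmetrization.

    Returns ``(left, lam, right)`` with ``P(t) = left @ diag(exp(lam*t)) @ right``.
    """
    freqs = np.asarray(freqs, dtype=float)
    q = hky_rate_matrix(kappa, freqs)
    sqrt_pi = np.sqrt(freqs)
    sym = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
    lam, u = np.linalg.eigh((sym + sym.T) / 2)
    left = u / sqrt_pi[:, None]
    right = u.T * sqrt_pi[None, :]
    return left, lam, right


class HkyModel:
    """Cached transition-probability engine for fixed HKY parameters."""

    def __init__(self, params: HkyParams):
        self.params = params
        self.freqs = params.freqs
        self._left, self._lam, self._right = hky_eigen(params.kappa, self.freqs)

    def transition_matrices(self, t) -> np.ndarray:
        """P(t) for an array of branch lengths; output shape ``t.shape + (4, 4)``."""
        t = np.asarray(t, dtype=float)
        expo = np.exp(self._lam * t[..., None])  # (..., 4)
        p = np.einsum("ik,...k,kj->...ij", self._left, expo, self._right)
        return np.clip(p, 0.0, 1.0)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string to int8 codes; anything else becomes -1."""
    table = np.full(256, -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        table[ord(base)] = idx
        table[ord(base.lower())] = idx
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    lookup = np.frombuffer(ALPHABET.encode("ascii"), dtype=np.uint8)
    return lookup[np.asarray(codes, dtype=np.int64)].tobytes().decode("ascii")


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMPLEMENT[codes]


def reverse_complement(seq: str) -> str:
    return decode_sequence(complement_codes(encode_sequence(seq))[::-1])
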