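"""Windowed nucleotide diversity and Tajima's D from first principles.

Per window, pi is the unbiased per-site heterozygosity summed over sites,

    pi = sum_sites 2 p (1-p) n/(n-1) / window_len,

equivalent to the mean number of pairwise differences per site over all
haplotype pairs.  Tajima's D contrasts pi (as a total over the window) with
Watterson's estimator S/a1, standardized by the usual variance constants;
it is reported as NaN (not 0) when a window has no segregating sites.

Missing genotypes are handled site-wise (complete-case n per site); the
variance constants use the panel's haplotype count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .formats import GenomicInterval, VariantMatrix, MISSING

__all__ = ["DiversityWindow", "tajima_constants", "pi_windows", "tajima_d_windows"]


@dataclass
class DiversityWindow:
    interval: GenomicInterval
    n_haplotypes: int
    S: int
    pi: float  # per site
    tajima_d: float  # NaN when S == 0

    def __post_init__(self):
        if self.pi < 0 or self.S < 0:
            raise ValueError("pi and S must be nonnegative")
        # D is undefined exactly when there are no segregating sites, or when
        # the variance constants vanish: e1 = e2 = 0 identically at n = 3,
        # and n = 2 has no variance constants at all
        undefined = self.S == 0 or self.n_haplotypes < 4
        if undefined != math.isnan(self.tajima_d):
            raise ValueError("tajima_d must be NaN exactly when S == 0 (or n < 4)")


def tajima_constants(n: int) -> dict:
    """The a1..e2 constants of Tajima's variance normalization."""
    if n < 3:
        raise ValueError("Tajima's D needs at least 3 haplotypes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def _site_stats(vm: VariantMatrix, cols: np.ndarray):
    """Per-site (n_eff, alt count) with site-wise complete cases."""
    g = vm.genotypes[:, cols]
    present = g != MISSING
    n_eff = present.sum(axis=0)
    alt = np.where(present, g, 0).sum(axis=0)
    return n_eff, alt


def _windows(region: GenomicInterval, window: int, step: int):
    start = region.start
    while start < region.end:
        yield GenomicInterval(region.seq_name, start, min(start + window, region.end))
        start += step


def _pairwise_total(n_eff, alt) -> float:
    """Sum over sites of the unbiased mean pairwise difference."""
    ok = n_eff >= 2
    n = n_eff[ok].astype(float)
    a = alt[ok].astype(float)
    p = a / n
    return float(np.sum(2.0 * p * (1.0 - p) * n / (n - 1.0)))


def pi_windows(
    vm: VariantMatrix,
    region: GenomicInterval,
    window: int = 20_000,
    step: int = 10_000,
) -> list[DiversityWindow]:
    """Sliding-window nucleotide diversity (per site)."""
    if vm.n_haplotypes < 2:
        raise ValueError("need at least two haplotypes")
    out = []
    for iv in _windows(region, window, step):
        cols = np.flatnonzero((vm.positions >= iv.start) & (vm.positions < iv.end))
        n_eff, alt = _site_stats(vm, cols)
        seg = int(np.sum((alt > 0) & (alt < n_eff)))
        pi = _pairwise_total(n_eff, alt) / iv.length()
        if seg == 0 or vm.n_haplotypes < 4:
            d = float("nan")
        else:
            d = _tajima_d(vm.n_haplotypes, seg, n_eff, alt)
        out.append(
            DiversityWindow(iv, vm.n_haplotypes, seg, pi, d)
        )
    return out


def _tajima_d(n: int, S: int, n_eff, alt) -> float:
    k = tajima_constants(n)
    pi_total = _pairwise_total(n_eff, alt)
    theta_w = S / k["a1"]
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return float((pi_total - theta_w) / math.sqrt(var))


def tajima_d_windows(
    vm: VariantMatrix,
    region: GenomicInterval,
    window: int = 20_000,
) -> list[DiversityWindow]:
    """Non-overlapping-window Tajima's D (NaN where S=0)."""
    if vm.n_haplotypes < 4:
        raise ValueError(
            "Tajima's D needs at least 4 haplotypes (e1 = e2 = 0 at n = 3)"
        )
    return pi_windows(vm, region, window=window, step=window)
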