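"""Singly unique nucleotide k-mers (SUNKs).

A SUNK is a k-mer that occurs exactly once in every genome of a reference
panel (and, optionally, never in a set of non-panel genomes).  SUNKs act as
presence markers: the fraction of a region's SUNKs found in a query genome
measures whether the region predates the query lineage's divergence.

K-mers are canonicalized (lexicographic minimum of the k-mer and its reverse
complement); k must be odd so no k-mer is its own reverse complement.
Censuses are held in memory, sized for region-scale analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .substitution import decode_sequence, encode_sequence, reverse_complement

__all__ = [
    "KmerCensus",
    "SunkReport",
    "canonical_kmer",
    "build_census",
    "identify_sunks",
    "query_presence",
]


def canonical_kmer(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerCensus:
    """Canonical k-mer -> occurrence count for one assembly."""

    k: int
    counts: dict = field(default_factory=dict)
    canonical: bool = True

    def __post_init__(self):
        if self.k % 2 == 0:
            raise ValueError("k must be odd")

    def get(self, kmer: str, default: int = 0) -> int:
        return self.counts.get(kmer, default)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.counts

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def total_mass(self) -> int:
        """Total number of counted windows (sum over stored k-mers)."""
        return int(sum(self.counts.values()))


@dataclass
class SunkReport:
    n_total: int
    n_detected: int
    presence: dict  # canonical k-mer -> bool

    @property
    def fraction(self) -> float:
        return self.n_detected / self.n_total

    @property
    def percent(self) -> float:
        """Presence fraction as a percentage, to one decimal place."""
        return round(100.0 * self.fraction, 1)


def _kmer_values(seq: str, k: int):
    """Canonical integer codes of all N-free k-length windows (2-bit packed)."""
    codes = encode_sequence(seq).astype(np.int64)
    n = len(codes) - k + 1
    if n <= 0:
        return np.array([], dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    bad = (codes < 0).astype(np.int64)
    bad_cum = np.concatenate([[0], np.cumsum(bad)])
    valid = (bad_cum[k:] - bad_cum[:-k]) == 0
    powers_fwd = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    powers_rev = 4 ** np.arange(k, dtype=np.int64)
    fwd = windows @ powers_fwd
    rev = (3 - windows) @ powers_rev  # value of the reverse complement
    return np.minimum(fwd, rev)[valid]


def _decode_value(value: int, k: int) -> str:
    digits = np.empty(k, dtype=np.int64)
    for i in range(k - 1, -1, -1):
        digits[i] = value & 3
        value >>= 2
    return decode_sequence(digits)


def build_census(sequences, k: int = 31):
    """Count canonical k-mers.

    ``sequences`` may be a single sequence string (returns one
    :class:`KmerCensus`) or a mapping of assembly name -> sequence (returns a
    mapping of name -> census).  Windows containing non-ACGT characters are
    skipped.
    """
    if k % 2 == 0 or not 11 <= k <= 63:
        raise ValueError("k must be odd and within [11, 63]")
    if isinstance(sequences, dict):
        return {name: build_census(seq, k=k) for name, seq in sequences.items()}
    seq = sequences
    if k > 31:  # 2-bit packing overflows int64 beyond k=31
        counts: dict[str, int] = {}
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k].upper()
            if any(b not in "ACGT" for b in km):
                continue
            km = canonical_kmer(km)
            counts[km] = counts.get(km, 0) + 1
        return KmerCensus(k=k, counts=counts)
    values = _kmer_values(seq, k)
    uniq, cnt = np.unique(values, return_counts=True)
    counts = {_decode_value(int(v), k): int(c) for v, c in zip(uniq, cnt)}
    return KmerCensus(k=k, counts=counts)


def identify_sunks(
    target, panel_censuses, nhp_censuses=(), require_nhp_absence: bool = True
) -> set[str]:
    """SUNKs of the target region with respect to a panel of censuses.

    A target k-mer qualifies when its count is exactly 1 in every panel
    census and (when ``require_nhp_absence``) 0 in every non-panel census.
    ``target`` is a sequence string or a census built from one.
    """
    panel = list(panel_censuses.values()) if isinstance(panel_censuses, dict) else list(panel_censuses)
    if not panel:
        raise ValueError("need at least one panel census")
    k = panel[0].k
    if any(c.k != k for c in panel):
        raise ValueError("panel censuses disagree on k")
    target_census = target if isinstance(target, KmerCensus) else build_census(target, k=k)
    out: set[str] = set()
    nhp = (
        list(nhp_censuses.values()) if isinstance(nhp_censuses, dict) else list(nhp_censuses)
    ) if require_nhp_absence else []
    for kmer in target_census.counts:
        if all(c.get(kmer) == 1 for c in panel) and all(c.get(kmer) == 0 for c in nhp):
            out.add(kmer)
    return out


def query_presence(sunks, query) -> SunkReport:
    """Which SUNKs occur (>= once, canonical) in the query sequence."""
    sunks = set(sunks)
    if not sunks:
        raise ValueError("empty SUNK set")
    k = len(next(iter(sunks)))
    census = query if isinstance(query, KmerCensus) else build_census(query, k=k)
    presence = {km: census.get(km) > 0 for km in sorted(sunks)}
    return SunkReport(
        n_total=len(sunks),
        n_detected=int(sum(presence.values())),
        presence=presence,
    )
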