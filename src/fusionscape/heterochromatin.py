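"""Satellite/spacer architecture, telomeric motifs, methylation and CDRs.

Pericentromeric heterochromatin here is modelled as long tandem satellite
arrays (a short AT-rich monomer, e.g. 32 bp) punctuated by non-satellite
spacer segments.  This module detects the arrays by period autocorrelation
plus consensus-monomer matching, summarizes the spacer architecture
(spacing between spacers, modal spacer length), scans for tandem telomeric
motifs on both strands, computes windowed methylation from site-level
tracks, calls centromere dip regions (CDRs: runs of below-lower-quartile
windows anchored at a methylation minimum), compares methylation between
region groups with a Mann-Whitney U test on chunk means, and classifies
structural haplotypes from per-sample satellite-array lengths by 1-D
gap clustering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

from .formats import GenomicInterval, MethylTrack
from .substitution import reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "ArrayAnnotation",
    "TelomericRun",
    "CdrCall",
    "HaplotypeClassification",
    "detect_satellite_arrays",
    "spacer_stats",
    "detect_telomeric_repeats",
    "windowed_methylation",
    "call_cdrs",
    "compare_methylation_groups",
    "classify_structural_haplotypes",
]


@dataclass
class ArrayAnnotation:
    """Labeled partition of a scanned sequence into satellite/spacer/other."""

    intervals: list  # GenomicInterval with .name in {satellite, spacer, other}
    monomer_period: int
    array_lengths: list = field(default_factory=list)

    def __post_init__(self):
        ivs = sorted(self.intervals, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if a.end > b.start:
                raise ValueError("annotation intervals must not overlap")
        for iv in self.intervals:
            if iv.name not in ("satellite", "spacer", "other"):
                raise ValueError(f"unknown label {iv.name!r}")

    def by_label(self, label: str) -> list:
        return sorted(
            (iv for iv in self.intervals if iv.name == label),
            key=lambda iv: iv.start,
        )


def _consensus_monomer(seq: str, start: int, end: int, m: int) -> str:
    """Majority base per position over the monomer-aligned slices of [start,end)."""
    arr = np.frombuffer(
        seq[start : start + ((end - start) // m) * m].encode(), dtype="S1"
    ).reshape(-1, m)
    cons = []
    for col in arr.T:
        values, counts = np.unique(col, return_counts=True)
        cons.append(values[np.argmax(counts)].decode())
    return "".join(cons)


def _monomer_divergence(seq: str, pos: int, consensus: str) -> float:
    m = len(consensus)
    chunk = seq[pos : pos + m]
    if len(chunk) < m:
        return 1.0
    return sum(a != b for a, b in zip(chunk, consensus)) / m


def detect_satellite_arrays(
    seq: str,
    monomer_len: int = 32,
    min_array: int = 5,
    max_divergence: float = 0.15,
    seq_name: str = "seq",
) -> ArrayAnnotation:
    """Detect tandem satellite arrays of a given monomer period.

    Candidate regions come from the lag-``monomer_len`` autocorrelation of
    the sequence (fraction of positions matching the base one period ahead,
    averaged over ``min_array`` monomers); each candidate is refined by
    building a consensus monomer and taking the maximal run of consecutive
    monomer-length slots within ``max_divergence`` of it.  Gaps between
    consecutive arrays are labeled ``spacer``; sequence before the first
    and after the last array is ``other``.
    """
    m = monomer_len
    span = min_array * m
    if len(seq) < span:
        raise ValueError("sequence shorter than min_array monomers")
    if not 0.0 <= max_divergence < 0.5:
        raise ValueError("max_divergence must be in [0, 0.5)")
    s = np.frombuffer(seq.encode(), dtype="S1")
    match = (s[:-m] == s[m:]).astype(float)
    # windowed mean of the period-match signal
    cum = np.concatenate([[0.0], np.cumsum(match)])
    win = (cum[span:] - cum[:-span]) / span
    # matched tandem copies agree except at mutated sites: expect ~1 - 2q
    threshold = 1.0 - 2.0 * max_divergence
    hot = win >= threshold
    # merge hot window starts into candidate regions
    candidates = []
    i = 0
    while i < len(hot):
        if hot[i]:
            j = i
            while j < len(hot) and hot[j]:
                j += 1
            candidates.append((i, min(len(seq), j - 1 + span + m)))
            i = j
        else:
            i += 1
    arrays = []
    for c_start, c_end in candidates:
        consensus = _consensus_monomer(seq, c_start, c_end, m)
        # evaluate monomer slots on the candidate's phase, slightly beyond
        # its edges; the array spans first..last matching monomer (isolated
        # divergent monomers inside the array are tolerated)
        first = max(0, c_start - span)
        phase_start = first + (c_start - first) % m
        last_limit = min(len(seq), c_end + span)
        matches = [
            p
            for p in range(phase_start, last_limit - m + 1, m)
            if _monomer_divergence(seq, p, consensus) <= max_divergence
        ]
        if len(matches) >= min_array:
            arrays.append((matches[0], matches[-1] + m))
    # merge overlapping arrays found from adjacent candidates
    arrays.sort()
    merged = []
    for a_start, a_end in arrays:
        if merged and a_start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], a_end)
        else:
            merged.append([a_start, a_end])
    intervals = []
    prev_end = None
    for a_start, a_end in merged:
        if prev_end is None:
            if a_start > 0:
                intervals.append(
                    GenomicInterval(seq_name, 0, a_start, name="other")
                )
        elif a_start > prev_end:
            intervals.append(
                GenomicInterval(seq_name, prev_end, a_start, name="spacer")
            )
        intervals.append(
            GenomicInterval(seq_name, a_start, a_end, name="satellite")
        )
        prev_end = a_end
    if prev_end is not None and prev_end < len(seq):
        intervals.append(
            GenomicInterval(seq_name, prev_end, len(seq), name="other")
        )
    return ArrayAnnotation(
        intervals=intervals,
        monomer_period=m,
        array_lengths=[e - s_ for s_, e in merged],
    )


def spacer_stats(annotation: ArrayAnnotation, length_bin: int = 1_000) -> dict:
    """Spacer architecture summary.

    Returns ``mean_spacing`` (mean distance between consecutive spacer
    midpoints; NaN with fewer than 2 spacers), ``modal_length`` (spacer
    length histogram mode, reported at ``length_bin`` granularity) and
    ``n_spacers``.
    """
    spacers = annotation.by_label("spacer")
    if not spacers:
        raise ValueError("annotation contains no spacers")
    mids = np.array([iv.midpoint for iv in spacers])
    if len(spacers) >= 2:
        mean_spacing = float(np.mean(np.diff(mids)))
    else:
        logger.warning("only one spacer; mean spacing undefined")
        mean_spacing = float("nan")
    lengths = np.array([iv.length() for iv in spacers])
    bins = np.round(lengths / length_bin).astype(int)
    values, counts = np.unique(bins, return_counts=True)
    modal = float(values[np.argmax(counts)] * length_bin)
    return {
        "mean_spacing": mean_spacing,
        "modal_length": modal,
        "n_spacers": len(spacers),
    }


@dataclass(frozen=True)
class TelomericRun:
    interval: GenomicInterval
    motif: str
    strand: str  # "+" or "-"
    n_units: int


def _scan_motif(seq: str, motif: str, min_units: int, max_mm: int):
    """Maximal tandem runs of the motif with per-unit mismatch budget."""
    m = len(motif)
    runs = []
    p = 0
    limit = len(seq) - m
    while p <= limit:
        u = 0
        q = p
        while q + m <= len(seq):
            mism = sum(a != b for a, b in zip(seq[q : q + m], motif))
            if mism > max_mm:
                break
            u += 1
            q += m
        if u >= min_units:
            runs.append((p, q, u))
            p = q
        else:
            p += 1
    return runs


def detect_telomeric_repeats(
    seq: str,
    motifs=("TTAGGG",),
    min_units: int = 3,
    max_mismatch_per_unit: int = 1,
    both_strands: bool = True,
    seq_name: str = "seq",
) -> list:
    """Tandem telomeric-motif runs, forward and reverse-complement.

    Each reported run has at least ``min_units`` consecutive motif copies,
    each copy within ``max_mismatch_per_unit`` mismatches of the motif.
    Reverse-complement runs (e.g. CCCTAA for TTAGGG) are reported on the
    ``-`` strand in forward coordinates.
    """
    out = []
    for motif in motifs:
        if len(motif) < 3:
            raise ValueError("motif length must be >= 3")
        targets = [(motif, "+")]
        if both_strands:
            rc = reverse_complement(motif)
            if rc != motif:
                targets.append((rc, "-"))
        for pattern, strand in targets:
            for start, end, units in _scan_motif(
                seq, pattern, min_units, max_mismatch_per_unit
            ):
                out.append(
                    TelomericRun(
                        interval=GenomicInterval(
                            seq_name, start, end, strand=strand, name=motif
                        ),
                        motif=motif,
                        strand=strand,
                        n_units=units,
                    )
                )
    out.sort(key=lambda r: (r.interval.start, r.strand))
    return out


def windowed_methylation(
    track: MethylTrack,
    window: int = 1_000,
    step: int = 500,
    region: GenomicInterval | None = None,
    coverage_weighted: bool = False,
) -> list:
    """Per-window mean methylation frequency over a sliding window.

    Sites are assigned to windows by midpoint; empty windows yield NaN.
    Returns a list of ``(GenomicInterval, mean)`` pairs.
    """
    if step > window or step <= 0:
        raise ValueError("need 0 < step <= window")
    if region is None:
        region = GenomicInterval(track.seq_name, 0, int(track.ends.max()))
    mids = (track.starts + track.ends) / 2.0
    out = []
    start = region.start
    while start < region.end:
        iv = GenomicInterval(region.seq_name, start, min(start + window, region.end))
        mask = (mids >= iv.start) & (mids < iv.end)
        if not mask.any():
            mean = float("nan")
        elif coverage_weighted:
            w = track.coverage[mask].astype(float)
            mean = float(np.sum(w * track.frequency[mask]) / np.sum(w))
        else:
            mean = float(np.mean(track.frequency[mask]))
        out.append((iv, mean))
        start += step
    return out


@dataclass
class CdrCall:
    hor: GenomicInterval
    cdrs: list  # of GenomicInterval
    window_means: list  # of (GenomicInterval, mean)
    q1: float
    flag: str | None = None  # "flat" | "degenerate" | None

    def __post_init__(self):
        ivs = sorted(self.cdrs, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if a.end > b.start:
                raise ValueError("CDR intervals must not overlap")


def call_cdrs(
    hor: GenomicInterval,
    track: MethylTrack,
    window: int = 5_000,
    mode: str = "min_anchored",
    min_depth_frac: float = 0.25,
) -> CdrCall:
    """Call centromere dip regions over a HOR interval.

    Window means (non-overlapping ``window`` tiling of ``hor``) below their
    lower quartile form candidate runs.  In the default ``min_anchored``
    mode a run is kept only when it contains a window close to the global
    minimum (mean <= gmin + ``min_depth_frac`` * (Q1 - gmin)), which ties
    CDRs to regions of minimum frequency and suppresses shallow noise runs
    that merely cross the quartile; ``mode='below_q1'`` keeps every run.  A
    flat profile yields no CDRs and ``flag='flat'``; a profile whose
    minimum does not fall below the lower quartile (a degenerate plateau of
    ties) yields no CDRs and ``flag='degenerate'``.
    """
    if mode not in ("min_anchored", "below_q1"):
        raise ValueError("mode must be 'min_anchored' or 'below_q1'")
    if hor.length() < 2 * window:
        raise ValueError("HOR must span at least two windows")
    wm = windowed_methylation(track, window=window, step=window, region=hor)
    means = np.array([v for _, v in wm])
    finite = means[np.isfinite(means)]
    if finite.size < 2:
        raise ValueError("fewer than two windows with methylation data")
    if np.all(finite == finite[0]):
        logger.warning("flat methylation profile over HOR; no CDRs")
        return CdrCall(hor, [], wm, q1=float(finite[0]), flag="flat")
    q1 = float(np.percentile(finite, 25))
    below = np.isfinite(means) & (means < q1)
    gmin = float(np.min(finite))
    if not below.any() or gmin >= q1:
        logger.warning("minimum window not below lower quartile; no CDRs")
        return CdrCall(hor, [], wm, q1=q1, flag="degenerate")
    n = len(means)
    deep_threshold = gmin + min_depth_frac * (q1 - gmin)
    is_deep = np.isfinite(means) & (means <= deep_threshold)
    cdrs = []
    i = 0
    while i < n:
        if below[i]:
            j = i
            while j < n and below[j]:
                j += 1
            if mode == "below_q1" or is_deep[i:j].any():
                cdrs.append(
                    GenomicInterval(
                        hor.seq_name, wm[i][0].start, wm[j - 1][0].end, name="CDR"
                    )
                )
            i = j
        else:
            i += 1
    return CdrCall(hor, cdrs, wm, q1=q1)


def _chunk_means(windows, chunk: int, step: int, exclude=()):
    """Collapse (interval, value) windows into chunk means by midpoint."""
    pts = []
    for iv, v in windows:
        if not np.isfinite(v):
            continue
        mid = iv.midpoint
        if any(e.start <= mid < e.end for e in exclude):
            continue
        pts.append((mid, v))
    if not pts:
        return np.array([])
    pts.sort()
    mids = np.array([p for p, _ in pts])
    vals = np.array([v for _, v in pts])
    lo = math.floor(mids.min() / step) * step
    out = []
    start = lo
    while start <= mids.max():
        mask = (mids >= start) & (mids < start + chunk)
        if mask.any():
            out.append(float(vals[mask].mean()))
        start += step
    return np.array(out)


def compare_methylation_groups(
    group_a,
    group_b,
    chunk: int = 17_100,
    step: int = 8_550,
    exclude_a=(),
    exclude_b=(),
):
    """Two-sided Mann-Whitney U between two groups of methylation windows.

    Each group is either a list of ``(GenomicInterval, mean)`` windows
    (collapsed into ``chunk``-bp means stepping by ``step``, after dropping
    windows whose midpoint falls inside the corresponding ``exclude``
    intervals, e.g. called CDRs) or a bare sequence of numbers used
    directly as chunk means.  Returns ``(U, p)`` with U the first group's
    statistic; the normal approximation includes tie correction and a
    continuity correction, and all-tied data gives p = 1.
    """

    def prep(group, exclude):
        group = list(group)
        if group and isinstance(group[0], (int, float, np.floating)):
            return np.asarray(group, dtype=float)
        return _chunk_means(group, chunk, step, exclude)

    a = prep(group_a, exclude_a)
    b = prep(group_b, exclude_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty after chunking")
    n1, n2 = a.size, b.size
    ranks = rankdata(np.concatenate([a, b]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction on the variance
    _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
    n = n1 + n2
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return float(u1), 1.0
    z = (abs(u1 - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    p = float(min(1.0, 2.0 * norm.sf(z)))
    return float(u1), p


@dataclass
class HaplotypeClassification:
    labels: dict  # sample -> tuple of per-array class indices (or None)
    n_classes: int
    unclassified: list = field(default_factory=list)


def classify_structural_haplotypes(
    array_length_table: dict,
    gap_frac: float = 0.25,
) -> HaplotypeClassification:
    """Classify samples into structural haplotypes from array lengths.

    ``array_length_table`` maps sample -> {array name -> length in bp};
    ``None``/NaN lengths flag the sample unclassified.  Per array, sorted
    lengths are split into classes wherever adjacent values differ by more
    than ``gap_frac`` times the array's median length; a haplotype is the
    tuple of per-array class indices, and ``n_classes`` counts distinct
    tuples among classified samples.
    """
    samples = sorted(array_length_table)
    if not samples:
        raise ValueError("empty table")
    arrays = sorted({a for s in samples for a in array_length_table[s]})
    if not arrays:
        raise ValueError("need at least one array column")

    def is_missing(v):
        return v is None or (isinstance(v, float) and math.isnan(v))

    unclassified = [
        s
        for s in samples
        if any(is_missing(array_length_table[s].get(a)) for a in arrays)
    ]
    classified = [s for s in samples if s not in unclassified]
    per_array_class: dict = {}
    for a in arrays:
        vals = sorted((float(array_length_table[s][a]), s) for s in classified)
        if not vals:
            continue
        median = float(np.median([v for v, _ in vals]))
        cls = 0
        prev = None
        for v, s in vals:
            if prev is not None and v - prev > gap_frac * median:
                cls += 1
            per_array_class[(s, a)] = cls
            prev = v
    labels: dict = {}
    for s in samples:
        if s in unclassified:
            labels[s] = None
        else:
            labels[s] = tuple(per_array_class[(s, a)] for a in arrays)
    n_classes = len({t for t in labels.values() if t is not None})
    if unclassified:
        logger.warning("%d samples unclassified (missing lengths)", len(unclassified))
    return HaplotypeClassification(
        labels=labels, n_classes=n_classes, unclassified=unclassified
    )
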