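"""Synteny analysis: non-syntenic segments, identity matrices, SD copies.

Non-syntenic segments are the complement of the union of aligned intervals
on a target sequence.  Windowed identity matrices estimate average
nucleotide identity between sequence windows from canonical k-mer
containment (identity ~ c**(1/k), the Mash containment formula).
Segmental-duplication (SD) copy counting filters alignment hits by
identity, length and query coverage and merges overlapping passing hits;
orthology between SD loci in different genomes is established by
reciprocal, co-linear mapping of both flanking regions, with ortholog
groups taken as connected components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .formats import GenomicInterval
from .sunk import build_census

logger = logging.getLogger(__name__)

__all__ = [
    "SyntenyReport",
    "SdHit",
    "SdLocus",
    "FlankMapping",
    "OrthologGroups",
    "nonsyntenic_segments",
    "windowed_identity_matrix",
    "sd_copy_count",
    "assign_orthologs",
]


@dataclass
class SyntenyReport:
    non_syntenic: list  # of GenomicInterval, non-overlapping, each >= min_len
    total_unaligned_bp: int  # all unaligned bp, including sub-threshold runs
    n_regions: int

    def __post_init__(self):
        if self.n_regions != len(self.non_syntenic):
            raise ValueError("n_regions must equal len(non_syntenic)")
        ivs = sorted(self.non_syntenic, key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if a.end > b.start:
                raise ValueError("non-syntenic intervals must not overlap")


def nonsyntenic_segments(
    target_len: int,
    aligned_intervals,
    min_len: int = 10_000,
    seq_name: str = "target",
) -> SyntenyReport:
    """Complement of the union of aligned intervals, filtered to >= min_len.

    ``total_unaligned_bp`` counts every unaligned base, including runs
    shorter than ``min_len`` that are not reported as regions.
    """
    if target_len <= 0:
        raise ValueError("target_len must be positive")
    spans = []
    for iv in aligned_intervals:
        if isinstance(iv, GenomicInterval):
            s, e = iv.start, iv.end
        else:
            s, e = int(iv[0]), int(iv[1])
            if s >= e:
                raise ValueError(f"empty interval ({s}, {e})")
        if s < 0 or e > target_len:
            raise ValueError(f"interval ({s}, {e}) outside [0, {target_len})")
        spans.append((s, e))
    spans.sort()
    # merge the union, then walk the gaps
    merged = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    gaps = []
    cursor = 0
    for s, e in merged:
        if s > cursor:
            gaps.append((cursor, s))
        cursor = e
    if cursor < target_len:
        gaps.append((cursor, target_len))
    total = sum(e - s for s, e in gaps)
    regions = [
        GenomicInterval(seq_name, s, e) for s, e in gaps if e - s >= min_len
    ]
    return SyntenyReport(
        non_syntenic=regions, total_unaligned_bp=total, n_regions=len(regions)
    )


def _window_kmer_sets(seq: str, window: int, k: int):
    """Canonical k-mer sets of consecutive windows (last partial kept if >=k)."""
    n = len(seq)
    if n <= window:
        starts = [0]
    else:
        starts = list(range(0, n, window))
    sets = []
    for s in starts:
        chunk = seq[s : s + window]
        if len(chunk) < k:
            sets.append(set())
            continue
        sets.append(set(build_census(chunk, k=k).counts))
    return sets


def windowed_identity_matrix(
    seqA: str,
    seqB: str | None = None,
    window: int = 5_000,
    k: int = 21,
) -> np.ndarray:
    """Matrix of ANI estimates between windows of seqA (rows) and seqB (cols).

    Identity is estimated from the canonical-k-mer containment
    ``c = |A & B| / min(|A|, |B|)`` as ``c ** (1/k)``; empty intersections
    give 0.  Symmetric (and unit diagonal) when ``seqB`` is omitted.
    """
    if window < k:
        raise ValueError("window must be >= k")
    if k % 2 == 0:
        raise ValueError("k must be odd (canonical k-mers)")
    self_compare = seqB is None
    sets_a = _window_kmer_sets(seqA, window, k)
    sets_b = sets_a if self_compare else _window_kmer_sets(seqB, window, k)
    mat = np.zeros((len(sets_a), len(sets_b)))
    for i, sa in enumerate(sets_a):
        cols = range(i, len(sets_b)) if self_compare else range(len(sets_b))
        for j in cols:
            sb = sets_b[j]
            denom = min(len(sa), len(sb))
            if denom == 0:
                c = 0.0
            else:
                c = len(sa & sb) / denom
            mat[i, j] = c ** (1.0 / k) if c > 0 else 0.0
    if self_compare:
        mat = np.maximum(mat, mat.T)
    return mat


@dataclass(frozen=True)
class SdHit:
    """One alignment hit of an SD query against a target genome."""

    genome: str
    query_name: str
    target: GenomicInterval
    identity: float
    aligned_len: int
    query_coverage: float

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValueError("query_coverage must be in [0, 1]")
        if self.aligned_len < 0:
            raise ValueError("aligned_len must be nonnegative")


def sd_copy_count(
    hits,
    min_identity: float = 0.98,
    min_len: int = 20_000,
    min_query_cov: float = 0.8,
) -> dict:
    """Per-genome copy number of full-length homologous segments.

    Hits below any of the identity/length/coverage thresholds are dropped;
    surviving hits that overlap on the same target sequence are merged
    before counting, so tandem fragmentary alignments count once.
    """
    passing: dict[str, list[GenomicInterval]] = {}
    for h in hits:
        if (
            h.identity >= min_identity
            and h.aligned_len >= min_len
            and h.query_coverage >= min_query_cov
        ):
            passing.setdefault(h.genome, []).append(h.target)
    out: dict[str, int] = {}
    for genome, ivs in passing.items():
        by_seq: dict[str, list] = {}
        for iv in ivs:
            by_seq.setdefault(iv.seq_name, []).append((iv.start, iv.end))
        count = 0
        for spans in by_seq.values():
            spans.sort()
            end = -1
            for s, e in spans:
                if s >= end:
                    count += 1
                    end = e
                else:
                    end = max(end, e)
        out[genome] = count
    return out


@dataclass(frozen=True)
class SdLocus:
    genome: str
    locus: GenomicInterval
    name: str

    @property
    def key(self):
        return (self.genome, self.name)


@dataclass(frozen=True)
class FlankMapping:
    """Where one flank of ``source`` maps in ``target``'s genome.

    ``side`` is "up" or "down"; ``position`` is the mapped flank midpoint
    on the target genome's coordinate system (same sequence as the target
    locus for a syntenic mapping).
    """

    source: tuple  # (genome, locus name)
    target: tuple  # (genome, locus name)
    side: str
    seq_name: str
    position: int

    def __post_init__(self):
        if self.side not in ("up", "down"):
            raise ValueError("side must be 'up' or 'down'")


@dataclass
class OrthologGroups:
    groups: list  # of sets of (genome, locus name)
    ungrouped: list = field(default_factory=list)  # loci flagged for missing flanks


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _colinear(locus: SdLocus, up_pos, down_pos, tolerance: int) -> bool:
    """Both flanks land near the locus, on its sequence, in up<locus<down order."""
    up_seq, up = up_pos
    down_seq, down = down_pos
    if up_seq != locus.locus.seq_name or down_seq != locus.locus.seq_name:
        return False
    if not up < down:
        return False
    return (
        abs(up - locus.locus.start) <= tolerance
        and abs(down - locus.locus.end) <= tolerance
    )


def assign_orthologs(
    sd_loci,
    flank_alignments,
    distance_tolerance: int = 100_000,
) -> OrthologGroups:
    """Group SD loci across genomes by flanking-region synteny.

    Two loci are called orthologous when both the upstream and downstream
    flanks map reciprocally between them, landing co-linearly within
    ``distance_tolerance`` of the partner locus.  Groups are the connected
    components of that relation.  Loci missing either flank mapping are
    left ungrouped and flagged.
    """
    loci = {l.key: l for l in sd_loci}
    # mapped[(source key, target key, side)] -> (seq, position)
    mapped = {}
    for fm in flank_alignments:
        if fm.source not in loci or fm.target not in loci:
            raise ValueError(f"flank mapping references unknown locus {fm}")
        mapped[(fm.source, fm.target, fm.side)] = (fm.seq_name, fm.position)

    def has_both_flanks(src, tgt):
        return (src, tgt, "up") in mapped and (src, tgt, "down") in mapped

    uf = _UnionFind(loci)
    linked = set()
    keys = sorted(loci)
    for i, a in enumerate(keys):
        for b in keys[i + 1 :]:
            if loci[a].genome == loci[b].genome:
                continue
            if not (has_both_flanks(a, b) and has_both_flanks(b, a)):
                continue
            if _colinear(
                loci[b], mapped[(a, b, "up")], mapped[(a, b, "down")],
                distance_tolerance,
            ) and _colinear(
                loci[a], mapped[(b, a, "up")], mapped[(b, a, "down")],
                distance_tolerance,
            ):
                uf.union(a, b)
                linked.add(a)
                linked.add(b)
    components: dict = {}
    for key in keys:
        if key in linked:
            components.setdefault(uf.find(key), set()).add(key)
    ungrouped = [key for key in keys if key not in linked]
    if ungrouped:
        logger.info("%d loci left ungrouped (missing or non-syntenic flanks)",
                    len(ungrouped))
    return OrthologGroups(
        groups=sorted(components.values(), key=lambda s: sorted(s)),
        ungrouped=ungrouped,
    )
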