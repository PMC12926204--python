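"""Per-window gene-tree topology classification and the polarized ILS profile.

Each orthologous window is classified by maximum likelihood among the three
resolved quartet topologies over {H, Pan, gorilla, outgroup}:

* ``concordant``: ((H,P),G) — the species-tree arrangement,
* ``ILS_HG``: ((H,G),P) — the human-gorilla discordant class,
* ``ILS_PG``: ((P,G),H) — the Pan-gorilla discordant class,

and windows failing the informative-site or support filters are
``unresolved``.  Under the multispecies coalescent a rooted triplet with an
internal branch of ``tau`` coalescent units yields each discordant class
with probability ``exp(-tau)/3``, i.e. total discordance ``(2/3)exp(-tau)``
(:func:`expected_discordance`), which serves as the closed-form check for
the whole scan.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .formats import GenomicInterval, WindowAlignment
from .phylo import QUARTET_PAIRINGS, QuartetPanel
from .substitution import HkyParams
from .trees import Clade, as_clade

logger = logging.getLogger(__name__)

__all__ = [
    "TopologyCall",
    "IlsProfile",
    "CALL_CLASSES",
    "classify_topology",
    "scan_windows",
    "ils_proportion",
    "fold_change",
    "polarity_contrast",
    "ils_profile",
    "expected_discordance",
]

CALL_CLASSES = ("concordant", "ILS_HG", "ILS_PG", "unresolved")

#: pairing index (taxa ordered H, P, G, outgroup) -> call class
_PAIRING_CALL = {0: "concordant", 1: "ILS_HG", 2: "ILS_PG"}


@dataclass
class TopologyCall:
    interval: GenomicInterval | None
    call: str
    delta_lnl: float
    n_informative_sites: int

    def __post_init__(self):
        if self.call not in CALL_CLASSES:
            raise ValueError(f"unknown call class {self.call!r}")

    @property
    def is_resolved(self) -> bool:
        return self.call != "unresolved"

    @property
    def is_discordant(self) -> bool:
        return self.call in ("ILS_HG", "ILS_PG")


@dataclass
class IlsProfile:
    """Binned discordance proportions plus region summaries."""

    bin_edges: np.ndarray
    bin_proportions: np.ndarray
    proximal: float
    distal: float
    background: float
    fold_proximal: float
    fold_distal: float


def expected_discordance(tau: float) -> float:
    """Total discordant-gene-tree probability (2/3)exp(-tau) under the MSC."""
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    return (2.0 / 3.0) * math.exp(-tau)


def classify_topology(tree, taxon_map=None, pan_taxa=None) -> str:
    """Classify a resolved gene tree by the sister pair among {H, P, G}.

    The tree is interpreted as rooted by the outgroup; a missing outgroup or
    an unresolved arrangement yields ``unresolved``.  When ``pan_taxa``
    names several Pan representatives (e.g. chimpanzee and bonobo), the
    tree is classified once per representative and the call is kept only
    when all representatives agree (else ``unresolved``).
    """
    from .synthdata import DEFAULT_TAXON_MAP

    taxon_map = taxon_map or DEFAULT_TAXON_MAP
    if pan_taxa is not None:
        calls = {
            classify_topology(tree, {**taxon_map, "P": pan})
            for pan in pan_taxa
        }
        return calls.pop() if len(calls) == 1 else "unresolved"
    clade: Clade = as_clade(tree)
    names = set(clade.leaf_names())
    roles = {taxon_map[k] for k in ("H", "P", "G")}
    if taxon_map["outgroup"] not in names or not roles <= names:
        return "unresolved"
    h, p, g, o = (taxon_map[k] for k in ("H", "P", "G", "outgroup"))
    four = {h, p, g, o}
    labels = {
        frozenset({h, p}): "concordant",
        frozenset({h, g}): "ILS_HG",
        frozenset({p, g}): "ILS_PG",
    }
    # quartet split induced on {H,P,G,outgroup}: the pair separated from
    # {third, outgroup} by some edge is the sister pair after outgroup rooting
    for node in clade.preorder():
        if node is clade:
            continue
        below = set(node.leaf_names()) & four
        for side in (frozenset(below), frozenset(four - below)):
            if side in labels and o not in side:
                return labels[side]
    return "unresolved"  # polytomy: no edge separates a pair from the rest


def scan_windows(
    window_alignments,
    taxon_map=None,
    min_sites: int = 3,
    support_threshold: float = 0.0,
    params: HkyParams | None = None,
    sweeps: int = 3,
) -> list[TopologyCall]:
    """Classify every window by quartet maximum likelihood.

    ``window_alignments`` is an iterable of ``(GenomicInterval,
    WindowAlignment)`` pairs (a bare alignment is also accepted).  Windows
    with fewer than ``min_sites`` variable sites, or with a winning margin
    below ``support_threshold`` log-likelihood units, are ``unresolved``.
    """
    from .synthdata import DEFAULT_TAXON_MAP

    taxon_map = taxon_map or DEFAULT_TAXON_MAP
    items = []
    for entry in window_alignments:
        if isinstance(entry, WindowAlignment):
            items.append((None, entry))
        else:
            interval, aln = entry[0], entry[1]
            items.append((interval, aln))
    if not items:
        return []
    taxa = (taxon_map["H"], taxon_map["P"], taxon_map["G"], taxon_map["outgroup"])
    panel = QuartetPanel([aln for _, aln in items], taxa, params=params)

    lnls = np.empty((panel.n_windows, 3))
    for idx, pairing in enumerate(QUARTET_PAIRINGS):
        _, lnls[:, idx] = panel.optimize(pairing, sweeps=sweeps)

    order = np.argsort(lnls, axis=1)
    best = order[:, 2]
    delta = lnls[np.arange(panel.n_windows), best] - lnls[
        np.arange(panel.n_windows), order[:, 1]
    ]
    calls = []
    n_unresolved = 0
    for w, (interval, _) in enumerate(items):
        n_var = int(panel.n_variable[w])
        if n_var < min_sites or delta[w] < support_threshold:
            call = "unresolved"
            n_unresolved += 1
        else:
            call = _PAIRING_CALL[int(best[w])]
        calls.append(
            TopologyCall(
                interval=interval,
                call=call,
                delta_lnl=float(delta[w]),
                n_informative_sites=n_var,
            )
        )
    if n_unresolved:
        logger.info(
            "scan: %d/%d windows unresolved (min_sites=%d, support=%.3g)",
            n_unresolved, len(calls), min_sites, support_threshold,
        )
    return calls


def _wilson_ci(k: int, n: int, conf: float = 0.95):
    z = norm.ppf(0.5 + conf / 2.0)
    phat = k / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    return max(0.0, center - half), min(1.0, center + half)


def ils_proportion(
    calls, region: GenomicInterval | None = None, denominator: str = "resolved"
):
    """Discordant fraction among resolved calls, with a Wilson 95% CI.

    Returns ``(proportion, (ci_low, ci_high), n)``; NaN proportion when the
    region has no resolved calls.  ``denominator`` selects the divisor:
    ``"resolved"`` (default) or ``"all"`` windows in the region.
    """
    if denominator not in ("resolved", "all"):
        raise ValueError("denominator must be 'resolved' or 'all'")
    selected = [
        c
        for c in calls
        if region is None
        or (c.interval is not None and c.interval.overlaps(region))
    ]
    resolved = [c for c in selected if c.is_resolved]
    if not resolved:
        logger.warning("no resolved calls in region; proportion undefined")
        return float("nan"), (float("nan"), float("nan")), 0
    k = sum(c.is_discordant for c in resolved)
    n = len(resolved) if denominator == "resolved" else len(selected)
    return k / n, _wilson_ci(k, n), n


def fold_change(region_prop: float, background_prop: float) -> float:
    """Ratio of a regional discordance proportion to the background."""
    if background_prop == 0:
        logger.warning("zero background proportion; fold change undefined")
        return float("nan")
    return region_prop / background_prop


def polarity_contrast(
    proximal_calls, distal_calls, n_perm: int = 10_000, seed=None
):
    """Difference in discordance across the breakpoint, with a permutation p.

    ``delta = distal - proximal`` discordant proportion over resolved
    windows; the two-sided p-value permutes side labels across windows.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-value resolution is coarse", n_perm)
    prox = np.array([c.is_discordant for c in proximal_calls if c.is_resolved])
    dist = np.array([c.is_discordant for c in distal_calls if c.is_resolved])
    if prox.size == 0 or dist.size == 0:
        raise ValueError("both sides need at least one resolved call")
    delta = dist.mean() - prox.mean()
    pooled = np.concatenate([dist, prox]).astype(float)
    n_d = dist.size
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        d = perm[:n_d].mean() - perm[n_d:].mean()
        if abs(d) >= abs(delta) - 1e-15:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return float(delta), float(p)


def ils_profile(
    calls,
    breakpoint: int,
    flank_span: int,
    bin_width: int = 100_000,
) -> IlsProfile:
    """Binned discordance along the scanned span plus side/background summaries.

    ``proximal`` covers ``[breakpoint - flank_span, breakpoint)``, ``distal``
    ``[breakpoint, breakpoint + flank_span)``; the background is the mean
    over all resolved windows (the whole-chromosome average).
    """
    located = [c for c in calls if c.interval is not None and c.is_resolved]
    if not located:
        raise ValueError("no resolved, located calls")
    positions = np.array([c.interval.midpoint for c in located])
    disc = np.array([c.is_discordant for c in located], dtype=float)
    lo = math.floor(positions.min() / bin_width) * bin_width
    hi = math.ceil(positions.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    props = np.full(len(edges) - 1, np.nan)
    which = np.digitize(positions, edges) - 1
    for b in range(len(props)):
        mask = which == b
        if mask.any():
            props[b] = disc[mask].mean()
    background = disc.mean()
    prox_mask = (positions >= breakpoint - flank_span) & (positions < breakpoint)
    dist_mask = (positions >= breakpoint) & (positions < breakpoint + flank_span)
    proximal = disc[prox_mask].mean() if prox_mask.any() else float("nan")
    distal = disc[dist_mask].mean() if dist_mask.any() else float("nan")
    return IlsProfile(
        bin_edges=edges,
        bin_proportions=props,
        proximal=float(proximal),
        distal=float(distal),
        background=float(background),
        fold_proximal=fold_change(proximal, background),
        fold_distal=fold_change(distal, background),
    )
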