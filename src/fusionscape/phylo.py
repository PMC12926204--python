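"""Distances, neighbor-joining, small-topology ML, tree comparison, dating.

The per-window topology scan needs maximum-likelihood evaluation of the three
resolved quartet topologies for tens of thousands of 500 bp windows, so the
quartet likelihood is implemented as a batch engine: site patterns from all
windows are pooled into flat arrays and branch lengths are optimized for all
windows simultaneously by a vectorized golden-section search.  The generic
(single-alignment, 4-5 taxon) entry point :func:`best_topology_ml` shares the
same machinery.

Robinson-Foulds distances are computed from explicit bipartition sets, which
keeps the leaf-label permutation test cheap (relabeling permutes the split
sets without re-walking the tree).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .formats import WindowAlignment
from .substitution import HkyModel, HkyParams, encode_sequence
from .trees import Clade, as_clade, to_dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "DatedNode",
    "pairwise_distance",
    "nj_tree",
    "best_topology_ml",
    "rf_distance",
    "cophylogeny_permutation_test",
    "strict_clock_dating",
    "root_at_outgroup",
    "QuartetPanel",
]

_INVPHI = (math.sqrt(5) - 1) / 2


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape inconsistent with labels")
        finite = np.isfinite(self.matrix)
        if np.any(self.matrix[finite] < 0):
            raise ValueError("negative distances")
        sym = self.matrix[finite & finite.T] - self.matrix.T[finite & finite.T]
        if sym.size and np.max(np.abs(sym)) > 1e-12:
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise ValueError("nonzero diagonal")

    def __getitem__(self, pair):
        a, b = pair
        return self.matrix[self.labels.index(a), self.labels.index(b)]


def _jc_distance(p: float) -> float:
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pairwise_distance(aln: WindowAlignment, model: str = "JC") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap/N sites.

    ``model`` is one of ``p`` (raw proportion of differences), ``JC``
    (Jukes-Cantor) or ``K2P`` (Kimura two-parameter).  Saturated pairs
    (inestimable correction) get ``+inf`` and a warning.
    """
    if model not in ("p", "JC", "K2P"):
        raise ValueError(f"unknown distance model {model!r}")
    taxa = aln.taxa
    if len(taxa) < 2:
        raise ValueError("need at least two sequences")
    codes = {t: encode_sequence(aln.sequences[t]) for t in taxa}
    n = len(taxa)
    out = np.zeros((n, n))
    purine = np.isin(np.arange(4), [0, 2])
    for i, j in itertools.combinations(range(n), 2):
        a, b = codes[taxa[i]], codes[taxa[j]]
        ok = (a >= 0) & (b >= 0)
        if not ok.any():
            raise ValueError(
                f"no comparable sites between {taxa[i]} and {taxa[j]}"
            )
        aa, bb = a[ok], b[ok]
        diff = aa != bb
        p = diff.mean()
        if model == "p":
            d = p
        elif model == "JC":
            d = _jc_distance(p)
        else:
            ts = (diff & (purine[aa] == purine[bb])).mean()
            tv = p - ts
            with np.errstate(invalid="ignore", divide="ignore"):
                inner1 = 1.0 - 2.0 * ts - tv
                inner2 = 1.0 - 2.0 * tv
            if inner1 <= 0 or inner2 <= 0:
                d = math.inf
            else:
                d = -0.5 * math.log(inner1) - 0.25 * math.log(inner2)
        if not np.isfinite(d):
            logger.warning("saturated distance between %s and %s", taxa[i], taxa[j])
        out[i, j] = out[j, i] = d
    return DistanceMatrix(labels=list(taxa), matrix=out)


# ---------------------------------------------------------------------------
# neighbor joining (scikit-bio backend)
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> Clade:
    """Neighbor-joining tree; exact on additive matrices."""
    import skbio

    if len(dm.labels) < 3:
        raise ValueError("need at least three taxa")
    if not np.all(np.isfinite(dm.matrix)):
        raise ValueError("non-finite distances")
    import io as _io

    sk_dm = skbio.DistanceMatrix(dm.matrix, ids=dm.labels)
    tree = skbio.tree.nj(sk_dm)
    buf = _io.StringIO()
    tree.write(buf)
    from .trees import from_newick

    return from_newick(buf.getvalue())


# ---------------------------------------------------------------------------
# batched quartet likelihood engine
# ---------------------------------------------------------------------------

#: the three resolved unrooted quartet pairings over taxon indices (0,1,2,3)
QUARTET_PAIRINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((1, 2), (0, 3)))


class QuartetPanel:
    """Pattern-compressed batch of 4-taxon windows under a shared HKY model."""

    def __init__(self, alignments, taxa, params: HkyParams | None = None):
        if len(taxa) != 4:
            raise ValueError("quartet engine requires exactly 4 taxa")
        self.taxa = tuple(taxa)
        self.params = params or HkyParams()
        self.model = HkyModel(self.params)
        self.n_windows = len(alignments)

        pats, counts, winidx = [], [], []
        n_sites = np.zeros(self.n_windows, dtype=np.int64)
        n_variable = np.zeros(self.n_windows, dtype=np.int64)
        for w, aln in enumerate(alignments):
            cols = np.stack([encode_sequence(aln.sequences[t]) for t in self.taxa])
            ok = (cols >= 0).all(axis=0)
            cols = cols[:, ok].astype(np.int64)
            packed = cols[0] + 4 * cols[1] + 16 * cols[2] + 64 * cols[3]
            u, c = np.unique(packed, return_counts=True)
            pats.append(u)
            counts.append(c)
            winidx.append(np.full(len(u), w, dtype=np.int64))
            n_sites[w] = cols.shape[1]
            base = u & 3
            variable = (
                ((u >> 2) & 3) != base
            ) | (((u >> 4) & 3) != base) | (((u >> 6) & 3) != base)
            n_variable[w] = c[variable].sum()
        packed_all = (
            np.concatenate(pats) if pats else np.array([], dtype=np.int64)
        )
        self.patterns = np.stack(
            [(packed_all >> (2 * i)) & 3 for i in range(4)], axis=1
        )
        self.counts = (
            np.concatenate(counts).astype(float)
            if counts
            else np.array([], dtype=float)
        )
        self.win_idx = (
            np.concatenate(winidx) if winidx else np.array([], dtype=np.int64)
        )
        self.n_sites = n_sites
        self.n_variable = n_variable

    # -- likelihood --------------------------------------------------------

    def loglik(self, pairing, bl: np.ndarray) -> np.ndarray:
        """Per-window log-likelihood for one pairing.

        ``bl`` has shape (n_windows, 5): the four tip branches in pairing
        order (i, j, k, l) then the internal branch.
        """
        (i, j), (k, l) = pairing
        freqs = self.model.freqs
        rates = self.params.category_rates()
        site = np.zeros(len(self.counts))
        for r in rates:
            p_mats = [self.model.transition_matrices(bl[:, b] * r) for b in range(5)]
            gi = p_mats[0][self.win_idx, :, self.patterns[:, i]]
            gj = p_mats[1][self.win_idx, :, self.patterns[:, j]]
            gk = p_mats[2][self.win_idx, :, self.patterns[:, k]]
            gl = p_mats[3][self.win_idx, :, self.patterns[:, l]]
            lu = gi * gj
            lv = gk * gl
            z = np.einsum("pxy,py->px", p_mats[4][self.win_idx], lv)
            site += (freqs * lu * z).sum(axis=1) / len(rates)
        ll = self.counts * np.log(np.maximum(site, 1e-300))
        return np.bincount(self.win_idx, weights=ll, minlength=self.n_windows)

    # -- branch-length optimization -----------------------------------------

    def _p_distances(self) -> np.ndarray:
        """Pairwise mismatch fractions per window, shape (W, 4, 4)."""
        out = np.zeros((self.n_windows, 4, 4))
        tot = np.maximum(
            np.bincount(self.win_idx, weights=self.counts, minlength=self.n_windows),
            1.0,
        )
        for a in range(4):
            for b in range(a + 1, 4):
                diff = self.patterns[:, a] != self.patterns[:, b]
                mism = np.bincount(
                    self.win_idx[diff],
                    weights=self.counts[diff],
                    minlength=self.n_windows,
                )
                out[:, a, b] = out[:, b, a] = mism / tot
        return out

    def optimize(
        self,
        pairing,
        sweeps: int = 3,
        tol: float = 1e-6,
        max_branch: float = 2.0,
    ):
        """Golden-section coordinate ascent on the 5 branch lengths.

        Returns (branch lengths, per-window log-likelihood).
        """
        (i, j), (k, l) = pairing
        p = np.clip(self._p_distances(), 0.0, 0.74)
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
        bl = np.empty((self.n_windows, 5))
        bl[:, 0] = 0.5 * d[:, i, j]
        bl[:, 1] = 0.5 * d[:, i, j]
        bl[:, 2] = 0.5 * d[:, k, l]
        bl[:, 3] = 0.5 * d[:, k, l]
        cross = (d[:, i, k] + d[:, i, l] + d[:, j, k] + d[:, j, l]) / 4.0
        bl[:, 4] = cross / 2.0 - (d[:, i, j] + d[:, k, l]) / 4.0
        np.clip(bl, 1e-6, max_branch, out=bl)

        lo, hi = 1e-8, max_branch
        n_iter = max(5, int(math.ceil(math.log(tol / (hi - lo)) / math.log(_INVPHI))))
        for _ in range(sweeps):
            for b in range(5):
                bl[:, b] = self._golden_branch(pairing, bl, b, lo, hi, n_iter)
        return bl, self.loglik(pairing, bl)

    def _branch_objective(self, pairing, bl, b):
        """lnL as a function of branch ``b`` alone, other branches frozen.

        Precomputes the per-pattern contribution of the four fixed branches
        so each golden-section probe only rebuilds one transition-matrix
        batch.
        """
        (i, j), (k, l) = pairing
        freqs = self.model.freqs
        rates = self.params.category_rates()
        tips = {0: i, 1: j, 2: k, 3: l}

        def gather(mat, tip):
            return mat[self.win_idx, :, self.patterns[:, tip]]

        fixed = []
        for r in rates:
            pm = {
                bb: self.model.transition_matrices(bl[:, bb] * r)
                for bb in range(5)
                if bb != b
            }
            if b in (0, 1):
                other = 1 - b
                lv = gather(pm[2], k) * gather(pm[3], l)
                z = np.einsum("pxy,py->px", pm[4][self.win_idx], lv)
                fixed.append(freqs * gather(pm[other], tips[other]) * z)
            elif b in (2, 3):
                other = 5 - b  # 2 <-> 3
                u = freqs * gather(pm[0], i) * gather(pm[1], j)
                z = np.einsum("px,pxy->py", u, pm[4][self.win_idx])
                fixed.append(z * gather(pm[other], tips[other]))
            else:
                u = freqs * gather(pm[0], i) * gather(pm[1], j)
                v = gather(pm[2], k) * gather(pm[3], l)
                fixed.append((u, v))

        obs = self.patterns[:, tips[b]] if b < 4 else None

        def f(t):
            site = np.zeros(len(self.counts))
            for r, fix in zip(rates, fixed):
                p_b = self.model.transition_matrices(t * r)
                if b < 4:
                    site += (fix * p_b[self.win_idx, :, obs]).sum(axis=1)
                else:
                    u, v = fix
                    site += np.einsum(
                        "px,pxy,py->p", u, p_b[self.win_idx], v
                    )
            site /= len(rates)
            ll = self.counts * np.log(np.maximum(site, 1e-300))
            return np.bincount(self.win_idx, weights=ll, minlength=self.n_windows)

        return f

    def _golden_branch(self, pairing, bl, b, lo, hi, n_iter):
        w = self.n_windows
        f = self._branch_objective(pairing, bl, b)
        a = np.full(w, lo)
        c = np.full(w, hi)
        x1 = c - _INVPHI * (c - a)
        x2 = a + _INVPHI * (c - a)
        f1, f2 = f(x1), f(x2)
        for _ in range(n_iter):
            move_right = f1 < f2
            a = np.where(move_right, x1, a)
            c = np.where(move_right, c, x2)
            x1_new = np.where(move_right, x2, c - _INVPHI * (c - a))
            x2_new = np.where(move_right, a + _INVPHI * (c - a), x1)
            f1_new = np.where(move_right, f2, 0.0)
            f2_new = np.where(move_right, 0.0, f1)
            probe = np.where(move_right, x2_new, x1_new)
            fp = f(probe)
            f1 = np.where(move_right, f1_new, fp)
            f2 = np.where(move_right, fp, f2_new)
            x1, x2 = x1_new, x2_new
        best = np.where(f1 > f2, x1, x2)
        return best


# ---------------------------------------------------------------------------
# generic small-tree ML (4-5 taxa)
# ---------------------------------------------------------------------------

def _tree_loglik(tree: Clade, patterns, counts, model: HkyModel, rates) -> float:
    """Felsenstein pruning over pattern-compressed columns; gamma by mixing."""
    taxa = {name: idx for idx, name in enumerate(tree.leaf_names())}
    site = np.zeros(patterns.shape[0])
    for r in rates:
        def partial(node: Clade) -> np.ndarray:
            if node.is_leaf:
                obs = patterns[:, taxa[node.name]]
                out = np.zeros((patterns.shape[0], 4))
                out[np.arange(len(obs)), obs] = 1.0
                return out
            prod = np.ones((patterns.shape[0], 4))
            for child in node.children:
                p = model.transition_matrices(np.array((child.length or 0.0) * r))
                prod *= partial(child) @ p.T
            return prod

        site += (model.freqs * partial(tree)).sum(axis=1) / len(rates)
    return float(counts @ np.log(np.maximum(site, 1e-300)))


def _compress(aln: WindowAlignment, taxa):
    cols = np.stack([encode_sequence(aln.sequences[t]) for t in taxa])
    ok = (cols >= 0).all(axis=0)
    cols = cols[:, ok].astype(np.int64)
    packed = np.zeros(cols.shape[1], dtype=np.int64)
    for i in range(len(taxa)):
        packed += cols[i] << (2 * i)
    u, c = np.unique(packed, return_counts=True)
    patterns = np.stack([(u >> (2 * i)) & 3 for i in range(len(taxa))], axis=1)
    return patterns, c.astype(float)


def best_topology_ml(
    aln: WindowAlignment,
    candidate_topologies,
    params: HkyParams | None = None,
    sweeps: int = 3,
    tol: float = 1e-6,
):
    """ML topology selection among candidate topologies (4-5 taxa).

    Branch lengths are optimized per candidate by golden-section coordinate
    ascent (``sweeps`` passes over all branches).  Returns
    ``(best_topology, lnl_per_candidate, delta_lnl)`` where ``delta_lnl`` is
    the margin of the best candidate over the runner-up.  Exact ties are
    broken by candidate order and logged.
    """
    params = params or HkyParams()
    model = HkyModel(params)
    rates = params.category_rates()
    candidates = [as_clade(t) for t in candidate_topologies]
    if not candidates:
        raise ValueError("no candidate topologies")
    taxa = sorted(candidates[0].leaf_names())
    if not 4 <= len(taxa) <= 5:
        raise ValueError("ML selection supports 4-5 taxa")
    for cand in candidates:
        if sorted(cand.leaf_names()) != taxa:
            raise ValueError("candidates must share the alignment's taxon set")
    missing = [t for t in taxa if t not in aln.sequences]
    if missing:
        raise ValueError(f"alignment lacks candidate taxa {missing}")
    patterns, counts = _compress(aln, taxa)
    if patterns.size == 0:
        raise ValueError("no comparable alignment columns")

    lo, hi = 1e-8, 2.0
    n_iter = max(5, int(math.ceil(math.log(tol / (hi - lo)) / math.log(_INVPHI))))
    lnls: list[float] = []
    for cand in candidates:
        tree = as_clade(cand.newick())  # private copy; lengths mutated below
        # pattern columns follow the sorted taxon order; _tree_loglik indexes
        # them through the tree's own leaf order
        remapped = np.zeros_like(patterns)
        for idx, name in enumerate(tree.leaf_names()):
            remapped[:, idx] = patterns[:, taxa.index(name)]
        edges = [n for n in tree.preorder() if n is not tree]
        for e in edges:
            if e.length is None:
                e.length = 0.05
        for _ in range(sweeps):
            for edge in edges:
                a, c = lo, hi
                x1 = c - _INVPHI * (c - a)
                x2 = a + _INVPHI * (c - a)
                edge.length = x1
                f1 = _tree_loglik(tree, remapped, counts, model, rates)
                edge.length = x2
                f2 = _tree_loglik(tree, remapped, counts, model, rates)
                for _ in range(n_iter):
                    if f1 < f2:
                        a, x1, f1 = x1, x2, f2
                        x2 = a + _INVPHI * (c - a)
                        edge.length = x2
                        f2 = _tree_loglik(tree, remapped, counts, model, rates)
                    else:
                        c, x2, f2 = x2, x1, f1
                        x1 = c - _INVPHI * (c - a)
                        edge.length = x1
                        f1 = _tree_loglik(tree, remapped, counts, model, rates)
                edge.length = x1 if f1 > f2 else x2
        lnl = _tree_loglik(tree, remapped, counts, model, rates)
        if not np.isfinite(lnl):
            raise ValueError("non-finite log-likelihood")
        lnls.append(lnl)

    order = np.argsort(lnls)[::-1]
    best_idx = int(order[0])
    delta = lnls[best_idx] - (lnls[int(order[1])] if len(lnls) > 1 else -math.inf)
    if len(lnls) > 1 and delta == 0.0:
        tied = [i for i, v in enumerate(lnls) if v == lnls[best_idx]]
        best_idx = min(tied)
        logger.warning("likelihood tie among candidates %s; keeping the first", tied)
    return candidate_topologies[best_idx], list(lnls), float(delta)


# ---------------------------------------------------------------------------
# Robinson-Foulds and the leaf-label permutation test
# ---------------------------------------------------------------------------

def _splits(tree: Clade) -> set[frozenset]:
    """Nontrivial unrooted bipartitions, each encoded as the side without
    the lexicographically smallest leaf."""
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    splits: set[frozenset] = set()
    for node in tree.preorder():
        if node is tree or node.is_leaf:
            continue
        below = frozenset(node.leaf_names())
        if len(below) <= 1 or len(below) >= len(all_leaves) - 1:
            continue
        splits.add(below if ref not in below else all_leaves - below)
    return splits


def rf_distance(t1, t2, normalized: bool = False) -> float:
    """Robinson-Foulds distance: bipartitions present in exactly one tree.

    ``normalized=True`` divides by the maximum ``2(n-3)``.
    """
    c1, c2 = as_clade(t1), as_clade(t2)
    leaves1, leaves2 = set(c1.leaf_names()), set(c2.leaf_names())
    if leaves1 != leaves2:
        raise ValueError("trees have different leaf sets")
    rf = len(_splits(c1) ^ _splits(c2))
    if not normalized:
        return float(rf)
    n = len(leaves1)
    if n <= 3:
        raise ValueError("normalized RF undefined for <4 leaves")
    return rf / (2.0 * (n - 3))


def cophylogeny_permutation_test(
    t1, t2, n_perm: int = 10_000, seed=None, normalized: bool = True
):
    """Permutation test of topological congruence between two trees.

    The null randomly relabels the leaves of the second tree; the p-value is
    ``(1 + #{permuted distance <= observed}) / (1 + n_perm)``.
    """
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-value resolution is coarse", n_perm)
    rng = np.random.default_rng(seed)
    c1, c2 = as_clade(t1), as_clade(t2)
    observed = rf_distance(c1, c2, normalized=normalized)
    names = sorted(c1.leaf_names())
    n = len(names)
    denom = 2.0 * (n - 3) if normalized else 1.0
    splits1 = _splits(c1)
    splits2 = _splits(c2)
    ref = min(names)
    all_leaves = frozenset(names)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        mapping = {names[i]: names[perm[i]] for i in range(n)}
        permuted = set()
        for split in splits2:
            side = frozenset(mapping[x] for x in split)
            permuted.add(side if ref not in side else all_leaves - side)
        dist = len(splits1 ^ permuted) / denom
        if dist <= observed:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return observed, p


# ---------------------------------------------------------------------------
# strict-clock dating
# ---------------------------------------------------------------------------

@dataclass
class DatedNode:
    clade: frozenset
    age: float  # mya
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not self.ci_low <= self.age <= self.ci_high:
            raise ValueError("age outside its confidence interval")


def root_at_outgroup(tree, outgroup: str, mode: str = "midpoint") -> Clade:
    """Reroot an (un)rooted tree on the branch leading to the outgroup leaf.

    ``mode='midpoint'`` puts the root at the middle of the outgroup branch.
    ``mode='clock'`` places it where the root-to-outgroup depth equals the
    mean root-to-ingroup-tip depth, which recovers the true root position
    under a strict clock (the midpoint systematically underestimates the
    outgroup-side depth whenever the ingroup subtree is deep).
    """
    if mode not in ("midpoint", "clock"):
        raise ValueError("mode must be 'midpoint' or 'clock'")
    dtree = to_dendropy(as_clade(tree).newick())
    node = dtree.find_node_with_taxon_label(outgroup)
    if node is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    length = node.edge.length or 0.0
    dtree.reroot_at_edge(node.edge, length1=length / 2, length2=length / 2)
    from .trees import as_clade as _as

    rooted = _as(dtree)
    if mode == "clock":
        out_child = next(
            c for c in rooted.children if c.leaf_names() == [outgroup]
        )
        in_child = next(c for c in rooted.children if c is not out_child)
        # total length of the merged outgroup--ingroup edge after rerooting
        total = (out_child.length or 0.0) + (in_child.length or 0.0)
        if total > 0:
            m_in = _mean_tip_depths_with_leaves(in_child)
            x = min(max((total + m_in) / 2.0, 0.0), total)
            out_child.length = x
            in_child.length = total - x
    return rooted


def _mean_tip_depths_with_leaves(node: Clade) -> float:
    """Mean path length from ``node`` down to its descendant tips."""

    def walk(n: Clade):
        if n.is_leaf:
            return 1, 0.0
        tips, total = 0, 0.0
        for child in n.children:
            t, s = walk(child)
            tips += t
            total += s + t * (child.length or 0.0)
        return tips, total

    tips, total = walk(node)
    return total / tips


def _mean_tip_depths(tree: Clade) -> dict[frozenset, float]:
    """Mean node-to-descendant-tip path length per internal node."""
    out: dict[frozenset, float] = {}

    def walk(node: Clade) -> tuple[int, float]:
        if node.is_leaf:
            return 1, 0.0
        n_tips, total = 0, 0.0
        for child in node.children:
            n, s = walk(child)
            n_tips += n
            total += s + n * (child.length or 0.0)
        out[frozenset(node.leaf_names())] = total / n_tips
        return n_tips, total

    walk(tree)
    return out


def _clock_ages(tree: Clade, calibrations: dict) -> dict[frozenset, float]:
    depths = _mean_tip_depths(tree)
    cal = {frozenset(k): float(v) for k, v in calibrations.items()}
    num = den = 0.0
    for names, age in cal.items():
        clade = frozenset(tree.mrca(names).leaf_names())
        depth = depths[clade]
        if depth <= 0:
            raise ValueError("calibrated node has zero depth")
        num += depth * age
        den += age * age
    rate = num / den  # substitutions/site per My, least squares through 0
    if rate <= 0:
        raise ValueError("non-positive clock rate")
    return {clade: depth / rate for clade, depth in depths.items()}


def strict_clock_dating(
    tree,
    calibrations: dict,
    n_boot: int = 1000,
    seed=None,
    alignment: WindowAlignment | None = None,
    outgroup: str | None = None,
    model: str = "JC",
) -> list[DatedNode]:
    """Date internal nodes under a strict molecular clock.

    A single substitution rate is fitted by least squares to the calibrated
    nodes (mean node-to-tip path length vs. calibration age); every internal
    node's age is its mean tip depth divided by that rate.  When an
    ``alignment`` (and ``outgroup`` for rerooting) is supplied, confidence
    intervals come from a nonparametric bootstrap over alignment columns
    (distance re-estimation + neighbor joining per replicate); otherwise the
    intervals collapse to the point estimate.
    """
    if not calibrations:
        raise ValueError("need at least one calibration")
    base = as_clade(tree)
    ages = _clock_ages(base, calibrations)

    boot_ages: dict[frozenset, list[float]] = {c: [] for c in ages}
    if alignment is not None and n_boot > 0:
        if outgroup is None:
            raise ValueError("bootstrap rerooting requires an outgroup")
        rng = np.random.default_rng(seed)
        taxa = alignment.taxa
        length = alignment.length
        codes = np.stack([encode_sequence(alignment.sequences[t]) for t in taxa])
        for _ in range(n_boot):
            idx = rng.integers(length, size=length)
            resampled = WindowAlignment(
                {
                    t: "".join("ACGT"[c] if c >= 0 else "N" for c in codes[i, idx])
                    for i, t in enumerate(taxa)
                }
            )
            try:
                dm = pairwise_distance(resampled, model=model)
                btree = root_at_outgroup(nj_tree(dm), outgroup, mode="clock")
                for clade, age in _clock_ages(btree, calibrations).items():
                    if clade in boot_ages:
                        boot_ages[clade].append(age)
            except ValueError:
                continue

    out = []
    for clade, age in sorted(ages.items(), key=lambda kv: sorted(kv[0])):
        draws = boot_ages.get(clade, [])
        if draws:
            lo, hi = np.percentile(draws, [2.5, 97.5])
            lo, hi = min(lo, age), max(hi, age)
        else:
            lo = hi = age
        out.append(DatedNode(clade=clade, age=age, ci_low=float(lo), ci_high=float(hi)))
    return out
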