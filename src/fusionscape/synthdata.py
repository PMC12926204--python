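"""Synthetic-data generators for every input class the pipeline consumes.

The generators are first-class, tested code: they produce orthologous
alignment windows whose genealogies follow a multispecies coalescent (MSC)
with a breakpoint-polarized discordance gradient, subterminal satellite
chromosomes with spacer punctuation, methylation tracks with hypomethylated
pockets and planted dips, neutral haplotype panels, and assembly sets with
planted unique k-mers.

Coalescent-unit convention: for a species-tree internal branch lasting
``dt`` generations in a population of diploid effective size ``Ne``, the
branch length in coalescent units is ``tau = dt / (2 * Ne)``.  For a rooted
triplet with internal branch ``tau`` the probability of each discordant
gene-tree topology is ``exp(-tau) / 3``.

All generators are bit-reproducible given (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .formats import GenomicInterval, MethylTrack, VariantMatrix, WindowAlignment
from .substitution import (
    ALPHABET,
    HkyModel,
    HkyParams,
    decode_sequence,
    encode_sequence,
)
from .trees import Clade, from_newick

__all__ = [
    "SpeciesTreeSpec",
    "IlsGradientSpec",
    "SatelliteSpec",
    "AssemblySet",
    "DEFAULT_TAXON_MAP",
    "default_species_tree",
    "sample_gene_tree",
    "triplet_topology",
    "simulate_alignment",
    "simulate_window_panel",
    "simulate_satellite_chromosome",
    "simulate_methylation_track",
    "simulate_haplotype_panel",
    "simulate_assembly_set",
    "species_tree_as_gene_tree",
]

#: Default roles in the rooted triplet + outgroup used by the topology scan.
DEFAULT_TAXON_MAP = {
    "H": "human",
    "P": "chimpanzee",
    "G": "gorilla",
    "outgroup": "macaque",
}

# 32 bp AT-rich subterminal satellite monomer used as the default repeat unit.
DEFAULT_MONOMER = "AATTCATTTGAAATGTTTAACCTAACAGTGGA"


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# species tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesTreeSpec:
    """Rooted species tree with split times, population sizes, and a clock.

    ``split_times`` maps the leaf set of each internal node (as a frozenset)
    to its age in years.  ``ancestral_Ne`` is either a single diploid
    effective size applied to every population or a mapping from clade leaf
    sets to sizes (``math.inf`` disables coalescence in that population).
    """

    topology: str
    split_times: dict
    ancestral_Ne: float | dict = 200_000.0
    generation_time: float = 20.0
    mutation_rate: float = 2.5e-8  # per site per generation

    def __post_init__(self):
        if self.generation_time <= 0:
            raise ValueError("generation_time must be positive")
        if self.mutation_rate <= 0:
            raise ValueError("mutation_rate must be positive")
        tree = self.tree()
        for node, clade, age in self._node_ages(tree):
            if node.is_leaf:
                continue
            for child in node.children:
                child_age = (
                    0.0
                    if child.is_leaf
                    else self.split_times[frozenset(child.leaf_names())]
                )
                if child_age >= age:
                    raise ValueError(
                        "split times must strictly decrease toward the leaves"
                    )
        for ne in self._all_ne(tree):
            if not ne > 0:
                raise ValueError("all Ne must be positive")

    def tree(self) -> Clade:
        return from_newick(self.topology)

    def _node_ages(self, tree: Clade):
        out = []
        for node in tree.preorder():
            clade = frozenset(node.leaf_names())
            if node.is_leaf:
                out.append((node, clade, 0.0))
            else:
                if clade not in self.split_times:
                    raise ValueError(f"missing split time for clade {sorted(clade)}")
                out.append((node, clade, float(self.split_times[clade])))
        return out

    def ne_for(self, clade: frozenset) -> float:
        if isinstance(self.ancestral_Ne, dict):
            if clade in self.ancestral_Ne:
                return float(self.ancestral_Ne[clade])
            if "default" in self.ancestral_Ne:
                return float(self.ancestral_Ne["default"])
            raise ValueError(f"missing Ne for clade {sorted(clade)}")
        return float(self.ancestral_Ne)

    def _all_ne(self, tree: Clade):
        return [self.ne_for(frozenset(n.leaf_names())) for n in tree.preorder()]

    def taxa(self) -> list[str]:
        return self.tree().leaf_names()

    def generations(self, years: float) -> float:
        return years / self.generation_time

    def internal_branch_tau(self, clade: frozenset) -> float:
        """Coalescent-unit length of the branch above the given clade."""
        tree = self.tree()
        ages = {c: a for _, c, a in self._node_ages(tree)}
        parent_age = None
        for node in tree.preorder():
            for child in node.children:
                if frozenset(child.leaf_names()) == clade:
                    parent_age = ages[frozenset(node.leaf_names())]
        if parent_age is None:
            raise ValueError(f"clade {sorted(clade)} has no parent branch")
        dt_gen = self.generations(parent_age - ages[clade])
        ne = self.ne_for(clade)
        return dt_gen / (2.0 * ne)

    def with_tau(self, tau: float, clade: frozenset) -> "SpeciesTreeSpec":
        """Return a spec whose named ancestral population has the given tau.

        Split times are left untouched; the population size of the branch is
        rescaled (``tau = dt_generations / (2 Ne)``); ``tau=0`` disables
        coalescence on that branch.
        """
        if tau < 0:
            raise ValueError("tau must be nonnegative")
        current = self.internal_branch_tau(clade)
        ne_now = self.ne_for(clade)
        new_ne = math.inf if tau == 0 else ne_now * current / tau
        ne_map = {
            frozenset(n.leaf_names()): self.ne_for(frozenset(n.leaf_names()))
            for n in self.tree().preorder()
        }
        ne_map[clade] = new_ne
        return replace(self, ancestral_Ne=ne_map)


def default_species_tree(**overrides) -> SpeciesTreeSpec:
    """Great-ape-like default: (((human,(chimp,bonobo)),gorilla),macaque).

    Split times 2.5 / 6 / 14 / 20 Mya with Ne = 200,000 and 20-year
    generations give tau = 1 on the branch separating the human-Pan
    ancestor from the human-Pan-gorilla ancestor.  Two defaults are
    deliberately calibrated rather than biological: the mutation rate of
    1e-7 per site per generation puts roughly 20 expected substitutions
    per coalescent unit on a 500 bp window's internal branch (at a
    realistic 2.5e-8 most of the ILS signal in a 500 bp window falls below
    the detection floor and scan proportions are visibly biased toward
    1/3), and the outgroup root sits at 20 Mya because a deeper root makes
    the outgroup branch long enough that homoplasy noise on it biases
    per-window topology calls toward excess discordance.  With these
    defaults the windowed scan recovers the generator's discordance
    probabilities within binomial noise and per-window call accuracy at
    tau = 1 exceeds 90%.
    """
    spec = dict(
        topology="(((human,(chimpanzee,bonobo)),gorilla),macaque);",
        split_times={
            frozenset({"chimpanzee", "bonobo"}): 2.5e6,
            frozenset({"human", "chimpanzee", "bonobo"}): 6.0e6,
            frozenset({"human", "chimpanzee", "bonobo", "gorilla"}): 14.0e6,
            frozenset({"human", "chimpanzee", "bonobo", "gorilla", "macaque"}): 20.0e6,
        },
        ancestral_Ne={
            frozenset({"human", "chimpanzee", "bonobo", "gorilla"}): 600_000.0,
            frozenset(
                {"human", "chimpanzee", "bonobo", "gorilla", "macaque"}
            ): 600_000.0,
            "default": 200_000.0,
        },
        generation_time=20.0,
        mutation_rate=1.0e-7,
    )
    spec.update(overrides)
    return SpeciesTreeSpec(**spec)


def triplet_clade(spec: SpeciesTreeSpec, taxon_map=None) -> frozenset:
    """Leaf set of the population ancestral to H and P but not G."""
    taxon_map = taxon_map or DEFAULT_TAXON_MAP
    tree = spec.tree()
    node = tree.mrca([taxon_map["H"], taxon_map["P"]])
    return frozenset(node.leaf_names())


# ---------------------------------------------------------------------------
# gene trees under the MSC
# ---------------------------------------------------------------------------

def sample_gene_tree(spec: SpeciesTreeSpec, seed) -> Clade:
    """Draw one gene tree (one haploid lineage per species) under the MSC.

    Branch lengths are in expected substitutions per site
    (generations * mutation_rate).
    """
    rng = _rng(seed)
    tree = spec.tree()
    ages = {c: a for _, c, a in spec._node_ages(tree)}
    times: dict[int, float] = {}  # id(gene node) -> time in generations

    def coalesce(lineages: list[Clade], t0: float, t1: float, ne: float):
        t = t0
        while len(lineages) >= 2:
            k = len(lineages)
            if not np.isfinite(ne):
                break
            rate = k * (k - 1) / 2.0 / (2.0 * ne)
            wait = rng.exponential(1.0 / rate)
            if t + wait > t1:
                break
            t += wait
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[i], lineages[j]
            parent = Clade(children=[a, b])
            times[id(parent)] = t
            lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
            lineages.append(parent)
        return lineages

    def walk(node: Clade) -> list[Clade]:
        clade = frozenset(node.leaf_names())
        if node.is_leaf:
            leaf = Clade(name=node.name)
            times[id(leaf)] = 0.0
            return [leaf]
        lineages: list[Clade] = []
        t_node = spec.generations(ages[clade])
        for child in node.children:
            child_clade = frozenset(child.leaf_names())
            child_age = spec.generations(ages[child_clade])
            entering = walk(child)
            lineages.extend(
                coalesce(entering, child_age, t_node, spec.ne_for(child_clade))
            )
        return lineages

    root_clade = frozenset(tree.leaf_names())
    lineages = walk(tree)
    t_root = spec.generations(ages[root_clade])
    ne_root = spec.ne_for(root_clade)
    if not np.isfinite(ne_root):
        raise ValueError("root population must have finite Ne")
    lineages = coalesce(lineages, t_root, math.inf, ne_root)
    assert len(lineages) == 1
    root = lineages[0]
    for node in root.preorder():
        for child in node.children:
            child.length = (times[id(node)] - times[id(child)]) * spec.mutation_rate
    return root


def triplet_topology(gene_tree: Clade, taxon_map=None) -> str:
    """Classify a gene tree by which of {H,P,G} coalesce first.

    Returns ``concordant`` (H,P sisters), ``ILS_HG`` or ``ILS_PG``.
    """
    taxon_map = taxon_map or DEFAULT_TAXON_MAP
    h, p, g = taxon_map["H"], taxon_map["P"], taxon_map["G"]
    depths = {
        "concordant": gene_tree.mrca_depth([h, p]),
        "ILS_HG": gene_tree.mrca_depth([h, g]),
        "ILS_PG": gene_tree.mrca_depth([p, g]),
    }
    # deepest MRCA depth = most recent coalescence (depths measured from root)
    return max(depths, key=depths.get)


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

def simulate_alignment(
    gene_tree: Clade, params: HkyParams, length: int, seed
) -> WindowAlignment:
    """Evolve one ungapped sequence per leaf along the tree under HKY(+gamma)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    for node in gene_tree.preorder():
        if node.length is not None and node.length < 0:
            raise ValueError("negative branch length")
    rng = _rng(seed)
    model = HkyModel(params)
    rates = params.category_rates()
    ncat = len(rates)
    cats = rng.integers(ncat, size=length) if ncat > 1 else np.zeros(length, dtype=int)
    root_states = rng.choice(4, size=length, p=model.freqs)

    sequences: dict[str, str] = {}

    def evolve(states: np.ndarray, node: Clade):
        for child in node.children:
            t = child.length or 0.0
            new = states.copy()
            if t > 0:
                for c in range(ncat):
                    mask = cats == c if ncat > 1 else slice(None)
                    sub = new[mask]
                    p = model.transition_matrices(np.array(t * rates[c]))
                    cum = np.cumsum(p[sub, :], axis=1)
                    u = rng.random(len(sub))
                    new[mask] = np.minimum((u[:, None] > cum).sum(axis=1), 3)
            if child.is_leaf:
                sequences[child.name] = decode_sequence(new)
            else:
                evolve(new, child)

    if gene_tree.is_leaf:
        sequences[gene_tree.name] = decode_sequence(root_states)
    else:
        evolve(root_states, gene_tree)
    return WindowAlignment(sequences)


def species_tree_as_gene_tree(spec: SpeciesTreeSpec) -> Clade:
    """The species tree itself as a clock-like gene tree (no coalescent noise).

    Branch lengths are substitutions/site implied by split times, the
    generation time and the mutation rate.
    """
    tree = spec.tree()
    ages = {c: a for _, c, a in spec._node_ages(tree)}
    for node in tree.preorder():
        t_node = ages[frozenset(node.leaf_names())]
        for child in node.children:
            t_child = ages[frozenset(child.leaf_names())]
            child.length = spec.generations(t_node - t_child) * spec.mutation_rate
    return tree


# ---------------------------------------------------------------------------
# breakpoint-polarized window panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IlsGradientSpec:
    """Discordance gradient polarized around a breakpoint.

    Windows on the distal side of ``breakpoint`` (within ``flank_span`` bp)
    have discordance probability ``background_discordance * flank_fold``;
    everything else sits at the background.
    """

    breakpoint: int
    background_discordance: float
    flank_fold: float = 1.0
    flank_span: int = 2_500_000

    def __post_init__(self):
        if not 0 <= self.background_discordance <= 1:
            raise ValueError("background_discordance must be in [0,1]")
        if self.background_discordance * self.flank_fold > 1:
            raise ValueError("background * fold exceeds 1")
        if self.flank_span <= 0:
            raise ValueError("flank_span must be positive")


def _tau_for_discordance(d: float) -> float:
    """Invert d = (2/3) exp(-tau); the MSC caps discordance at 2/3."""
    if d < 0 or d > 2.0 / 3.0 + 1e-12:
        raise ValueError(
            "target discordance must be in [0, 2/3] under the coalescent"
        )
    if d == 0:
        return math.inf
    return -math.log(1.5 * min(d, 2.0 / 3.0))


def simulate_window_panel(
    tree_spec: SpeciesTreeSpec,
    gradient: IlsGradientSpec,
    n_windows: int,
    window_len: int = 500,
    seed=None,
    params: HkyParams | None = None,
    taxon_map=None,
    seq_name: str = "chrF",
):
    """Tile a synthetic chromosome with labeled orthologous windows.

    Returns a list of ``(GenomicInterval, WindowAlignment, true_label)``
    where the label is the realized gene-tree triplet topology.
    """
    if n_windows < 1:
        raise ValueError("need at least one window")
    taxon_map = taxon_map or DEFAULT_TAXON_MAP
    params = params or HkyParams()
    rng = _rng(seed)
    clade = triplet_clade(tree_spec, taxon_map)

    d_bg = gradient.background_discordance
    d_flank = d_bg * gradient.flank_fold
    spec_bg = tree_spec.with_tau(_tau_for_discordance(d_bg), clade)
    spec_flank = tree_spec.with_tau(_tau_for_discordance(d_flank), clade)

    out = []
    for i in range(n_windows):
        start = i * window_len
        interval = GenomicInterval(seq_name, start, start + window_len)
        distal = (
            gradient.breakpoint <= start < gradient.breakpoint + gradient.flank_span
        )
        spec_w = spec_flank if distal else spec_bg
        gtree = sample_gene_tree(spec_w, rng)
        label = triplet_topology(gtree, taxon_map)
        aln = simulate_alignment(gtree, params, window_len, rng)
        out.append((interval, aln, label))
    return out


# ---------------------------------------------------------------------------
# satellite chromosomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SatelliteSpec:
    """Tandem satellite arrays punctuated by spacer segments.

    ``monomer_sub_rate`` is the per-base substitution probability applied
    independently to every monomer copy (0.05 -> ~95% identity to consensus).
    ``spacer_length_dist`` is (mode, spread) of a normal draw, rounded and
    floored at 1 kbp; spread 0 plants the modal length exactly.
    """

    monomer: str = DEFAULT_MONOMER
    array_lengths: tuple = (255_000,) * 10
    spacer_length_dist: tuple = (32_000, 0)
    monomer_sub_rate: float = 0.05

    def __post_init__(self):
        if len(self.monomer) < 2:
            raise ValueError("monomer length must be >= 2")
        if not self.array_lengths:
            raise ValueError("need at least one array")
        if any(a <= 0 for a in self.array_lengths):
            raise ValueError("array lengths must be positive")
        if not 0 <= self.monomer_sub_rate < 1:
            raise ValueError("monomer_sub_rate must be in [0,1)")

    @classmethod
    def uniform_spacing(
        cls, n_spacers: int, spacing: int, spacer_len: int = 32_000, **kw
    ) -> "SatelliteSpec":
        """Arrays sized so consecutive spacer midpoints sit ``spacing`` bp apart."""
        inner = spacing - spacer_len
        if inner <= 0:
            raise ValueError("spacing must exceed the spacer length")
        lengths = (inner,) * (n_spacers + 1)
        return cls(
            array_lengths=lengths, spacer_length_dist=(spacer_len, 0), **kw
        )


def simulate_satellite_chromosome(spec: SatelliteSpec, seed):
    """Build (sequence, truth intervals) for a satellite/spacer chromosome.

    The truth intervals partition the sequence and are labeled ``satellite``
    or ``spacer``.  Array lengths are rounded up to whole monomers.
    """
    rng = _rng(seed)
    m = len(spec.monomer)
    monomer_codes = encode_sequence(spec.monomer)
    if np.any(monomer_codes < 0):
        raise ValueError("monomer must be A/C/G/T only")
    mode, spread = spec.spacer_length_dist

    pieces: list[np.ndarray] = []
    truth: list[GenomicInterval] = []
    pos = 0
    seq_name = "chrT"
    for i, target in enumerate(spec.array_lengths):
        n_mon = int(math.ceil(target / m))
        arr = np.tile(monomer_codes, n_mon)
        if spec.monomer_sub_rate > 0:
            mask = rng.random(arr.size) < spec.monomer_sub_rate
            arr[mask] = (arr[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
        pieces.append(arr)
        truth.append(
            GenomicInterval(seq_name, pos, pos + arr.size, name="satellite")
        )
        pos += arr.size
        if i < len(spec.array_lengths) - 1:
            slen = int(mode) if spread == 0 else max(
                1000, int(round(rng.normal(mode, spread)))
            )
            spacer = rng.integers(0, 4, size=slen, dtype=np.int8)
            pieces.append(spacer)
            truth.append(GenomicInterval(seq_name, pos, pos + slen, name="spacer"))
            pos += slen
    seq = decode_sequence(np.concatenate(pieces))
    return seq, truth


# ---------------------------------------------------------------------------
# methylation tracks
# ---------------------------------------------------------------------------

def simulate_methylation_track(
    region_len: int,
    truth: list[GenomicInterval] | None = None,
    dip: GenomicInterval | None = None,
    levels: tuple = (0.9, 0.2, 0.1),
    noise_sd: float = 0.0,
    seed=None,
    site_spacing: int = 25,
    coverage: int = 30,
    seq_name: str = "chrT",
) -> MethylTrack:
    """Per-site methylation frequencies with interval-specific means.

    ``levels = (satellite_mean, spacer_mean, dip_mean)``: sites default to the
    satellite level, sites inside a ``spacer``-labeled truth interval get the
    spacer level, and sites inside ``dip`` get the dip level (dip wins).
    Values are Normal(level, noise_sd) clipped to [0, 1].
    """
    sat_mean, spacer_mean, dip_mean = levels
    for lv in levels:
        if not 0 <= lv <= 1:
            raise ValueError("level means must be in [0,1]")
    if dip is not None and not (0 <= dip.start and dip.end <= region_len):
        raise ValueError("dip interval outside region")
    rng = _rng(seed)
    starts = np.arange(0, region_len - 1, site_spacing, dtype=np.int64)
    ends = starts + 2
    mids = (starts + ends) / 2
    level = np.full(len(starts), sat_mean)
    if truth:
        for iv in truth:
            if iv.name == "spacer":
                level[(mids >= iv.start) & (mids < iv.end)] = spacer_mean
    if dip is not None:
        level[(mids >= dip.start) & (mids < dip.end)] = dip_mean
    freq = level if noise_sd == 0 else np.clip(
        level + rng.normal(0.0, noise_sd, size=len(level)), 0.0, 1.0
    )
    return MethylTrack(
        seq_name=seq_name,
        starts=starts,
        ends=ends,
        frequency=freq,
        coverage=np.full(len(starts), coverage, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# neutral haplotype panels
# ---------------------------------------------------------------------------

def simulate_haplotype_panel(
    n_haplotypes: int,
    seq_len: int,
    theta_per_site: float,
    seed=None,
    seq_name: str = "chrS",
) -> VariantMatrix:
    """Neutral infinite-sites panel on a Kingman coalescent genealogy.

    ``theta_per_site`` is the population-scaled mutation rate 4*Ne*mu; the
    expected number of segregating sites is ``theta * L * a1`` with
    ``a1 = sum_{i<n} 1/i`` (Watterson).
    """
    if n_haplotypes < 2:
        raise ValueError("need at least two haplotypes")
    if theta_per_site < 0:
        raise ValueError("theta must be nonnegative")
    rng = _rng(seed)
    n = n_haplotypes

    # coalescent genealogy: branches carry the leaf set below them
    active: list[tuple[frozenset, float]] = [
        (frozenset([i]), 0.0) for i in range(n)
    ]
    branches: list[tuple[frozenset, float]] = []  # (leaf set, length in 2N gens)
    t = 0.0
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (set_j, born_j) = active.pop(j)
        (set_i, born_i) = active.pop(i)
        branches.append((set_i, t - born_i))
        branches.append((set_j, t - born_j))
        active.append((set_i | set_j, t))

    genotypes_cols: list[np.ndarray] = []
    if theta_per_site > 0:
        per_site_rate = theta_per_site / 2.0  # mutations per site per 2N gens
        counts = rng.poisson(
            np.array([l for _, l in branches]) * per_site_rate * seq_len
        )
        total = int(counts.sum())
        total = min(total, seq_len)  # infinite-sites on a finite grid
        if total:
            positions = np.sort(rng.choice(seq_len, size=total, replace=False))
            carriers = []
            for (leafset, _), c in zip(branches, counts):
                carriers.extend([leafset] * int(c))
            carriers = carriers[:total]
            order = rng.permutation(total)
            for idx in order:
                col = np.zeros(n, dtype=np.int8)
                col[list(carriers[idx])] = 1
                genotypes_cols.append(col)
            genotypes = np.stack(genotypes_cols, axis=1)
            return VariantMatrix(
                samples=[f"hap{i}" for i in range(n)],
                positions=positions,
                genotypes=genotypes,
                seq_name=seq_name,
                seq_len=seq_len,
            )
    return VariantMatrix(
        samples=[f"hap{i}" for i in range(n)],
        positions=np.array([], dtype=np.int64),
        genotypes=np.zeros((n, 0), dtype=np.int8),
        seq_name=seq_name,
        seq_len=seq_len,
    )


# ---------------------------------------------------------------------------
# assembly sets with planted unique k-mers
# ---------------------------------------------------------------------------

@dataclass
class AssemblySet:
    """A panel of synthetic assemblies plus a query genome.

    ``planted`` is the truth set of canonical k-mers unique in every panel
    genome; ``carried`` is the subset present in the query.
    """

    panel: dict[str, str]
    query: str
    planted: set[str]
    carried: set[str]
    k: int


def _random_seq(rng, length: int) -> str:
    return decode_sequence(rng.integers(0, 4, size=length, dtype=np.int8))


def _canonical(kmer: str) -> str:
    from .sunk import canonical_kmer

    return canonical_kmer(kmer)


def _plant(rng, background: str, kmers: list[str], flank_base: str | None = None) -> str:
    """Overwrite one non-overlapping slot per k-mer (one slot per equal block).

    When ``flank_base`` is given, the bases immediately flanking each plant
    are pinned to it.  Panel genomes use different flank bases so that
    k-mers straddling a plant boundary (shared plant content plus flanking
    background) can never occur in every genome, which would otherwise
    create unplanted k-mers unique to all assemblies.
    """
    n = len(kmers)
    if n == 0:
        return background
    length = len(background)
    k = len(kmers[0])
    block = length // n
    if block < k + 2:
        raise ValueError("genome too short for the requested number of k-mers")
    seq = list(background)
    for i, kmer in enumerate(kmers):
        # keep one background base on each side inside the block so the
        # pinned flanks never touch a neighboring plant
        offset = i * block + 1 + int(rng.integers(0, block - k - 1))
        seq[offset : offset + k] = kmer
        if flank_base is not None:
            seq[offset - 1] = flank_base
            if offset + k < length:
                seq[offset + k] = flank_base
    return "".join(seq)


def simulate_assembly_set(
    n_panel: int,
    genome_len: int,
    n_planted_sunks: int,
    k: int = 31,
    query_carries: float = 1.0,
    seed=None,
    max_retries: int = 100,
) -> AssemblySet:
    """Panel genomes each carrying every planted k-mer exactly once.

    The query carries exactly ``ceil(query_carries * n_planted)`` of them.
    Background collisions are resolved by redrawing the offending k-mer, up
    to ``max_retries`` times.
    """
    from .sunk import build_census, canonical_kmer

    if n_planted_sunks * k > genome_len:
        raise ValueError("planted k-mers exceed the genome length")
    if not 0 <= query_carries <= 1:
        raise ValueError("query_carries must be in [0,1]")
    if k % 2 == 0:
        raise ValueError("k must be odd")
    rng = _rng(seed)

    kmers: list[str] = []
    seen: set[str] = set()
    while len(kmers) < n_planted_sunks:
        cand = _random_seq(rng, k)
        canon = canonical_kmer(cand)
        if canon not in seen:
            seen.add(canon)
            kmers.append(cand)

    panel: dict[str, str] = {}
    for attempt in range(max_retries + 1):
        panel = {
            f"panel{g}": _plant(
                rng, _random_seq(rng, genome_len), kmers, flank_base="ACGT"[g % 4]
            )
            for g in range(n_panel)
        }
        censuses = build_census(panel, k=k)
        bad = {
            idx
            for idx, km in enumerate(kmers)
            for census in censuses.values()
            if census.get(canonical_kmer(km), 0) != 1
        }
        if not bad:
            break
        if attempt == max_retries:
            raise RuntimeError("could not place collision-free k-mers")
        for idx in bad:  # redraw the colliding k-mers and rebuild the panel
            while True:
                cand = _random_seq(rng, k)
                canon = canonical_kmer(cand)
                if canon not in seen:
                    seen.add(canon)
                    kmers[idx] = cand
                    break

    n_carry = int(math.ceil(query_carries * n_planted_sunks))
    carry_idx = rng.permutation(n_planted_sunks)[:n_carry]
    carried_kmers = [kmers[i] for i in sorted(carry_idx)]
    planted_canon = {canonical_kmer(km) for km in kmers}
    carried_canon = {canonical_kmer(km) for km in carried_kmers}
    for attempt in range(max_retries + 1):
        query = _plant(rng, _random_seq(rng, genome_len), carried_kmers)
        qcensus = build_census({"query": query}, k=k)["query"]
        present = {km for km in planted_canon if qcensus.get(km, 0) > 0}
        if present == carried_canon:
            break
        if attempt == max_retries:
            raise RuntimeError("could not build a collision-free query")
    return AssemblySet(
        panel=panel,
        query=query,
        planted=planted_canon,
        carried=carried_canon,
        k=k,
    )
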