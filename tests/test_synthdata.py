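"""Generator contracts: MSC topology frequencies, HKY alignments, truth
annotations, neutral panels, assembly sets, and bit-reproducibility."""

import math

import numpy as np
import pytest

from fusionscape.formats import GenomicInterval
from fusionscape.substitution import HkyParams
from fusionscape.synthdata import (
    DEFAULT_TAXON_MAP,
    IlsGradientSpec,
    SatelliteSpec,
    SpeciesTreeSpec,
    default_species_tree,
    sample_gene_tree,
    simulate_alignment,
    simulate_assembly_set,
    simulate_haplotype_panel,
    simulate_methylation_track,
    simulate_satellite_chromosome,
    simulate_window_panel,
    triplet_topology,
)
from fusionscape.synthdata import triplet_clade

TRIPLET = frozenset({"human", "chimpanzee", "bonobo"})


# ---------------------------------------------------------------------------
# species tree spec
# ---------------------------------------------------------------------------

def test_spec_validation():
    with pytest.raises(ValueError, match="strictly decrease"):
        default_species_tree(
            split_times={
                frozenset({"chimpanzee", "bonobo"}): 7.0e6,  # older than parent
                frozenset({"human", "chimpanzee", "bonobo"}): 6.0e6,
                frozenset({"human", "chimpanzee", "bonobo", "gorilla"}): 14.0e6,
                frozenset(
                    {"human", "chimpanzee", "bonobo", "gorilla", "macaque"}
                ): 20.0e6,
            }
        )
    with pytest.raises(ValueError):
        default_species_tree(mutation_rate=0.0)
    with pytest.raises(ValueError):
        default_species_tree(generation_time=-1.0)
    with pytest.raises(ValueError):
        default_species_tree(ancestral_Ne=0.0)


def test_default_tau_is_one():
    spec = default_species_tree()
    assert spec.internal_branch_tau(TRIPLET) == pytest.approx(1.0)


def test_with_tau_sets_tau():
    spec = default_species_tree()
    for tau in (0.25, 0.5, 2.0):
        assert spec.with_tau(tau, TRIPLET).internal_branch_tau(
            TRIPLET
        ) == pytest.approx(tau)
    assert math.isinf(spec.with_tau(0.0, TRIPLET).ne_for(TRIPLET))
    with pytest.raises(ValueError):
        spec.with_tau(-0.5, TRIPLET)


# ---------------------------------------------------------------------------
# MSC gene trees
# ---------------------------------------------------------------------------

def _topology_freqs(spec, n, seed):
    rng = np.random.default_rng(seed)
    counts = {"concordant": 0, "ILS_HG": 0, "ILS_PG": 0}
    for _ in range(n):
        counts[triplet_topology(sample_gene_tree(spec, rng))] += 1
    return {k: v / n for k, v in counts.items()}


@pytest.mark.parametrize("tau", [0.0, 0.25, 0.5, 1.0, 2.0])
def test_msc_topology_frequencies(tau):
    """Each discordant class at (1/3)e^-tau within 3 binomial sigma, 1e4 draws."""
    n = 10_000
    spec = default_species_tree().with_tau(tau, TRIPLET)
    freqs = _topology_freqs(spec, n, seed=int(1000 * tau) + 7)
    p_disc = math.exp(-tau) / 3.0
    sigma = math.sqrt(p_disc * (1 - p_disc) / n)
    assert abs(freqs["ILS_HG"] - p_disc) <= 3 * sigma
    assert abs(freqs["ILS_PG"] - p_disc) <= 3 * sigma
    p_conc = 1.0 - 2.0 * p_disc
    sigma_c = math.sqrt(p_conc * (1 - p_conc) / n)
    assert abs(freqs["concordant"] - p_conc) <= 3 * sigma_c


def test_msc_huge_tau_no_discordance():
    spec = default_species_tree().with_tau(50.0, TRIPLET)
    freqs = _topology_freqs(spec, 2_000, seed=5)
    assert freqs["ILS_HG"] == 0.0
    assert freqs["ILS_PG"] == 0.0


def test_msc_against_msprime_oracle():
    """Cross-check the MSC sampler against msprime at tau = 1."""
    import msprime

    tau = 1.0
    n = 5_000
    gen = 20.0
    t_hp, t_hpg = 6.0e6 / gen, 14.0e6 / gen
    # with sim_ancestry(ploidy=1) the pairwise coalescence rate is 1/N per
    # generation, so tau = dt/N here (not dt/2N)
    ne = (t_hpg - t_hp) / tau
    demography = msprime.Demography()
    demography.add_population(name="H", initial_size=100)
    demography.add_population(name="P", initial_size=100)
    demography.add_population(name="G", initial_size=100)
    demography.add_population(name="HP", initial_size=ne)
    demography.add_population(name="HPG", initial_size=ne)
    demography.add_population_split(time=t_hp, derived=["H", "P"], ancestral="HP")
    demography.add_population_split(
        time=t_hpg, derived=["HP", "G"], ancestral="HPG"
    )
    disc = 0
    reps = msprime.sim_ancestry(
        samples={"H": 1, "P": 1, "G": 1},
        demography=demography,
        ploidy=1,
        num_replicates=n,
        random_seed=42,
    )
    for ts in reps:
        tree = ts.first()
        # samples 0, 1, 2 are H, P, G respectively
        first_pair = min(
            [(0, 1), (0, 2), (1, 2)], key=lambda ab: tree.time(tree.mrca(*ab))
        )
        if first_pair != (0, 1):
            disc += 1
    p = 2.0 * math.exp(-tau) / 3.0
    sigma = math.sqrt(p * (1 - p) / n)
    assert abs(disc / n - p) <= 3 * sigma

    ours = _topology_freqs(default_species_tree().with_tau(tau, TRIPLET), n, seed=43)
    ours_disc = ours["ILS_HG"] + ours["ILS_PG"]
    # both estimates target the same closed form; allow combined noise
    assert abs(ours_disc - disc / n) <= 3 * sigma * math.sqrt(2)


def test_gene_tree_leaves_and_lengths():
    spec = default_species_tree()
    tree = sample_gene_tree(spec, seed=9)
    assert sorted(tree.leaf_names()) == sorted(spec.taxa())
    for node in tree.preorder():
        if node is not tree:
            assert node.length is not None and node.length >= 0


# ---------------------------------------------------------------------------
# alignment simulation
# ---------------------------------------------------------------------------

def test_alignment_zero_branches_identical():
    from fusionscape.trees import from_newick

    tree = from_newick("((a:0,b:0):0,c:0);")
    aln = simulate_alignment(tree, HkyParams(), length=200, seed=1)
    seqs = list(aln.sequences.values())
    assert seqs[0] == seqs[1] == seqs[2]
    assert len(seqs[0]) == 200


def test_alignment_negative_branch_rejected():
    from fusionscape.trees import from_newick

    tree = from_newick("(a:-0.1,b:0.1);")
    with pytest.raises(ValueError, match="negative"):
        simulate_alignment(tree, HkyParams(), length=10, seed=1)


def test_alignment_jc_divergence():
    """Path length 0.1, kappa=1, uniform freqs: p approx 0.0936 +- 3 sigma."""
    from fusionscape.trees import from_newick

    tree = from_newick("(a:0.05,b:0.05);")
    params = HkyParams(kappa=1.0, base_freqs=(0.25, 0.25, 0.25, 0.25))
    L = 100_000
    aln = simulate_alignment(tree, params, length=L, seed=12)
    a, b = aln.sequences["a"], aln.sequences["b"]
    p = sum(x != y for x, y in zip(a, b)) / L
    expected = 0.75 * (1.0 - math.exp(-4.0 * 0.1 / 3.0))
    sigma = math.sqrt(expected * (1 - expected) / L)
    assert abs(p - expected) <= 3 * sigma


def test_gamma_shape_inf_is_homogeneous():
    params = HkyParams(gamma_shape=math.inf)
    assert params.category_rates().tolist() == [1.0]


# ---------------------------------------------------------------------------
# window panels
# ---------------------------------------------------------------------------

def test_window_panel_single_window():
    spec = default_species_tree()
    grad = IlsGradientSpec(breakpoint=10_000, background_discordance=0.365)
    panel = simulate_window_panel(spec, grad, 1, seed=3)
    assert len(panel) == 1
    iv, aln, label = panel[0]
    assert (iv.start, iv.end) == (0, 500)
    assert label in ("concordant", "ILS_HG", "ILS_PG")
    assert sorted(aln.sequences) == sorted(spec.taxa())


def test_window_panel_tiles_chromosome():
    spec = default_species_tree()
    grad = IlsGradientSpec(breakpoint=2_000, background_discordance=0.3)
    panel = simulate_window_panel(spec, grad, 10, window_len=400, seed=3)
    for i, (iv, _, _) in enumerate(panel):
        assert (iv.start, iv.end) == (i * 400, (i + 1) * 400)


def test_gradient_spec_rejects_overflow():
    with pytest.raises(ValueError):
        IlsGradientSpec(breakpoint=0, background_discordance=0.6, flank_fold=2.0)


def test_gradient_distal_enrichment():
    """Distal windows carry the elevated discordance by construction."""
    spec = default_species_tree()
    grad = IlsGradientSpec(
        breakpoint=150_000, background_discordance=0.2,
        flank_fold=3.0, flank_span=150_000,
    )
    panel = simulate_window_panel(spec, grad, 600, seed=21)
    prox = [l for iv, _, l in panel if iv.start < 150_000]
    dist = [l for iv, _, l in panel if iv.start >= 150_000]
    f_prox = np.mean([l != "concordant" for l in prox])
    f_dist = np.mean([l != "concordant" for l in dist])
    # 0.2 vs 0.6 with 300 windows/side separates by far more than noise
    assert f_dist - f_prox > 0.2


# ---------------------------------------------------------------------------
# satellite chromosomes
# ---------------------------------------------------------------------------

def test_satellite_pristine_single_array():
    spec = SatelliteSpec(
        monomer="AATTCATTTGAAATGTTTAACCTAACAGTGGA",
        array_lengths=(320,),
        monomer_sub_rate=0.0,
    )
    seq, truth = simulate_satellite_chromosome(spec, seed=1)
    assert seq == spec.monomer * 10
    assert len(truth) == 1
    assert (truth[0].start, truth[0].end, truth[0].name) == (0, 320, "satellite")


def test_satellite_truth_partitions_sequence():
    spec = SatelliteSpec(array_lengths=(10_000, 20_000, 15_000),
                         spacer_length_dist=(5_000, 500))
    seq, truth = simulate_satellite_chromosome(spec, seed=2)
    pos = 0
    for iv in truth:
        assert iv.start == pos
        pos = iv.end
    assert pos == len(seq)
    labels = [iv.name for iv in truth]
    assert labels == ["satellite", "spacer", "satellite", "spacer", "satellite"]


def test_satellite_spacing_by_construction():
    spec = SatelliteSpec.uniform_spacing(3, 287_000)
    _, truth = simulate_satellite_chromosome(spec, seed=3)
    mids = [iv.midpoint for iv in truth if iv.name == "spacer"]
    spacing = np.diff(mids)
    # arrays are rounded up to whole monomers: within one monomer of target
    assert np.all(np.abs(spacing - 287_000) <= 32)


def test_satellite_monomer_identity():
    spec = SatelliteSpec(array_lengths=(64_000,), monomer_sub_rate=0.05)
    seq, truth = simulate_satellite_chromosome(spec, seed=4)
    m = spec.monomer
    ident = np.mean([
        a == b
        for i in range(0, len(seq) - len(m) + 1, len(m))
        for a, b in zip(seq[i : i + len(m)], m)
    ])
    assert abs(ident - 0.95) <= 0.01


def test_satellite_empty_arrays_rejected():
    with pytest.raises(ValueError):
        SatelliteSpec(array_lengths=())


# ---------------------------------------------------------------------------
# methylation tracks
# ---------------------------------------------------------------------------

def test_methylation_exact_levels():
    truth = [
        GenomicInterval("chrT", 0, 10_000, name="satellite"),
        GenomicInterval("chrT", 10_000, 15_000, name="spacer"),
        GenomicInterval("chrT", 15_000, 30_000, name="satellite"),
    ]
    track = simulate_methylation_track(30_000, truth=truth, noise_sd=0.0, seed=1)
    mids = track.midpoints
    in_spacer = (mids >= 10_000) & (mids < 15_000)
    assert np.all(track.frequency[in_spacer] == 0.2)
    assert np.all(track.frequency[~in_spacer] == 0.9)


def test_methylation_dip_is_minimum_window():
    dip = GenomicInterval("chrT", 50_000, 55_000)
    track = simulate_methylation_track(
        100_000, dip=dip, levels=(0.85, 0.2, 0.1), noise_sd=0.02, seed=2
    )
    means = []
    for s in range(0, 100_000, 5_000):
        mask = (track.midpoints >= s) & (track.midpoints < s + 5_000)
        means.append(track.frequency[mask].mean())
    assert int(np.argmin(means)) == 10  # the window containing the dip


def test_methylation_noise_sd():
    track = simulate_methylation_track(
        300_000, noise_sd=0.05, seed=3, site_spacing=25
    )
    assert len(track) >= 10_000
    assert abs(float(np.std(track.frequency)) - 0.05) <= 0.005


def test_methylation_dip_outside_region_rejected():
    with pytest.raises(ValueError):
        simulate_methylation_track(
            1_000, dip=GenomicInterval("chrT", 900, 1_200), seed=1
        )


# ---------------------------------------------------------------------------
# haplotype panels
# ---------------------------------------------------------------------------

def test_panel_theta_zero_no_variants():
    vm = simulate_haplotype_panel(5, 10_000, 0.0, seed=1)
    assert vm.n_sites == 0
    assert vm.n_haplotypes == 5


def test_panel_negative_theta_rejected():
    with pytest.raises(ValueError):
        simulate_haplotype_panel(5, 10_000, -1e-3, seed=1)


def test_panel_two_haplotypes_all_singletons():
    vm = simulate_haplotype_panel(2, 100_000, 1e-3, seed=2)
    assert vm.n_sites > 0
    counts = vm.genotypes.sum(axis=0)
    assert np.all(counts == 1)


def test_panel_watterson_expectation():
    """Mean S over 500 replicates approx theta*L*a1 within 3 SE."""
    n, L, theta, reps = 10, 100_000, 1e-3, 500
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    tl = theta * L
    expect = tl * a1
    var = tl * a1 + tl**2 * a2
    se = math.sqrt(var / reps)
    rng = np.random.default_rng(77)
    s_vals = [
        simulate_haplotype_panel(n, L, theta, seed=rng).n_sites
        for _ in range(reps)
    ]
    assert abs(np.mean(s_vals) - expect) <= 3 * se


# ---------------------------------------------------------------------------
# assembly sets
# ---------------------------------------------------------------------------

def test_assembly_fraction_one_and_zero():
    full = simulate_assembly_set(3, 20_000, 40, query_carries=1.0, seed=1)
    assert full.carried == full.planted
    none = simulate_assembly_set(3, 20_000, 40, query_carries=0.0, seed=2)
    assert none.carried == set()


def test_assembly_planted_unique_everywhere():
    from fusionscape.sunk import build_census

    aset = simulate_assembly_set(4, 30_000, 60, seed=3)
    censuses = build_census(aset.panel, k=aset.k)
    for census in censuses.values():
        for km in aset.planted:
            assert census.get(km) == 1


def test_assembly_carried_count_exact():
    aset = simulate_assembly_set(3, 50_000, 200, query_carries=0.975, seed=4)
    assert len(aset.carried) == math.ceil(0.975 * 200)  # 195
    from fusionscape.sunk import query_presence

    report = query_presence(aset.planted, aset.query)
    assert report.n_detected == 195


def test_assembly_validation():
    with pytest.raises(ValueError):
        simulate_assembly_set(2, 100, 50, k=31, seed=1)  # k-mers exceed genome
    with pytest.raises(ValueError):
        simulate_assembly_set(2, 10_000, 10, k=30, seed=1)  # even k
    with pytest.raises(ValueError):
        simulate_assembly_set(2, 10_000, 10, query_carries=1.5, seed=1)


# ---------------------------------------------------------------------------
# bit-reproducibility
# ---------------------------------------------------------------------------

def test_generators_bit_reproducible():
    spec = default_species_tree()
    t1 = sample_gene_tree(spec, seed=99).newick()
    t2 = sample_gene_tree(spec, seed=99).newick()
    assert t1 == t2

    grad = IlsGradientSpec(breakpoint=1_000, background_discordance=0.3)
    p1 = simulate_window_panel(spec, grad, 3, seed=7)
    p2 = simulate_window_panel(spec, grad, 3, seed=7)
    assert [a.sequences for _, a, _ in p1] == [a.sequences for _, a, _ in p2]
    assert [l for _, _, l in p1] == [l for _, _, l in p2]

    sat = SatelliteSpec(array_lengths=(5_000, 5_000))
    assert simulate_satellite_chromosome(sat, seed=11)[0] == \
        simulate_satellite_chromosome(sat, seed=11)[0]

    m1 = simulate_methylation_track(10_000, noise_sd=0.05, seed=13)
    m2 = simulate_methylation_track(10_000, noise_sd=0.05, seed=13)
    np.testing.assert_array_equal(m1.frequency, m2.frequency)

    v1 = simulate_haplotype_panel(6, 20_000, 1e-3, seed=17)
    v2 = simulate_haplotype_panel(6, 20_000, 1e-3, seed=17)
    np.testing.assert_array_equal(v1.genotypes, v2.genotypes)
    np.testing.assert_array_equal(v1.positions, v2.positions)

    a1 = simulate_assembly_set(3, 20_000, 30, seed=19)
    a2 = simulate_assembly_set(3, 20_000, 30, seed=19)
    assert a1.panel == a2.panel and a1.query == a2.query
    assert a1.planted == a2.planted
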