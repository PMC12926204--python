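"""Satellite arrays, spacer stats, telomeric motifs, methylation windows,
CDR calling, Mann-Whitney comparison, and structural haplotypes."""

import itertools
import math

import numpy as np
import pytest

from fusionscape.formats import GenomicInterval, MethylTrack
from fusionscape.heterochromatin import (
    ArrayAnnotation,
    call_cdrs,
    classify_structural_haplotypes,
    compare_methylation_groups,
    detect_satellite_arrays,
    detect_telomeric_repeats,
    spacer_stats,
    windowed_methylation,
)
from fusionscape.substitution import reverse_complement
from fusionscape.synthdata import (
    DEFAULT_MONOMER,
    SatelliteSpec,
    simulate_methylation_track,
    simulate_satellite_chromosome,
)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# detect_satellite_arrays
# ---------------------------------------------------------------------------

def test_pristine_array_detected_exactly():
    seq = DEFAULT_MONOMER * 50
    ann = detect_satellite_arrays(seq)
    sats = ann.by_label("satellite")
    assert len(sats) == 1
    assert (sats[0].start, sats[0].end) == (0, 1600)
    assert ann.array_lengths == [1600]


def test_random_sequence_false_positive_rate(rng):
    fp = 0
    for _ in range(300):
        seq = _random_seq(rng, 3_000)
        if detect_satellite_arrays(seq).by_label("satellite"):
            fp += 1
    assert fp / 300 < 0.01


def test_boundaries_near_truth_on_simulated_chromosome():
    spec = SatelliteSpec(
        array_lengths=(20_000, 30_000, 25_000),
        spacer_length_dist=(8_000, 500),
        monomer_sub_rate=0.05,
    )
    seq, truth = simulate_satellite_chromosome(spec, seed=10)
    ann = detect_satellite_arrays(seq)
    called = ann.by_label("satellite")
    true_sats = [iv for iv in truth if iv.name == "satellite"]
    assert len(called) == len(true_sats)
    m = spec and len(spec.monomer)
    for got, want in zip(called, true_sats):
        assert abs(got.start - want.start) <= m
        assert abs(got.end - want.end) <= m


def test_detect_validation():
    with pytest.raises(ValueError):
        detect_satellite_arrays("ACGT" * 10, monomer_len=32)
    with pytest.raises(ValueError):
        detect_satellite_arrays("A" * 1_000, max_divergence=0.6)


def test_annotation_invariants():
    with pytest.raises(ValueError):
        ArrayAnnotation(
            intervals=[
                GenomicInterval("s", 0, 100, name="satellite"),
                GenomicInterval("s", 50, 150, name="spacer"),
            ],
            monomer_period=32,
        )
    with pytest.raises(ValueError):
        ArrayAnnotation(
            intervals=[GenomicInterval("s", 0, 100, name="bogus")],
            monomer_period=32,
        )


# ---------------------------------------------------------------------------
# spacer_stats
# ---------------------------------------------------------------------------

def _truth_annotation(truth, period=32):
    return ArrayAnnotation(intervals=list(truth), monomer_period=period)


def test_spacer_stats_uniform_spacing():
    spec = SatelliteSpec.uniform_spacing(5, 287_000)
    _, truth = simulate_satellite_chromosome(spec, seed=11)
    stats = spacer_stats(_truth_annotation(truth))
    assert abs(stats["mean_spacing"] - 287_000) <= 32
    assert stats["modal_length"] == 32_000
    assert stats["n_spacers"] == 5


def test_spacer_stats_modal_length():
    ivs = [
        GenomicInterval("s", 0, 100_000, name="satellite"),
        GenomicInterval("s", 100_000, 132_000, name="spacer"),
        GenomicInterval("s", 132_000, 232_000, name="satellite"),
        GenomicInterval("s", 232_000, 264_000, name="spacer"),
        GenomicInterval("s", 264_000, 364_000, name="satellite"),
        GenomicInterval("s", 364_000, 404_000, name="spacer"),
        GenomicInterval("s", 404_000, 504_000, name="satellite"),
    ]
    stats = spacer_stats(_truth_annotation(ivs))
    assert stats["modal_length"] == 32_000  # {32k, 32k, 40k} -> mode 32k
    # midpoint-to-midpoint oracle
    mids = [116_000, 248_000, 384_000]
    assert stats["mean_spacing"] == pytest.approx(np.mean(np.diff(mids)))


def test_spacer_stats_requires_spacers():
    ann = _truth_annotation([GenomicInterval("s", 0, 1_000, name="satellite")])
    with pytest.raises(ValueError):
        spacer_stats(ann)


def test_spacer_stats_single_spacer_nan_spacing():
    ivs = [
        GenomicInterval("s", 0, 1_000, name="satellite"),
        GenomicInterval("s", 1_000, 2_000, name="spacer"),
        GenomicInterval("s", 2_000, 3_000, name="satellite"),
    ]
    stats = spacer_stats(_truth_annotation(ivs))
    assert math.isnan(stats["mean_spacing"])
    assert stats["n_spacers"] == 1


# ---------------------------------------------------------------------------
# detect_telomeric_repeats
# ---------------------------------------------------------------------------

def test_telomeric_forward_run(rng):
    seq = _random_seq(rng, 100) + "TTAGGG" * 10 + _random_seq(rng, 100)
    runs = detect_telomeric_repeats(seq)
    plus = [r for r in runs if r.strand == "+"]
    assert len(plus) == 1
    assert plus[0].n_units == 10
    assert (plus[0].interval.start, plus[0].interval.end) == (100, 160)


def test_telomeric_reverse_run(rng):
    seq = _random_seq(rng, 50) + "CCCTAA" * 5 + _random_seq(rng, 50)
    runs = detect_telomeric_repeats(seq)
    minus = [r for r in runs if r.strand == "-"]
    assert len(minus) == 1
    assert minus[0].n_units == 5


def test_telomeric_mismatch_budget():
    # TGAGGG is 1 mismatch from TTAGGG: allowed with budget 1, not with 0
    seq = "TTAGGG" + "TGAGGG" + "TTAGGG"
    runs = detect_telomeric_repeats(seq, min_units=3, max_mismatch_per_unit=1)
    assert runs and runs[0].n_units == 3
    assert detect_telomeric_repeats(seq, min_units=3,
                                    max_mismatch_per_unit=0) == []


def test_telomeric_revcomp_mirror(rng):
    seq = _random_seq(rng, 80) + "TTAGGG" * 6 + _random_seq(rng, 80)
    fwd = detect_telomeric_repeats(seq)
    rev = detect_telomeric_repeats(reverse_complement(seq))
    assert len(fwd) == len(rev) == 1
    assert fwd[0].strand == "+" and rev[0].strand == "-"
    assert fwd[0].n_units == rev[0].n_units
    # mirrored coordinates
    assert rev[0].interval.start == len(seq) - fwd[0].interval.end


def test_telomeric_motif_validation():
    with pytest.raises(ValueError):
        detect_telomeric_repeats("ACGT" * 10, motifs=("AT",))


# ---------------------------------------------------------------------------
# windowed_methylation
# ---------------------------------------------------------------------------

def _track(starts, freq, seq_name="chrT"):
    starts = np.asarray(starts)
    return MethylTrack(
        seq_name=seq_name,
        starts=starts,
        ends=starts + 2,
        frequency=np.asarray(freq, dtype=float),
    )


def test_windowed_methylation_constant():
    track = _track(np.arange(0, 10_000, 50), np.full(200, 0.7))
    wm = windowed_methylation(track, window=1_000, step=1_000)
    assert all(v == pytest.approx(0.7) for _, v in wm)


def test_windowed_methylation_per_site_oracle(rng):
    starts = np.sort(rng.choice(5_000, size=120, replace=False))
    freq = rng.random(120)
    track = _track(starts, freq)
    region = GenomicInterval("chrT", 0, 5_000)
    wm = windowed_methylation(track, window=1_000, step=1_000, region=region)
    mids = starts + 1.0
    for iv, v in wm:
        mask = (mids >= iv.start) & (mids < iv.end)
        if mask.any():
            assert v == pytest.approx(float(freq[mask].mean()))
        else:
            assert math.isnan(v)


def test_windowed_methylation_coverage_weighted():
    track = MethylTrack(
        seq_name="chrT",
        starts=np.array([10, 20]),
        ends=np.array([12, 22]),
        frequency=np.array([0.0, 1.0]),
        coverage=np.array([10, 30]),
    )
    ((_, v),) = windowed_methylation(track, window=100, step=100,
                                     region=GenomicInterval("chrT", 0, 100),
                                     coverage_weighted=True)
    assert v == pytest.approx(0.75)


def test_windowed_methylation_validation(rng):
    track = _track([10], [0.5])
    with pytest.raises(ValueError):
        windowed_methylation(track, window=100, step=200)


# ---------------------------------------------------------------------------
# call_cdrs
# ---------------------------------------------------------------------------

def _hor(length=100_000):
    return GenomicInterval("chrT", 0, length)


def test_cdr_recovers_planted_dip():
    dip = GenomicInterval("chrT", 40_000, 50_000)
    track = simulate_methylation_track(
        100_000, dip=dip, levels=(0.9, 0.2, 0.1), noise_sd=0.02, seed=1
    )
    res = call_cdrs(_hor(), track)
    assert res.flag is None
    assert len(res.cdrs) == 1
    assert res.cdrs[0].start == 40_000
    assert res.cdrs[0].end == 50_000


def test_cdr_two_dips():
    track = simulate_methylation_track(
        200_000, dip=GenomicInterval("chrT", 20_000, 30_000),
        noise_sd=0.02, seed=2,
    )
    # add a second dip manually over [150k, 160k)
    mids = track.midpoints
    second = (mids >= 150_000) & (mids < 160_000)
    freq = track.frequency.copy()
    freq[second] = 0.1
    track2 = MethylTrack(track.seq_name, track.starts, track.ends, freq,
                         coverage=track.coverage)
    res = call_cdrs(_hor(200_000), track2)
    assert len(res.cdrs) == 2
    assert res.cdrs[0].overlaps(GenomicInterval("chrT", 20_000, 30_000))
    assert res.cdrs[1].overlaps(GenomicInterval("chrT", 150_000, 160_000))


def test_cdr_flat_profile_flagged():
    track = _track(np.arange(0, 100_000, 25), np.full(4_000, 0.8))
    res = call_cdrs(_hor(), track)
    assert res.cdrs == [] and res.flag == "flat"


def test_cdr_degenerate_profile_flagged():
    # window means {0.5, 0.5, 0.5, 0.9}: Q1 = 0.5 = min, nothing below
    starts = np.arange(0, 20_000, 25)
    freq = np.where(starts >= 15_000, 0.9, 0.5)
    res = call_cdrs(GenomicInterval("chrT", 0, 20_000),
                    _track(starts, freq))
    assert res.cdrs == [] and res.flag == "degenerate"


def test_cdr_invariants_on_simulated_tracks():
    rng = np.random.default_rng(33)
    for _ in range(20):
        start = int(rng.integers(0, 15)) * 5_000
        dip = GenomicInterval("chrT", start, start + 5_000)
        track = simulate_methylation_track(
            100_000, dip=dip, noise_sd=0.03, seed=rng
        )
        res = call_cdrs(_hor(), track)
        means = {iv.start: v for iv, v in res.window_means}
        gmin_start = min(means, key=lambda s: means[s])
        for cdr in res.cdrs:
            # every CDR window mean lies below the lower quartile
            for s, v in means.items():
                if cdr.start <= s < cdr.end:
                    assert v < res.q1
        # the global minimum window is inside some CDR
        assert any(c.start <= gmin_start < c.end for c in res.cdrs)


def test_cdr_validation():
    track = _track(np.arange(0, 2_000, 25), np.full(80, 0.5))
    with pytest.raises(ValueError):
        call_cdrs(GenomicInterval("chrT", 0, 6_000), track)  # < 2 windows
    with pytest.raises(ValueError):
        call_cdrs(_hor(), track, mode="bogus")


# ---------------------------------------------------------------------------
# compare_methylation_groups
# ---------------------------------------------------------------------------

def test_mwu_u_complement():
    rng = np.random.default_rng(4)
    a = rng.random(12).tolist()
    b = rng.random(9).tolist()
    u1, _ = compare_methylation_groups(a, b)
    u2, _ = compare_methylation_groups(b, a)
    assert u1 + u2 == pytest.approx(len(a) * len(b))


def test_mwu_constant_groups_p_one():
    u, p = compare_methylation_groups([0.5] * 8, [0.5] * 8)
    assert p == 1.0


def test_mwu_clear_separation():
    a = list(np.linspace(0.8, 0.9, 30))
    b = list(np.linspace(0.1, 0.2, 30))
    _, p = compare_methylation_groups(a, b)
    assert p < 1e-6


def test_mwu_against_exact_permutation(rng):
    """Tie-free small samples: |p_normal - p_exact| < 0.1."""
    for _ in range(5):
        a = list(np.round(rng.random(6), 6))
        b = list(np.round(rng.random(5), 6))
        u_obs, p_norm = compare_methylation_groups(a, b)
        pooled = a + b
        n1 = len(a)
        mu = n1 * len(b) / 2.0
        count = 0
        total = 0
        for comb in itertools.combinations(range(len(pooled)), n1):
            grp = [pooled[i] for i in comb]
            rest = [pooled[i] for i in range(len(pooled)) if i not in comb]
            u = sum(x > y for x in grp for y in rest) + \
                0.5 * sum(x == y for x in grp for y in rest)
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
            total += 1
        p_exact = count / total
        assert abs(p_norm - p_exact) < 0.1


def test_mwu_window_groups_and_exclusions():
    a_windows = [
        (GenomicInterval("c", i * 1_000, (i + 1) * 1_000), 0.8)
        for i in range(40)
    ]
    b_windows = [
        (GenomicInterval("c", i * 1_000, (i + 1) * 1_000), 0.3)
        for i in range(40)
    ]
    _, p = compare_methylation_groups(a_windows, b_windows)
    assert p < 0.01
    with pytest.raises(ValueError):
        compare_methylation_groups(
            a_windows, b_windows,
            exclude_b=(GenomicInterval("c", 0, 40_000),),
        )


# ---------------------------------------------------------------------------
# classify_structural_haplotypes
# ---------------------------------------------------------------------------

def test_haplotypes_single_class():
    table = {f"s{i}": {"arr1": 100_000 + i} for i in range(4)}
    res = classify_structural_haplotypes(table)
    assert res.n_classes == 1
    assert res.unclassified == []


def test_haplotypes_two_by_two_combinations():
    """Two arrays, each bimodal: four distinct haplotype classes."""
    table = {}
    i = 0
    for l1 in (100_000, 200_000):
        for l2 in (50_000, 150_000):
            for _ in range(2):
                table[f"s{i}"] = {"arrA": l1 + i, "arrB": l2 + i}
                i += 1
    res = classify_structural_haplotypes(table)
    assert res.n_classes == 4


def test_haplotypes_missing_flagged():
    table = {
        "s0": {"arr1": 100_000},
        "s1": {"arr1": None},
        "s2": {"arr1": float("nan")},
    }
    res = classify_structural_haplotypes(table)
    assert sorted(res.unclassified) == ["s1", "s2"]
    assert res.labels["s1"] is None
    assert res.n_classes == 1


def test_haplotypes_five_classes_recovered(rng):
    """Five well-separated length modes in one array: five classes."""
    modes = [100_000, 160_000, 230_000, 320_000, 450_000]
    table = {}
    i = 0
    for m in modes:
        for _ in range(4):
            table[f"s{i}"] = {"arr": m + int(rng.integers(-2_000, 2_000))}
            i += 1
    res = classify_structural_haplotypes(table)
    assert res.n_classes == 5
    # samples sharing a mode share a label
    for m_idx, m in enumerate(modes):
        labels = {res.labels[s] for s, v in table.items()
                  if abs(v["arr"] - m) < 10_000}
        assert len(labels) == 1


def test_haplotypes_validation():
    with pytest.raises(ValueError):
        classify_structural_haplotypes({})
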