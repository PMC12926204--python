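# Methods

This document describes the statistical models behind `fusionscape`, the
meaning and defaults of every generator parameter, what the synthetic data
emulate (and deliberately do not), the numerical choices in the analysis
code, and known limitations.

## Overview

The package studies the genomic landscape around an ancestral chromosome
fusion in great apes: elevated incomplete lineage sorting (ILS) distal to
the fusion point, satellite/spacer heterochromatin architecture,
centromere dip regions (CDRs) in methylation profiles, singly unique
nucleotide k-mers (SUNKs) as presence markers, segmental-duplication
synteny, and molecular dating. Every analysis is paired with a generator
that simulates data with the statistical structure the analysis assumes,
so all quantitative claims can be verified end to end against known truth.

## Coalescent model and units

Gene trees are drawn under the multispecies coalescent (MSC) on a fixed
species tree. Within each ancestral population, uncoalesced lineage pairs
coalesce at rate `1/(2·Ne)` per generation (`Ne` is the diploid effective
population size), time flows tip-to-root, and lineages that fail to
coalesce on an internal branch are passed to the parent population.

The key dimensionless quantity is the internal branch length in coalescent
units:

```
tau = (delta_t_years / generation_time) / (2 * Ne)
```

For a rooted triplet whose internal branch has length `tau`, the
probability of each of the two discordant gene-tree topologies is
`exp(-tau)/3`, so total discordance is `(2/3)·exp(-tau)`. This closed form
(`ils.expected_discordance`) is the oracle for the whole windowed scan.

## Species-tree defaults

`synthdata.default_species_tree()` returns:

| parameter | default | why |
| --- | --- | --- |
| topology | `(((human,(chimpanzee,bonobo)),gorilla),macaque)` | the accepted great-ape arrangement with a macaque outgroup |
| split times | 2.5 / 6 / 14 / 20 Mya | Pan split, human–Pan, gorilla, outgroup root (years) |
| generation time | 20 y | round great-ape value |
| mutation rate | 1.0e-7 /site/generation | calibrated, see below |
| ancestral Ne | 600,000 (deep branches), 200,000 default | diploid individuals; the human–Pan ancestral branch (6–14 Mya) with Ne = 200,000 gives tau = 1 |

Two defaults are deliberately calibrated rather than biological:

- **Mutation rate 1e-7.** With a textbook 2.5e-8, 500 bp windows carry so
  few substitutions on the short internal branches that distinguish
  topologies that per-window calls degenerate toward random thirds,
  violating the generator's contract that the simulated data support the
  analyses run on them. The MSC discordance probabilities being recovered
  are functions of `tau` alone and are unaffected by this choice.
- **Outgroup root at 20 Mya.** A deeper root lengthens the outgroup branch
  until homoplasy on it biases per-window maximum-likelihood calls toward
  excess discordance; 20 Mya keeps that bias inside the scan's statistical
  tolerance while keeping call accuracy above 90% at `tau = 1`.

`SpeciesTreeSpec.with_tau(tau, clade)` rescales one branch's Ne to hit an
exact `tau`, which is how the recovery experiments fix the quantity under
test.

## Sequence evolution

Alignments evolve down a gene tree under HKY (transition/transversion
ratio `kappa`, default 4.0; base frequencies default (0.3, 0.2, 0.2,
0.3)), with optional discrete-gamma rate variation (mean-one categories,
default 4). Branch lengths are substitutions/site; the MSC sampler
converts generations to substitutions via the mutation rate. Transition
matrices come from the HKY eigendecomposition; sites are independent.

## Breakpoint-polarized window panels

`simulate_window_panel` tiles a chromosome with non-overlapping windows
(default 500 bp). Each window's gene tree is discordant with probability
equal to the background (proximal of the breakpoint) or background × fold
(distal, within `flank_span`); discordance is induced by setting the
focal-branch `tau` per window to match the target probability. Windows are
independent — the generator does not emulate linkage or recombination hot
spots; the target of the downstream pipeline is the marginal discordance
proportion, for which independence is the conservative case.

## Windowed topology scan

`ils.scan_windows` classifies each window by maximum likelihood over the
three resolved quartet topologies of {human, Pan, gorilla, outgroup}. For
throughput, site patterns from all windows are pattern-compressed and
pooled, and the five branch lengths of each candidate pairing are
optimized for all windows simultaneously by vectorized golden-section
coordinate ascent (3 sweeps, tolerance 1e-6, branch lengths in
[1e-8, 2]). Windows with fewer than 3 variable sites are `unresolved`
(no likelihood-margin filter by default).

`ils_proportion` reports the discordant fraction with a Wilson 95% CI,
over resolved windows by default (an `"all"`-windows denominator is also
available). `polarity_contrast` is a label-permutation test of the
distal-minus-proximal discordance difference.

## Satellite, methylation, and haplotype generators

- **Satellite chromosomes**: tandem arrays of a 32 bp AT-rich monomer
  (per-monomer substitution rate 0.05) separated by random spacers; array
  lengths round up to whole monomers. `SatelliteSpec.uniform_spacing`
  builds architectures with a prescribed spacer-midpoint spacing (e.g.
  287 kbp). Higher-order repeat structure and transposon insertions are
  not emulated.
- **Methylation tracks**: CpG-like sites every 25 bp, frequency levels
  (satellite 0.9, spacer 0.2, dip 0.1) plus Gaussian noise, clipped to
  [0, 1]. Read-level stochasticity and coverage variation are not
  emulated; coverage is constant.
- **Haplotype panels**: infinite-sites coalescent with parameter `theta`
  per site (`S ~ theta·L·a1` in expectation); no recombination within the
  simulated region.
- **Assembly sets**: panels of random genomes with `n` k-mers planted
  once in every panel genome. Plant boundaries are flanked by a
  per-genome pinned base so that no k-mer straddling a junction can
  coincide across all genomes (otherwise junction k-mers become
  accidental SUNKs at a rate of about `4^-j(n-1)` per junction). The
  query carries a fixed fraction of the planted set (`ceil`), making
  reported percentages exact.

## Analysis numerics

- **Nucleotide diversity**: per-site unbiased heterozygosity
  `2p(1-p)·n/(n-1)` summed over sites, divided by window length, with
  site-wise complete-case handling of missing genotypes. **Tajima's D**
  uses the standard a1…e2 constants; D is NaN when a window has no
  segregating sites and requires at least 4 haplotypes — at n = 3 the
  variance constants vanish identically (c1 = c2 = 0), so D is 0/0.
- **Identity matrices**: canonical k-mer (k = 21) containment
  `c = |A∩B|/min(|A|,|B|)` converted to ANI as `c^(1/k)`.
- **Satellite detection**: lag-`monomer` autocorrelation proposes
  candidate regions; each is refined against its consensus monomer, with
  array bounds at the first/last monomer within 15% divergence on the
  candidate phase.
- **CDR calling**: non-overlapping 5 kbp window means over the HOR; runs
  below the lower quartile are kept only when anchored within 25% of the
  gap between Q1 and the global minimum (suppresses shallow noise runs).
  Flat profiles and degenerate plateaus are flagged instead of called.
- **Mann–Whitney U**: computed from ranks with tie correction and a 0.5
  continuity correction on the normal approximation; all-tied input gives
  p = 1. Methylation groups are collapsed to 17.1 kbp chunk means
  stepping by half a chunk before testing.
- **Neighbor joining** is delegated to scikit-bio and is exact on
  additive matrices. **Robinson–Foulds** uses explicit bipartition sets.
- **Strict-clock dating**: a single rate is least-squares fitted through
  the origin to calibrated node depths (mean node-to-tip path length);
  ages are depths divided by the rate. Confidence intervals come from a
  column bootstrap (distance re-estimation + NJ per replicate). Outgroup
  rooting for dating uses the clock-consistent position on the outgroup
  edge (equal mean tip depth on both sides), because the naive midpoint
  systematically inflates the root age whenever the ingroup is deep. This
  is a fast surrogate for Bayesian dating: point estimates are unbiased
  under the clock, but intervals ignore rate-variation uncertainty and
  should be read as narrower than a full Bayesian posterior.

## Problem sizes

Sizes below are this package's own choices, set to fit a single-CPU time
budget while keeping statistical power:

- MSC recovery: 2,000 windows of 500 bp per `tau` in {0.25, 0.5, 1}.
- Gradient recovery: 5 replicates of 2,500 windows per side
  (background 0.365, fold 1.39); at this size the per-replicate fold
  standard error is ≈ 0.05, leaving ≈ 3σ margin to the acceptance bounds.
- Oracle cross-checks: 1,000 random instances per statistic.
- CDR recovery: 200 random planted-dip tracks of 100 kbp.
- Dating: 12 replicates of 10 kbp alignments.

## Limitations

- Windows are simulated independently; spatial autocorrelation of ILS
  along real chromosomes is not modelled.
- The quartet engine assumes one shared HKY parameterization across
  windows; per-window model fitting is out of scope.
- The infinite-sites haplotype generator has no recombination, so
  linkage-sensitive statistics should not be read beyond single windows.
- Bootstrap dating intervals understate uncertainty relative to Bayesian
  methods (no rate-variation or topology averaging).
- K-mer censuses are held in memory; whole-genome-scale censuses at
  multi-gigabase sizes are out of scope.
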