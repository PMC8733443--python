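# Methods

## Problem setting

In an advanced intercross line (AIL) descending from two fully inbred
founders, every autosomal locus segregates exactly two founder alleles.  A
heterozygous parent is expected to transmit either allele to an offspring
with probability 1/2.  Systematic departures from this ratio —
transmission ratio distortion (TRD) — arise from meiotic drive, gamete
competition, or selection against particular allele combinations
(Bateson–Dobzhansky–Muller, BDM, incompatibilities).  This package
implements the statistical machinery to detect TRD from trio genotypes,
to localise it into regions, to test region pairs for two-locus
incompatibilities, and to ask whether the implicated genes are unusually
rich in protein-altering variants.  A forward simulator with injectable
drive and viability selection provides ground truth for every stage.

## Data model

Genotypes are founder-polarized: `HOM_A` is homozygous for founder 1's
allele (the BFMI-like line in the motivating cross), `HOM_B` for founder
2's (B6N-like), with `HET` and `MISSING` completing the code set.
Polarization happens at load time against the two founder samples; markers
where the founders carry the same allele are flagged uninformative and
excluded from all tests, because no transmission can be resolved at them.
Coordinates are 1-based inclusive base pairs internally; BED export
converts to 0-based half-open.

## Trio QC

Trios are built per generation from the pedigree; a child enters only if
both parents are known and genotyped.  Parent misassignment is detected
from the Mendelian-error fraction: the share of complete, informative
markers at which the child's genotype is impossible given the two parental
genotypes (e.g. a `HOM_B` child of a `HOM_A` parent).  A trio exceeding the
threshold (default 0.05) is removed together with all its pedigree
descendants, since offspring of a wrongly assigned parent inherit the
uncertainty.  The threshold is a free parameter: genotyping error inflates
the baseline rate, and 0.05 cleanly separates true parents (rate ~ the
genotyping error rate) from impostors (rate typically 0.1–0.5 on simulated
data; close relatives of the true parent can evade detection, which is a
limitation of any Mendelian-only check).  Marker-level QC removes markers
below a 90% call rate and uninformative markers.

## Transmission asymmetry test

For one focal parental sex, transmissions are counted at each marker over
all trios whose focal parent is heterozygous.  The transmitted allele is
resolvable only when the co-parent is homozygous: the child's genotype then
pins down the focal parent's contribution.  Double-heterozygous matings are
tallied and excluded — the transmitted allele cannot be determined —
rather than probabilistically imputed, keeping the test free of phasing
assumptions.  With `n_A` and `n_B` resolved transmissions of the two
founder alleles, the statistic is

    chi2 = (n_A − n_B)² / (n_A + n_B),

referred to the 1-df chi-square upper tail, and reported as
LOD = −log10(p).  No continuity correction is applied; the statistic is
implemented exactly in the printed form.  P-values below the smallest
positive double (≈5e−324) are floored there and the result flagged
`lod_capped`.

Eligibility requires (i) founder informativeness, (ii) ≥ 10 heterozygous
parents of the focal sex (below that the test is hopelessly underpowered),
and (iii) Hardy–Weinberg equilibrium in the offspring generation.  The HWE
gate matters scientifically: embryonic lethality distorts offspring
genotype frequencies and would masquerade as TRD, so loci out of HWE are
excluded rather than tested.  The HWE p-value comes from the exact
conditional test (enumeration of all heterozygote counts given the allele
counts, two-sided by summing configurations no more probable than the
observed one), computed by the standard numerically stable recurrence.
`hwe_alpha` defaults to 0.01.

Marker-level distortion is summarised as the signed percent excess over
the Mendelian expectation,
`100 · (n_A − (n_A+n_B)/2) / ((n_A+n_B)/2)`, positive for founder-A excess.

### Significance thresholds

The default genome-wide LOD thresholds are 6.75 (5%) and 7.45 (1%), the
published constants for this family of mouse AIL scans; they are config
values, not derived quantities, because the Bonferroni denominator behind
them is not reconstructible from the stated marker counts.
`bonferroni_lod_threshold(alpha, n_tests) = −log10(alpha/n_tests)` lets a
user derive thresholds matched to their own scan size, and the simulated
analyses in the test-suite do exactly that.

### Region calling

Map-ordered markers with LOD at or above the 1% threshold and a common
preferred allele are merged into regions.  Two design choices are genuinely
open and made here as follows: a run tolerates an intervening sub-threshold
stretch of at most `max_nonsig_run = 3` markers (a single noisy marker
should not split an obviously continuous signal), and consecutive
significant markers must lie within `merge_gap_bp = 5 Mb`.  Both are
configurable.  The top marker is the LOD maximum; ties within 1e−9 resolve
to the proximal (smaller-bp) marker, so a plateau of equally distorted
markers is anchored at its proximal flank.  Per-region means and SDs of
`n_A`/`n_B` are computed over member markers; consistent distortion shows
up as small SDs.

## Pairwise incompatibility scan

For every unordered pair of TRD regions on *different* chromosomes, a 3×3
contingency table of joint genotype classes at the two regions' top markers
is built over the offspring generation (individuals missing at either
marker drop out).  Expected counts are the outer product of the marginals
divided by n — the independent-segregation null.  The test statistic sums
(O−E)²/E over cells with E > 0, with df = (r−1)(c−1) over non-empty
marginal classes (4 for a full table), and is reported as a LOD.  Pairs on
the same chromosome are emitted as `not_tested`: linked loci never
segregate independently, so the null is meaningless there.  The cell with
the largest percent deficit 100·(E−O)/E is reported as the most-reduced
combination — the candidate disadvantaged genotype pairing; ties resolve
toward the larger expected count.  No minimum expected count is enforced,
but a warning is emitted when any E < 5.

Degrees-of-freedom caveat: the chi-square reference assumes independent
individuals.  Litter structure and drift-generated associations between
unlinked loci in a finite breeding population inflate the statistic
somewhat; the genome-wide threshold below absorbs this in practice, but
nominal per-pair p-values should not be over-interpreted.

### Effective number of tests (simpleM-style)

Linked markers are redundant, so Bonferroni correction over raw marker
counts is too strict.  Per chromosome, markers are split into consecutive
blocks of at most `fix_length` (default 1200); for each block the
eigenvalues of the genotype-dosage correlation matrix (0/1/2 coding,
pairwise-complete over missing calls) are computed, and the block
contributes the smallest k whose top-k eigenvalues reach
`variance_fraction` (default 0.995) of the total.  The genome-wide
`n_effective` is the block sum.  The composite-LD flavour of the original
procedure is approximated by plain dosage correlation; with one block per
chromosome the result equals a direct whole-matrix eigen-decomposition,
which the tests verify.

The pair-scan threshold is `−log10(alpha / (n_eff² · 0.5))`: the pair count
is written as n_eff·n_eff·0.5, reproducing the published constants 7.0
(α = 0.05) and 7.7 (α = 0.01) at n_eff = 1008 exactly.  A strict
n_eff(n_eff−1)/2 variant is available (`strict_pairs=True`) but off by
default; at n_eff ≈ 1000 the two differ by < 0.001 LOD.

## nsSNP enrichment

Given a gene annotation with per-gene nonsynonymous SNP counts and the set
of genes overlapping TRD regions (overlap of ≥ 1 bp with the region
interval), the permutation test draws equally many distinct non-predicted
protein-coding genes uniformly (predicted genes are recognised by the
Gm####/…Rik symbol convention, configurable) and records the summed nsSNP
count per draw.  The empirical p-value uses the (r+1)/(n+1) estimator so it
is never exactly zero; with 50,000 permutations the smallest reportable
value is 1/50,001 ≈ 2×10⁻⁵.  The null mean of a without-replacement sum is
(draw/universe)·total, which the tests check against the Monte-Carlo
estimate.  The draw size defaults to the observed gene count and is
configurable, as published descriptions of comparable analyses are
ambiguous on this point.  Excess is reported as
`100·(observed − null_mean)/null_mean`.

A generic hypergeometric overrepresentation test (upper tail, BH-corrected
across all supplied gene sets) and a PPI-edge overlay complete the module.
The overlay keeps an edge only if both genes carry ≥ 1 nsSNP, lie in
different regions on different chromosomes, and a pair of their regions is
among the significant incompatibilities — same-chromosome edges are
dropped because the pair test is undefined for linked loci.

## Forward AIL simulator

Founders are fully homozygous and opposite at every marker; the F1 is
uniformly heterozygous; each later generation is formed by random
male–female pairings avoiding full siblings where possible (a pragmatic
stand-in for kinship-minimising mating software, whose exact algorithm is
not public), each producing a fixed litter size.  Meiosis follows a
Haldane (no-interference) model: the crossover count per chromosome is
Poisson with mean L/100 for a length of L cM, crossover positions are
uniform, and the starting haplotype is fair.  Marker positions are evenly
spaced in cM and mapped to bp at 2 Mb/cM, a round figure near the mouse
genome-wide average, so region outputs carry realistic coordinates.

Drive is implemented by rejection sampling of whole gametes: for a
heterozygous carrier, a gamete carrying founder allele A at the driver
locus is accepted with probability τ/max(τ,1−τ) and a B-gamete with
(1−τ)/max(τ,1−τ), giving a marginal transmission probability of exactly τ
while preserving linkage between the driver and its flanking markers —
which is what makes simulated TRD regions spatially coherent, as in real
data.  Two-locus viability selection accepts each conceived offspring with
probability equal to the product of the 3×3 viability entries over injected
pairs, retrying a litter slot up to 100 times before it is lost; a
generation that produces no survivors (or lacks one sex) raises an
extinction error rather than looping forever.

What the generator does *not* emulate: genotyping error (QC thresholds are
tested against clean calls plus injectable missingness only), mutation,
recombination interference and hotspots, X/Y/mito inheritance, unequal
litter sizes, and selection on polygenic phenotypes.  Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated model, not robustness to array-level artefacts.

### Problem sizes used in the verification suite

The checked analyses run at desk scale, chosen so each completes in
seconds while retaining the qualitative structure of a real AIL:

* **Null calibration** — 20 replicates of one 200-marker, 100 cM
  chromosome, 6 generations, with a 660-trio final generation; the
  fraction of marker tests with p < 0.05 must land in [0.03, 0.07].  The
  per-marker resolved count (~160) matters here: the chi-square test on a
  discrete binomial oscillates around its nominal size, and very small
  counts push it outside the band.
* **Drive recovery** — one 100-marker, 60 cM chromosome with a τ = 0.7
  driver at its centre and a 4,800-trio final generation, giving > 2,000
  informative meioses at the driver; the distortion estimate must cover
  the theoretical +40% within its 95% binomial CI and the region caller
  must return a single region containing the driver.
* **Incompatibility round trip** — three 30-marker chromosomes, a lethal
  (viability 0) HOM_A×HOM_B cell for one unlinked marker pair, and a
  1,800-trio final generation; exactly the injected pair must exceed the
  LOD 7.0 genome-wide bar with the injected cell as its most-reduced
  combination.  The breeding population is kept at 600 per generation:
  smaller populations accumulate drift LD between unlinked loci, which —
  together with litter clustering — can push null pairs over genome-wide
  thresholds.  That behaviour is a property of the design, not a bug, and
  is worth remembering when interpreting borderline pairs in real data.

## Numerical choices

* HWE probabilities by two-sided recurrence from the modal heterozygote
  count; comparison tolerance 1+1e−12 on the observed probability to keep
  ties stable against rounding.
* p-values floored at 5e−324 (LOD capped ≈ 323.3, flagged).
* Region-member SDs use ddof = 1 (ddof = 0 for singleton regions).
* Eigenvalues clipped at 0 before cumulative sums; a `searchsorted` with
  1e−12 slack avoids off-by-one at exact variance fractions.
* All simulator randomness flows from one `numpy.random.default_rng(seed)`;
  identical config ⇒ bit-identical outputs.

## Known limitations

* Transmission resolution discards double-heterozygous matings (~25% of
  matings at intermediate allele frequencies); statistical phasing could
  recover some of them at the cost of model assumptions.
* The pair test treats siblings as independent; see above.
* The misassignment check cannot see an impostor who is a close relative
  of the true parent.
* Thresholds 6.75/7.45 are adopted constants; users scanning different
  marker panels should derive their own via `bonferroni_lod_threshold`.
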