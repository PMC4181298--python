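# Methods

This note documents the statistical conventions, the synthetic-data
model, and the design choices made where the design was genuinely open.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and formats

Internally every interval is 0-based half-open; VCF and GFF3 coordinates
(1-based inclusive) are converted at the format boundary and nowhere
else. The one exception is `VariantRecord.pos`, which keeps the VCF
1-based position because variant sites are keyed and reported in VCF
coordinates throughout. Indels are parsed and counted but excluded from
π, Hp, the tree and haplotype sharing, all of which are SNP statistics;
indel heterozygosity rates are reported but genotyping conventions for
indels differ between callers, so they should be read as
convention-dependent. Gene strand is carried but ignored by overlap
queries: selected loci are strand-agnostic.

## Cross-accession retention filter

A site is retained iff the variant allele is *present* (genotype het or
hom_alt — hom_ref and missing are not presence) in at least
`min_accessions` (default 2) accessions, or present in exactly one
accession with strictly more than `min_reads` (default 10) supporting
reads. "Strictly more" follows the usual phrasing "above 10 reads";
whether the single-carrier threshold counts variant-supporting reads or
total site depth is ambiguous in published pipelines, so
`support="alt"` (default) vs `support="depth"` is an explicit switch.
The filter is monotone: adding an accession can only add retained sites.

## Heterozygosity rate

`het_rate` divides an accession's heterozygous calls by its *own*
variant-site count (sites where it carries the variant allele), not by a
panel-wide union; an accession with no variant sites reports NaN, not 0.
This is the statistic under which recent F1 hybrids sit near 0.25–0.5
while selfing wild/cultivated lines sit below 0.05.

## Nucleotide diversity (π)

Per segregating site the probability that one allele drawn from line *i*
and one from line *j* differ is `f_i(1−f_j) + f_j(1−f_i)` with `f` the
variant-allele dosage/2; the per-site value is the mean over all
unordered line pairs, summed over sites and divided by the **whole
reference length** (a `callable_length` override exists — the
whole-genome denominator understates π but is the convention genome-wide
surveys print). Three conventions worth calling out:

* heterozygous genotypes contribute via dosage rather than being
  excluded — excluding them would bias π downward exactly for the highly
  heterozygous semi-wild material; `het_mode="exclude"` restores the
  stricter convention, in which the excluded genotype's pairs are
  skipped at that site and the mean is over observed pairs;
* a line with *no record* at a site counts as homozygous reference
  (variant-only call-set convention) — call sets carry no explicit
  missing genotype, so absence cannot be distinguished from hom_ref;
* the vectorised implementation is checked exactly against an
  independent O(sites × pairs) double loop.

## Pooled-heterozygosity sweep scan

1. **Depth normalisation.** Lines are thinned toward a common target
   depth (default 4×) by independent binomial sampling of the major and
   minor counts with retention probability target/mean — the count-level
   equivalent of subsampling reads, identical in expectation. Lines at
   or below target are left unchanged.
2. **Pooling.** Counts are summed per population; the major allele is
   the larger pooled count (ties to reference). Sites with pooled depth
   outside the inclusive gate [10, 500] are dropped (noise floor /
   collapsed repeats). Sites monomorphic in one pool but variant in the
   panel union are **retained** — depressed minor-allele mass is the
   sweep signal; sites variant in no line never enter the union.
3. **Windows.** 100 kb windows sliding by 50 kb, tiled from 0 per
   chromosome, last window truncated. `Hp = 2·ΣnMAJ·ΣnMIN/(ΣnMAJ+ΣnMIN)²`
   lies in [0, 0.5], reaching 0.5 iff the pooled counts balance.
   Windows with fewer than `min_sites = 10` SNPs get Hp = NaN and stay
   out of the Z distribution — near-empty windows otherwise produce
   spurious extremes.
4. **Standardisation and calling.** Z uses the genome-wide mean and the
   population (divisor-N) standard deviation per pool; the sample/
   population distinction is negligible at genome scale but is fixed for
   exactness. Windows with Z strictly below −4 are merged when
   overlapping or adjacent on the step grid; the region's Z is its most
   extreme window. A cultivated region survives the differential screen
   iff no overlapping wild or semi-wild window has Z strictly below −2.
   Merging overlapping significant windows into loci is the only
   convention that avoids double-counting the 50 kb-step overlaps.

**A scale caveat that matters for simulation studies.** Z(Hp) is a
*relative* outlier statistic: if a fraction *f* of windows is maximally
depressed, no window can fall below −√((1−f)/f). Sweeps must therefore
occupy well under 1/17 ≈ 6 % of window mass for a −4 cut-off to be
attainable at all. On a ~1 Gb genome a realistic sweep load is a
fraction of a percent and the cut-off behaves as intended; on the
desk-scale 20 Mb panels used here, five 300 kb sweeps already exceed the
bound, so recovery demonstrations use two injected sweeps (plus one
shared) — below the bound, where every injected sweep is recovered at
Z < −4. Passing those tests shows the scan's machinery is correct; it
does not show that −4 is an appropriate threshold for any particular
genome size and sweep load, which the bound above makes explicit.

## Coverage set algebra

"Mapped" means depth ≥ `min_depth` (default 1); the tracks are
run-length encoded and all operations work on maximal interval runs,
verified against per-base boolean sweeps in the tests. Defaults follow
the two conventions the analyses use: ≥ 100 bp for specific/common
sequence extraction, and strictly > 1 kb for the large-unmapped-region
summary (with a > 10 kb sub-count). The wild-specific pipeline of the
original study design (unmapped reads → de novo contigs screened against
cultivars) is represented by running `uncovered_by_all` over cultivar
tracks aligned to a supplied wild-contig reference; assembly itself is
out of scope.

## Population structure

**Tree-SNP selection** applies three filters in order, reporting
stage-wise attrition: (1) depth ≥ 3 in *every* line (a missing call
fails), (2) drop any locus heterozygous in any line — the whole locus,
not just that genotype, because the tree needs a complete haplotype-like
matrix (`het_policy="drop_genotype"` gives the per-genotype alternative),
(3) drop *both* members of any surviving pair within 50 bp on a
chromosome, scanning retained candidates in position order. Stage
outputs are nested by construction.

**Distances and tree.** p-distance (share of differing loci,
pairwise-complete) feeds Saitou–Nei neighbor joining via scikit-bio;
negative branch lengths are clamped to zero (on additive matrices none
arise, and NJ then reproduces all path lengths exactly — the tests check
this to 1e−9). The distance model fed to NJ is not dictated by any
convention here; p-distance is the default and the `DistanceMatrix`
input makes alternatives trivial. Bootstrap support resamples loci with
replacement and reports, per internal branch of the full-data tree, the
fraction of replicate trees containing its bipartition; seeded and
deterministic.

**Evanno ΔK.** With replicate curves L_r(K) (rank-paired within K;
replicate counts must match), ΔK(K) = mean_r |L_r(K+1) − 2L_r(K) +
L_r(K−1)| / sd_r(L_r(K)), defined for interior K only, NaN (with a
warning) where the replicate sd is zero, and invariant to adding a
constant to all lnP values. The clustering inference itself (STRUCTURE's
MCMC) is out of scope; ΔK consumes a user-supplied table.

**Haplotype sharing** declares a group shared iff all members' genotype
vectors are identical with no missing entries (missing is a mismatch),
returning the distinct haplotype strings observed.

## The synthetic panel generator

The generator emulates the three-population study design rather than a
coalescent: its purpose is truth-labelled inputs for every pipeline
stage, not demographic realism.

* **Genome.** Default 20 chromosomes × 1 Mb. Ancestral biallelic SNPs
  are placed uniformly at density 0.015/bp with alternate-allele
  frequencies from Beta(0.2, 0.2) — a U-shaped spectrum that produces a
  realistic rare-allele load without coalescent machinery, and puts wild
  π near 2×10⁻³ substitutions/site, the magnitude typical of wild
  soybean panels.
* **Populations.** Default 19 wild, 10 semi-wild, 14 cultivated lines
  (the composition of the real panels this emulates) at mean depth 4×.
  Wild and cultivated genotypes are drawn with inbreeding coefficients
  0.95 / 0.99 (soybean is predominantly selfing; wild outcrossing runs a
  few percent), giving wild het rates below 0.05. Cultivated frequencies
  pass a bottleneck: each polymorphism survives with probability 0.6,
  survivors are drift-perturbed (Beta with concentration 4), losses are
  fixed — depressing cultivated π to roughly 0.6 of wild.
* **Sweeps.** Configurable segments forced monomorphic for the major
  allele in the cultivated pool (optionally also in wild, for
  shared-sweep negatives), recorded in the truth set. Before read noise
  the swept counts are exactly monomorphic; with noise the pooled
  minor-allele fraction stays below twice the error rate.
* **Hybrids.** Semi-wild lines are F1 (one wild + one cultivated gamete
  from randomly chosen parents) or F2 (one selfing meiosis with exactly
  one crossover per chromosome at a uniform position — a deliberate
  simplification adequate for het-rate and mosaic structure, not for LD).
  The truth set stores each hybrid's expected het fraction among its
  variant sites, computed from the realized parental gametes.
* **Reads and coverage.** Per-site depth ~ Poisson(4); alternate-read
  counts ~ Binomial(depth, f) with f = (g/2)(1−e) + (1−g/2)e at
  base-call error e = 0.01, which gives pools a realistic nonzero Hp
  floor. Per-base coverage tracks are piecewise constant over 1 kb tiles
  with Poisson tile depths, sampled independently of the per-site
  variant depths (a simplification: the two views are separately, not
  jointly, calibrated). Lineage-specific segments have zero depth — and
  no variant records — in non-carrier lines; semi-wild lines carry both
  lineages' segments by default, as hybrids do.
* **Determinism.** All randomness flows from one seed through named
  child streams; identical configs produce byte-identical file bundles.

What passing tests on this generator shows: the filters, statistics and
set operations compute what they claim on data with known truth. What it
does not show: robustness to alignment artefacts, indel-rich regions,
depth heterogeneity along the genome, linkage disequilibrium, or
population structure beyond the three-pool design.

The emitted bundle (reference FASTA, per-accession VCFs with GT/DP/AD —
including hom_ref records wherever the line has reads, so per-line
coverage is known at every site — samtools-style depth TSVs, panel TSV,
truth BEDs/JSON) round-trips through the package's own readers; this is
itself under test.

## Problem sizes used in the checks

The unit suite runs on panels of a few hundred kb; the end-to-end sweep
demonstrations use 20 Mb three-pool panels with 8–10 lines per pool,
and the acceptance script uses the same scale — chosen so wild π, het
contrasts and window counts are estimated stably while the whole battery
remains a desk-scale computation. The ΔK lnP tables use K = 2–9 with 8
replicates and Gaussian replicate noise (sd 0.5) around a piecewise
linear mean with its slope break at the true K.

## Known limitations

* The whole-genome π denominator ignores callability; use
  `callable_length` when comparing across datasets with different depth.
* The sweep scan reports no significance beyond the Z threshold; the
  −4/−2 cut-offs are conventions, and their attainability depends on
  genome size and sweep load (see the scale caveat above).
* `uncovered_by_all` treats a single unmapped base as evidence of
  absence at depth floor 1; raising `min_depth` trades sensitivity for
  robustness to mapping dropouts.
* ΔK requires balanced replicate counts and is undefined at boundary K;
  it cannot distinguish K = 1 from K = 2 by construction.
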