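# Methods

## The measurement problem

In a cross of two near-isogenic strains (maternal "strain A" ≙ *w1*-like,
paternal "strain B" ≙ *CaS*-like), every maternally deposited mRNA
carries strain-A alleles, while zygotic transcription draws on both
parental chromosomes.  A read overlapping a site fixed between the
strains is therefore assignable to a parental chromosome, and
paternal-allele reads are unambiguous evidence of zygotic origin.  The
package turns this into per-gene maternal/zygotic decomposition over an
8-point developmental axis (mitotic cycles C10–C13 and cellularization
substages 14A–14D, indexed t = 0…7; no wall-clock times are attached),
and into female:male comparisons of zygotic transcription on the X.

## SNP calling

Per-strain pileups (`chrom pos ref A C G T N`, 1-based) are reduced to a
consensus per position: call the most common base if A+C+G+T depth
≥ `min_depth` (13) and its frequency is ≥ `min_major_freq` (0.95);
otherwise no-call with reason `low_depth` or `polymorphic` (an exact tie
can never reach 95%, but a `tie` branch exists defensively).  Ambiguous
(N) reads are excluded from the denominator — the conservative reading
of "frequency of the most common base"; whether the original filter
counted all or only high-quality bases is unknowable from the outside,
and we count all tabulated bases.  A position is a fixed SNP when both
strains yield a consensus and the bases differ.  Both boundaries are
inclusive ("at least"): depth 13 and frequency exactly 19/20 pass.
Raising either threshold can only remove records (monotone filtering).
Sites with adequate depth that fail the 95% rule are reported in a side
table as residual within-strain polymorphism; nothing downstream uses
them.  SNP-in-gene counting intersects SNP positions with exonic
intervals (RNA-seq reads span exons); a whole-span mode exists for
comparison.  Input GTF is read via gffutils with overlapping exons
merged per gene.

## Normalization and allelic partition

Each sample is scaled by one scalar so that its autosomal RPKM total
equals the mean pre-normalization autosomal total (any constant target
would do; the mean keeps values near the input scale).  X-linked genes
receive the same per-sample scalar, leaving sex differences on X intact.
A gene's RPKM then splits in proportion to its maternal/paternal
informative read counts; with zero informative reads the split is
undefined (NaN) and the gene routes to correlation-based classification.
Wherever defined, the two components sum to the input RPKM exactly (to
float precision; the conservation test uses 1e-9).

The zygotic fraction doubles the paternal share — min(1, 2p/(m+p)) —
because zygotic transcription is biallelic on autosomes and the female
X, so the paternal allele carries half the zygotic pool.  The doubling
is configurable off (`doubling=False` gives the raw paternal share);
both conventions are emitted because published zygotic-proportion curves
do not state theirs.  The fraction is computed from read counts, so it
is invariant to the per-sample normalization scalar.  Male X-linked
entries are undefined: with no paternal X there is nothing to observe,
and any paternal-allele read on the male X is reported by
`male_x_paternal_violations` as a sexing/genotyping diagnostic.

The optional F13 imputation replaces the female cycle-13 column by the
arithmetic mean of the female C12 and 14A columns (flagged in sample
metadata, idempotent); it exists for datasets where that embryo is
suspect and is off by default.

## MZT classification

Gene profiles use the 12 female samples only — the male X lacks a
paternal allele, so mixed-sex profiles would confound class with
chromosome.  Replicates at 14A–D are averaged (arithmetic mean of
RPKM); the allele split at each stage pools reads across that stage's
replicates (read-weighted pooling), falling back to the gene-level
pooled share for stages with zero reads (only low-expression stages,
where the components are negligible anyway).

Genes with ≥ 10 informative reads summed over the female samples (the
threshold is interpreted as a per-gene total; a per-sample reading would
be far stricter) are clustered on the 16-vector
[maternal(8) ‖ paternal(8)] in log₂(x+1): the log stabilizes a dynamic
range of several orders of magnitude, and +1 keeps zeros finite.
k-medians uses city-block distance with coordinate-wise median
centroids — the classical pairing — with k = 20, 20 random point
initializations, and reseeding of emptied clusters with the point
farthest from its centroid.  The objective never increases within a run
and the best restart is kept; everything is deterministic given the
seed.

Clusters are labeled on the back-transformed (linear) centroid with a
detection floor ε = 0.5 RPKM:

* **maternal** — max paternal < ε and maternal at 14D < maternal at C10
  ("declining" is judged on the endpoints, robust to mid-course noise);
* **zygotic** — total at C10 < ε and max paternal ≥ ε;
* **maternal+zygotic** — maternal at C10 ≥ ε and max paternal ≥ ε;
* otherwise unclassified.

Labels are invariant to a global rescaling of profiles when ε is
rescaled with them.

SNP-free genes are assigned by Pearson correlation (Spearman available)
between their total female profile and each cluster's reference
profile, on log₂(x+1) scale, requiring r strictly > 0.8; ties go to the
lower cluster index and zero-variance profiles stay unclassified.  The
reference profile is the **centroid** total (sum of the maternal and
paternal halves of the back-transformed median centroid), not the
arithmetic member mean: cluster means are dominated by their
largest-amplitude members and blur profile shape, which measurably
degrades propagation on synthetic data (≈80% vs ≈91% correct).  The
member means are still computed and written to the model dump for
audit.  Propagation by total profile is intrinsically lossier than the
direct route — a maternal+zygotic gene whose minor component is small is
indistinguishable from a pure class by total shape alone.

## Dosage-compensation statistics

All F:M statistics are computed on replicate-averaged stage levels per
sex.  Per-stage ratios are defined only where **both** sexes reach
2 RPKM (a noise floor; the filter wording "at least 2" is inclusive).
The per-gene compensation score is the through-origin least-squares
slope of female (response) on male (predictor), ĉ = Σf·m / Σm², for
zygotic genes with maximum normalized RPKM strictly > 3.0.  Omitting the
intercept makes the score a ratio estimator: ĉ = 1 ⇔ equal expression,
and the score is equivariant in the female scale and invariant under
joint rescaling, which is what makes reading scores against 1.0 / 1.5 /
2.0 meaningful.  Raw RPKM is fitted by default (a log₂ option exists;
which scale the original slopes used is unstated).  Ratio-bin summaries
use F:M edges (1/2, 1/1.75, 1/1.5, 1/1.25, 1, 1.25, 1.5, 1.75, 2) with
open outer bins; undefined ratios are excluded, not imputed.  Chromosome
aggregates sum the partitioned components of zygotic genes per (arm,
sex, stage, parental origin) over genes with a defined split, so
maternal + paternal = total holds by construction.

## SXL motif scan

Sites are AUUUUUUU or UUUUUUUU, case-insensitive, T ≡ U, N never
matches.  The default count is greedy, left-to-right, non-overlapping —
a "site" is modeled as a bound protein footprint — with an overlapping
mode exposed because published tallies do not state a convention (on a
run of n ≥ 8 U's the conventions give ⌊n/8⌋ vs n−7).  Genes with ≥ 3
sites are flagged as predicted SXL targets; multi-isoform genes are
scored by the maximum over their supplied UTR records.

## The synthetic generator

The generator emulates the study design so that every operation has
ground truth; it is not a model of any particular deposited dataset.

* **Design**: 24 samples — one embryo per sex at C10–C13, two per sex at
  14A–14D.  Default 14,833 genes with 5,598 maternal / 2,210 zygotic /
  1,195 maternal+zygotic (the study's class counts; the remainder is
  silent background), ~16% of genes on X, 70% carrying ≥ 1 fixed SNP.
* **Kinetics** on the integer stage axis: maternal pools decay as
  M₀·e^(−0.3t) (≈ 8-fold over the course — deposited mRNA largely but
  not fully cleared by late cycle 14); zygotic expression rises along a
  logistic in t with midpoint 5 (≈ stage 14B) and steepness 1.5,
  anchored to exactly 0 at C10 and its maximum at 14D, matching a
  mid-cycle-14 acceleration with no transcription at cycle 10.
  Amplitudes M₀, Z_max are lognormal (median ≈ 20 RPKM, log-sd 1.0).
* **Sex and compensation**: maternal deposits are sex-independent.
  X-linked zygotic genes carry a per-gene F:M target c ~ U[1.0, 2.0];
  the expected male level is the female level divided by c, so c = 2
  corresponds to transcription proportional to X copy number and c = 1
  to full compensation.  Autosomes have c = 1 (no sex effect).
* **Noise**: observed RPKM = expected × lognormal(0, σ), σ = 0.25.  σ
  was calibrated once so that same-stage replicate Spearman correlation
  lands in the 0.94–0.98 band reported for single-embryo replicates
  (measured 0.967–0.977 on the default design), together with the
  silent-gene model: silent genes sit at a 0.05 RPKM background and drop
  to exactly 0 with probability 0.9 per sample, emulating undetected
  genes' tied ranks.
* **Allele counts**: informative depth per gene×sample is
  Poisson(0.5 × RPKM) for SNP-carrying genes (zero otherwise); the
  paternal count is Binomial with the expected zygotic-biallelic
  fraction — ½·zygotic/total generally, 0 on the male X.
* **Pileups**: by default fixed SNPs are planted inside exons of the
  SNP-carrying genes (1 + Poisson(0.5) per gene) at ~35× simulated
  coverage with a 0.2% error rate capped below the 5% rule, so calling
  is guaranteed to succeed on them; decoy positions engineered to fail
  each criterion (depth < 13, a 60/40 residual-polymorphism mix,
  identical consensus) verify the filters.  An explicit
  (`n_positions`, `n_fixed_snps`) mode decouples pileups from the gene
  table.
* **UTRs**: background sequence with poly-U runs capped at five (so it
  can never contain a site) plus C-flanked planted sites, Poisson rates
  1.2 (X) / 0.3 (autosomes) — an X enrichment of predicted SXL targets
  with exactly known per-gene counts.

What the generator does **not** model: fragment/length bias, mapping
bias between alleles, isoform structure, read-level error in RNA-seq,
spatial expression, or inter-embryo staging error.  Passing tests
demonstrate that the pipeline's arithmetic, filters and classifiers
recover a truth of this idealized form — not that any biological claim
holds in real data.

## Numerical and reproducibility choices

Every stochastic component takes a numpy `SeedSequence`-derived seed;
one global seed fixes the entire pipeline (`run_all` writes it to the
manifest), and equal seeds give byte-identical outputs.  k-medians
restarts default to 20; the small-instance tests use 40 restarts where
they compare against the exhaustive optimum.  Equal-total normalization
is exact to float accumulation error (validated at relative 1e-9 —
absolute 1e-9 is not meaningful for totals of order 1e5 in float64).
Degenerate inputs are defined throughout: empty informative-read cells
give NaN components, zero-variance profiles stay unclassified, all-zero
male stage levels give an undefined score, and a sample with zero
autosomal expression refuses to normalize.

Problem sizes in the test suite (full 14,833-gene default run once per
session; 200–1,000-gene designs per statistical check; 10,000 pileup
columns against the brute-force caller oracle) were chosen so the
statistical assertions have comfortable margins while the whole suite
runs in a few minutes.

## Known limitations

* Propagated labels are only as good as total-profile shape; expect ~90%
  agreement with truth under default noise, worse for strongly
  imbalanced maternal+zygotic mixtures.
* The compensation score is a ratio estimator on noisy levels and is
  slightly attenuated by male-side noise (≈2–3% at default σ); medians
  of score distributions are unbiased in the simulations.
* The caller has no quality model, no indel handling, and treats the
  reference base as pass-through only.
* Real-data ingestion starts from pileup counts and RPKM/allele-count
  matrices; alignment and transcript quantification are upstream of
  this package, and read-level allele assignment from BAM is not
  implemented.
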