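# Methods

`hydroxyscan` reimplements a promoter tiling-array analysis of the mouse
liver 5-hydroxymethylome under drug (phenobarbital) exposure: probe-level
log2(IP/input) normalization, percentile-window peak calling, genic
annotation, TSS meta-profiles, ChIP-seq region scoring, CpG promoter
classification, glucosylation-qPCR quantification and the differential
5mC/5hmC analysis of induced genes.  Every stage is exercised against a
synthetic study generator whose ground truth is recorded in a
`TruthLedger`, so planted effects can be recovered by direct
recomputation without the original arrays.

## Coordinate conventions

All intervals are 0-based half-open.  TSS-relative offsets are
strand-aware: offset 0 is the first transcribed base and positive
offsets run with transcription.  Window membership for probes is decided
by the probe midpoint throughout (50–70 bp probes against ≥200 bp
windows make any-overlap and midpoint nearly identical; midpoint is
unambiguous and is recorded in the output metadata).

## The synthetic study

The generator emulates a promoter-centred tiling design: 50–70 bp probes
at 100 bp start-to-start spacing over tiled regions spanning TSS −7.25 kb
.. +3 kb of every gene (plus a little intergenic array content), two
groups of five animals, and a matched expression matrix, ChIP-seq
fragment libraries and qPCR Cq tables.  Defaults, with rationale:

- **Genome**: 2 chromosomes × 5 Mb, 200 non-overlapping genes with 1–8
  exons, mixed strands; 15% of genes are 2–3 kb "short" genes fully
  covered by the tiling, supporting whole-body profiles.  Desk-scale by
  design; the structure (not the magnitude) of the real array is what
  the analysis logic depends on.
- **Probe noise**: Normal(0, 0.5) log2 units per probe and sample, plus
  a per-animal offset of sd 0.1.  The between-animal component is a free
  parameter: inter-individual variance is not identifiable from the
  published group means, so it is exposed rather than asserted.
- **Intragenic 5hmC domains**: half of all genes carry a planted
  gene-body 5hmC domain of 2.0–2.8 kb at +2.0 log2, scaled by expression
  tier (low ×0.5, medium ×1.0, high ×1.5).  5hmC forms broad kb-scale
  domains over the bodies of expressed genes, and tier scaling gives the
  transcription-coupled body enrichment the profile analyses look for.
- **5mC background**: +0.5 log2 over every gene body, matching the
  broad genic methylation the 5mC mark shows.
- **Induced genes**: 30 genes with true expression log2 fold changes
  drawn from U(1.6, 4).  In treated animals they gain
  `lfc/2` log2 of 5hmC and lose the same amount of 5mC over the TSS
  ±0.25–3 kb flanks (reciprocal switching), and both marks drop by 0.75
  over the TSS ±250 bp core.  Scaling the planted change with the fold
  change is what makes change-vs-expression correlations meaningful.
- **Intensity covariate**: each probe carries a mean log-intensity
  (A-value); a saturation-shaped trend of amplitude 0.3
  (−0.3·tanh((A−13.5)/1.5)) is added to the scores so within-array
  loess correction has something real to remove.
- **ChIP-seq libraries**: 50,000 fragments per library, two replicates
  per group per mark, with matched uniform background libraries and 10%
  exact duplicates injected so deduplication is exercised.  Control
  enrichment follows expression tier (H3K4me2 over TSS −1/+2 kb and
  H3K36me3 over bodies increase with tier; H3K27me3 decreases); in
  treated livers induced genes scale their enrichment by (1 + 0.8·lfc)
  (divided by it for H3K27me3).  Depth and effect size were chosen so
  the per-gene fold changes rise clearly above Poisson counting noise at
  these region sizes — the study conditions are meant to carry the
  correlation signal the real data carried.
- **EpiMark forward model**: surviving template fraction f maps to
  Cq = Cq_uncut − log2(f) (efficiency fixed at 2.0), with a 40-cycle
  ceiling representing complete digestion.  Gaussian Cq noise.
- **Tissue panel**: 10% of genes designed uniform, 10% single-tissue,
  the rest log-normal, for specificity-score tests.

What the generator does *not* emulate: probe sequence effects and GC
bias, dye-specific scanner artefacts beyond the single intensity
covariate, fragment-size variation in IP efficiency, copy-number
variation, and correlated biological variation between neighbouring
genes.  Passing recovery tests therefore demonstrates the correctness of
the analysis arithmetic under the stated statistical model, not
robustness to every artefact of real arrays.

## Normalization

Within-array: a locally weighted linear regression (tricube weights,
degree 1, 3 robustness iterations, span 0.3) of score on intensity is
fitted per sample and subtracted.  The method is the classical loess
correction for saturation; the span default tracks broad intensity
trends without chasing individual peaks, and is configurable.  A
constant intensity column falls back to median subtraction with a logged
warning.  Between-array: each sample is divided by its median absolute
deviation and multiplied by the geometric mean of all samples' MADs, the
scale-normalization contract (idempotent, equalizes spread, preserves
ranking).  The pipeline order is within-array first; 5hmC and 5mC tracks
are always normalized separately.  Missing values propagate and are
never imputed — peak calling treats missing as below threshold, which is
conservative.

## Peak calling

The threshold is the 90th percentile (linear-interpolation quantile) of
the whole group-mean score vector.  Windows of 5 consecutive probes
(consecutive = same tiled region, start-to-start gap ≤ 500 bp) qualify
when ≥4 probes strictly exceed the threshold; overlapping or adjacent
qualifying windows merge into one peak spanning first-probe start to
last-probe end, and the peak's member probes are all probes in that
span.  Strict exceedance, the quantile convention and the midpoint rule
are recorded in the peak-set metadata.  Windows never bridge tiled-region
boundaries: the array is a disjoint promoter design and bridging would
fabricate intervals the array never measured.  Note one consequence of
the merged-span rule: a peak typically includes one below-threshold probe
on each edge (the outermost qualifying windows carry 4 of 5 above), so
probe-level false discovery against planted truth is bounded below by
roughly 2/(probes per peak) even at infinite signal-to-noise.

## Genic categories

Six mutually exclusive categories by interval midpoint with precedence
promoter > exon > intron > downstream > upstream > intergenic; the gene
context is the nearest TSS among genes whose windows contain the
midpoint.  Windows: promoter TSS −1 kb..+250 bp (strand-aware), upstream
−7.25 kb..−1 kb (the array's upstream tiling reach), downstream 1 kb
past the gene end; all configurable and recorded in output metadata.
Distribution tests are Pearson chi-square against the all-probe category
distribution (zero-expected categories are pooled out with a warning);
coverage-normalized distributions divide by per-category probe counts
and rescale to 1.

## Profiles and heat maps

Meta-profiles use 200 bp windows stepped every 50 bp; for span ±1.5 kb
that is (2·1500 − 200)/50 + 1 = 57 offsets.  Each gene contributes its
window mean, genes are averaged with equal weight, and the per-offset
contributing-gene count is reported.  Expression tiers are quartiles of
mean control expression (low = bottom 25%, high = top 25%, medium =
rest) with stable tie-breaking so tier sizes are deterministic.
Gene-body profiles for short (2–3 kb) genes run in absolute bp from the
TSS with no length scaling.  PPR (TSS ±1 kb) heat maps clip per-animal
means to ±2.5 and order rows by Ward/Euclidean agglomerative clustering;
at each merge the children are laid out by (cluster size, then smallest
member id), making the leaf order reproducible bit-for-bit.

## ChIP-seq region scores

Fragment libraries are deduplicated on exact (chrom, start, end);
fragments count for every region they overlap by ≥1 bp; counts are
scaled by total library size to the mean of the libraries, and scores
are log2((IP + 1)/(background + 1)) against the per-sample matched
background.  The pseudocount of 1 keeps zero-count regions finite and is
recorded in metadata.  H3K4me2 is scored over TSS −1/+2 kb, H3K27me3 and
H3K36me3 over gene bodies; group means use the two replicates per group.

## Differential analysis

Expression change is mean(log2 treated) − mean(log2 control) with a
Welch two-sample t test — a deliberate substitution of a plain t test
for a moderated empirical-Bayes statistic, which belongs to the
expression-preprocessing stack this package consumes rather than
implements.  Induced genes are those with lfc strictly above 1.5 log2.
"Unaffected" genes are the n smallest |lfc| among genes with |lfc| < 0.1
and p > 0.5 (deterministic; declared in metadata).  Change correlations
are Pearson r between each mark's change and the expression lfc over the
induced set, computed on group-mean changes.  The family region analysis
reports, per region × mark, the family's mean change, standard error,
two-sided Wilcoxon rank-sum p against the unaffected genes' changes, a
significance flag at p < 0.005 and a |mean|-ratio fold enrichment; raw
p-values are reported without multiplicity correction, deliberately.
When recovery experiments skip the within-array loess step they do so
because the planted intensity trend is common to both groups and cancels
exactly in treated − control; the full pipeline always runs it.

## EpiMark quantification

Glucosylation protects 5hmC from MspI; HpaII is blocked by any CpG
modification.  Under that enzymology the unique linear solution for the
three CpG states is

    f_5hmC = f(MspI | glucosylated) − f(MspI | untreated)
    f_5mC  = f(HpaII | untreated)  − f(MspI | glucosylated)
    f_C    = 1 − f(HpaII | untreated)

with surviving fractions f = 2^(Cq_uncut − Cq_digested) clamped to
[0, 1], a Cq at the 40-cycle ceiling mapping to 0, and the untreated
MspI reaction acting as background correction (this is what makes the
noise-free round trip exact).  The three states partition the site, so
f_C is a complement: assays cannot distinguish "unmodified" from "not
cut for any other reason".  Fractions are clamped to [0, 1]; violations
beyond 0.05 before clamping are logged.  Replicates are resolved
independently, averaged, and reported with standard errors.

## Tissue specificity

Si = Σ_t p_t · log2(p_t · T) with p_t the expression share of tissue t —
the Kullback–Leibler divergence from the uniform profile.  Exactly 0 for
uniform expression, exactly log2 T for single-tissue expression,
invariant to rescaling.  The number of tissues behind any particular
printed maximum is a free parameter (log2 T); the package exposes T
rather than fixing it.

## Problem sizes and determinism

Recovery experiments run at desk scale as the package's own choice of
study conditions: peak recovery on 150 genes / 2×4 Mb; differential sign
recovery over 100 replicate default studies; null calibration of the
family analysis over 200 replicates of a 40-gene genome with 5,000
fragments per library.  Every stochastic component takes an explicit
integer seed and identical seeds give byte-identical outputs; the
pipeline writes a manifest (package and library versions, full
configuration, input digests) sufficient to re-run any stage.

## Known limitations

- Only the first TSS per gene id is used; multi-TSS isoforms are out of
  scope, as is nearest-gene assignment by regulatory-domain models.
- The peak caller reports no FDR; it is the fixed percentile-window rule
  with its edge-probe behaviour described above.
- Raw Nimblegen `.pair`/`.xys` parsing and expression-array
  preprocessing (RMA, moderated t) are out of scope; the package
  consumes probe-level log2 ratios and a normalized expression matrix.
- The EpiMark model fixes qPCR efficiency at 2.0 per cycle and does not
  model melt-curve QC or incomplete digestion.
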