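# Methods

somakit is a desk-scale somatic-genome interpretation stack: it simulates
whole-genome tumour/normal observables under an explicit purity/copy-number
mixture model and then inverts that model stage by stage — purity and
allele-specific copy number, whole-genome duplication (WGD), per-variant
ploidy and clonality, MSI/TMB, mutational signatures, a driver catalogue
with per-event likelihoods, and evidence-level actionability.  This note
documents the models, the parameters that matter, and the design choices
made where the design was genuinely open.

## The mixture model

All inference rests on one generative model.  For a locus with
allele-specific tumour copy number (major M, minor m; CN = M + m), tumour
purity p and normal copy number nc (2 on autosomes and female X, 1 on male
X/Y):

* depth ratio (tumour/normal coverage, diploid-normalised):
  `r = (p·CN + nc·(1−p)) / nc`
* folded B-allele frequency of heterozygous SNPs (nc = 2):
  `b = (p·M + (1−p)) / (p·CN + 2(1−p))`
* variant allele fraction of a somatic variant on `mult` chromatids in a
  clone of cancer-cell fraction c:
  `VAF = p·mult·c / (p·CN + nc·(1−p))`

The generator draws reads binomially from these success probabilities at
per-site depths from a negative binomial (mean 106× tumour / 38× normal,
overdispersion 0.1); the interpreter inverts the same equations.

## Synthetic cohort generator

**Genome.** The default "mini" genome uses GRCh37 chromosome lengths
scaled down 30-fold (≈103 Mb total), which keeps whole-cohort runs at
seconds while preserving per-autosome logic (the WGD rule needs 22 real
autosomes).  Genes carry synthetic coding sequences (seeded random codons,
no internal stops) at realistic CDS lengths (360–1,200 bp) with 2–5 exons;
two long genes (>500 kb span) model common fragile sites.  Canonical
oncogene/TSG names are used so that fixture panels read naturally, but all
coordinates and sequences are synthetic.  Every chromosome carries
microsatellite annotations (homopolymers ≥5 bp and 2–4 bp-unit repeats).

**Copy-number profiles.**  A configurable fraction of autosomes (default
0.4) receives arm- or chromosome-level events from a state palette; WGD
samples start at (2,2) with post-WGD losses.  At least two autosomes carry
LOH whenever any aneuploidy is simulated — this mirrors the pervasive LOH
of real tumours (~23% of the autosomal genome) and is also what makes
purity identifiable: a fully allele-balanced genome admits a family of
(purity, ploidy-multiple) solutions, and LOH segments with odd allele
counts break it.

**Point mutations.**  Per-clone counts with exactly one clone at CCF 1.0
and subclones restricted to CCF 0.1–0.9 (default: 250 clonal + 30
subclonal at CCF 0.4, ≈11% subclonal).  SNVs are placed in coding sequence
at the human exome fraction (1.1% — the mini-genome's own gene density is
much sparser, so the exome fraction is imposed rather than inherited) and
otherwise intergenically, with trinucleotide contexts drawn from a mixture
of fixture signature profiles.  Because the mini-genome has no reference
sequence outside genes, each SNV's context travels with the variant as a
VCF INFO tag; coding consequence annotation comes from the synthetic CDS.
Phased adjacent SNV pairs provide MNV-merging truth.  Planted driver
events (hotspot SNVs, biallelic TSG hits with LOH overlays, focal
amplifications at ~5× ploidy — real high-level amplifications sit far
above the 3× call boundary — homozygous deletions, in-frame fusions with
matched exon phases, germline variants with configurable allele fates)
give every downstream stage recoverable ground truth.

**Segment BAF observable.**  Segment BAF is simulated oriented to the
major haplotype (mean major-allele read fraction), i.e. the generator
emits the bias-corrected folded BAF that a copy-number caller consumes.
Modelling the fold-at-0.5 estimator bias of raw per-SNP BAF is
deliberately out of scope; with pooled segment-level BAF the residual bias
is ≪0.01 at default depths.

**What the generator does not emulate:** read-level artefacts (mapping
error, strand bias, FFPE damage), sequencing-error false positives,
kataegis/chromothripsis, subclonal copy number, germline SNP phasing
error.  Tests passing on this generator therefore validate the
*model-inversion* logic and decision rules, not robustness to artefactual
noise.

## Purity/ploidy fitting

A grid search over purity 0.08–1.00 (step 0.01) × candidate sample ploidy
1.0–8.0 (step 0.02).  For each hypothesis a normalisation factor maps the
length-weighted mean depth ratio to the candidate ploidy; each segment's
implied real-valued CN and major allele are rounded to the nearest integer
state, and the score is the SNP-count-weighted squared BAF deviation plus
length-weighted squared depth-ratio deviation from that state, plus an
aberration penalty (1e-4 per SNP-equivalent per unit allele distance from
(1,1)).  The penalty is essential: higher-ploidy hypotheses tile
observation space with more integer states and would otherwise absorb read
noise, aliasing the fit to multiples of the true ploidy.  Ties (a flat
score surface in purity, e.g. a fully balanced genome) break to the lowest
candidate ploidy, then the lowest purity, and the fit is flagged
`purity_unreliable`.  Reported sample ploidy is recomputed as the
length-weighted mean of the fitted real-valued CNs.  The exact objective
of production purity callers is not published in the main text we follow;
this scoring is this package's own declared surrogate.

Recovery under the default study conditions (segmented mini-genome, 100×,
purity 0.2–1.0): |Δpurity| ≤ 0.03 and |Δploidy| ≤ 0.1 in ≥90% of samples
(observed 20/20 on the analysis cohort).

**WGD rule.** An autosome is duplicated when the length fraction with
major allele ploidy > 1.5 is ≥50%; WGD is called at ≥11 duplicated
autosomes.  On mixed cohorts the duplicated-autosome count is strongly
bimodal (WGD samples ≈ 22, non-WGD ≤ ~9 by construction of realistic
aneuploidy rates).

**CNA categories.** Loss ring: homozygous deletion at min exonic CN <
0.5; else LOH (minor allele ploidy < 0.25 — the LOH bound is unprinted in
our source and 0.25 separates fitted-zero minors from noise at grid
precision) split into significant loss (CN < 0.6× ploidy) vs near
copy-neutral.  Gain ring: >3× / >2× / >1.4× sample ploidy.  Y loss is
reported for male samples at Y CN < 0.5.

**Sample QC.** Exclusion on zero somatic variants, purity < 0.20, or a
GC-bias metric above threshold (default 0.25 relative amplitude; the
upstream QC criterion is unstated, so the metric is exposed as a
parameter).  Multi-biopsy patients keep the highest-purity passing sample.

## Somatic interpretation

**Variant ploidy.** `v = VAF·(p·CN + nc·(1−p))/p`; biallelic iff
`v > CN − 0.5`.  Sex-chromosome normal copy number: X = 1 and Y = 1 in
males, X = 2 in females (required to invert VAF off-autosome; a
convention of this package).

**Clonality.** A Gaussian mixture over variant-ploidy space, EM-fitted
with 1–5 components selected by BIC (seeded, `reg_covar` 1e-4).  Peaks
with location < 0.85 (CCF-equivalent at single-chromatid multiplicity)
are subclonal; the subclonal boundary and peak-count selection are this
package's declared realisation of a two-step peak-fitting procedure whose
functional form is unpublished.  Mixture weights are recomputed from the
final E-step responsibilities so that the sample subclonal fraction equals
the probability-weighted variant mean exactly.  Below 50 variants a single
clonal peak is returned.  Recovery: a 70/30 clonal/subclonal mixture
(n = 2,000, 100×) is estimated within ±1 pp across seeds.

**MSI.** Qualifying indels are those whose reference span overlaps a
homopolymer ≥5 bases or a 2–4 bp-unit repeat of ≥4 units; the score is
qualifying indels per Mb of the configured genome (mini-genome aware —
the production denominator is not printed) and MSI is called strictly
above 4.  Indels are counted per variant, not per locus.

**TMB.** All small-variant classes (SNV+MNV+indel) per Mb; the
immunotherapy-eligibility flag is strictly above 10/Mb.

**Signatures.** Non-negative least squares of the 96-context count vector
onto a column-normalised signature matrix; residual is the L1 distance.
Signatures below 5% of the sample total or below 300 fitted variants are
excluded from the reported set (inclusive at the boundary, with a 1e-6
numerical tolerance on the NNLS loads).  The fixture matrix is synthetic
(sparse Dirichlet columns), standing in for a curated catalogue; only
refitting is in scope, not de novo extraction.

## Driver catalogue

**Simplified dN/dS.** Context rates are estimated from synonymous sites
cohort-wide (96 trinucleotide classes; unobservable contexts fall back to
the global synonymous rate); expected missense/nonsense counts come from
per-gene context-resolved opportunity counting over the synthetic CDS;
each gene × class is tested one-sided Poisson against the neutral null
with BH correction and flagged at q < 0.01.  Splice and indel classes
have no sequence context here; their expectations are
opportunity-proportional shares of the cohort totals, so their *global*
ratios are 1 by construction while per-gene excess remains testable.  No
covariates and no negative-binomial shrinkage — deliberately reduced from
the production regression machinery.  Calibration: ≤1 significant gene in
20 neutral cohorts (50 samples × 40 coding SNVs); a 10× missense excess in
one gene is detected in ≥19/20 runs of 200 samples.

**Panel and roles.** The panel is the union of cohort SMGs (q < 0.01),
external SMG lists and curated genes, each with provenance flags.
TSG/oncogene roles come from a seeded logistic classifier over per-gene
features (truncating fraction, missense concentration, biallelic
fraction, in-frame indel fraction) trained on a synthetic labelled
fixture (held-out accuracy ≥0.9); fixture truth roles take precedence for
curated genes.

**Peaks.** Per chromosome and direction, iterative GISTIC-like peel-off
on the boolean samples × genes event matrix (amplification: min exonic CN
> 3× ploidy; deletion: < 0.5, Y excluded).  The maximal-support gene
seeds a peak (the contiguous run with identical supporting sets); each
supporter's contiguous event run through the seed is removed; iteration
stops below max(5 samples, 2% of cohort) — an unprinted stopping rule
chosen to suppress noise peaks on small cohorts.  Target-gene curation,
in priority order: panel gene in the peak > shortest gene in the peak >
the seed gene.  Deletion peaks are fragile-site-annotated when the target
gene is longer than 500 kb *and* >30% of its deletions are 20 kb–1 Mb
(conjunction).

**Point-driver likelihood.** Inclusion: missense and in-frame indels for
oncogenes; any non-synonymous or essential-splice point mutation and
indels for TSGs; non-coding only TERT promoter variants.  The likelihood
is `E/(E + P_s)` with E the gene/class driver excess (observed −
expected, floored at 0) and `P_s = expected × burden_s/burden_mean` the
sample-scaled passenger expectation — the simplest form that is monotone
non-increasing in sample burden and bounded in [0,1]; the production
allocation formula is unpublished.  Overrides to ≥0.99: oncogene variants
at or within 5 nt of a fixture hotspot; biallelic TSG variants in genes
whose cohort biallelic fraction exceeds 0.5; TERT promoter variants
(treated as known recurrent hotspots).

**CN/fusion/germline events.** Amplification drivers at min exonic CN >
3× ploidy in peak targets or panel oncogenes; deletion drivers at < 0.5
in peak targets or panel TSGs.  Fusions classify as in-frame coding
(known pair, intronic breakpoints with equal exon phases), cis-activating
(breakpoint in the 5' regulatory window of a known/promiscuous 3'
partner) or in-frame intragenic exon deletion (deleted exonic length ≡ 0
mod 3).  Germline drivers are restricted to the 29-gene high-confidence
panel (the 25 ACMG v2.0 cancer genes plus CDKN2A, CHEK2, BAP1, ATM); for
each variant the tumour allele configuration is resolved from minor
allele ploidy and the variant ploidy implied by tumour VAF —
loss-of-wild-type (LOH retaining the variant), loss-of-variant (excluded
from the catalogue unless a somatic second hit exists), or second somatic
hit.

**Summaries.** Driver burden is the sum of likelihoods; subclonal driver
burden is Σ subclonal probability × likelihood.  Pairwise co-occurrence
uses two-sided Fisher exact tests with BH correction, signed by the odds
direction.

## Actionability

Evidence records live in a common model (biomarker = gene + event class ±
exact variant, drug, level A/B, direction, disease-ontology id); C/D/E
levels are dropped at load.  Matching specificity: exact variant >
gene + class.  On-label means the sample DOID equals or descends from the
record DOID in a fixture parent-child table (no live ontology; unmatched
types degrade to off-label).  MSI adds a level-A match.  A drug is
excluded when the sample carries a resistance biomarker for it at the
same or higher evidence level; exclusion is applied per drug (the
equivalence classes for "same biomarker type" are not published).
Remaining matches rank A on-label > A off-label > B on-label > B
off-label; ranking is a total order and permutation-invariant.

## Numerical choices and degenerate inputs

* Purity grid ties: tolerance 1e-12 + 1e-9·|score|; lowest ploidy, then
  lowest purity.
* Segments without heterozygous SNPs get minor = major = CN/2 (no BAF
  evidence); male X/Y segments get minor = 0.
* Homozygously deleted regions reject somatic variant placement in the
  generator; variants with zero sampled alt reads are dropped
  (unobservable).
* NNLS reporting filters use a 1e-6 tolerance; clonality EM uses
  reg_covar 1e-4 and 2 seeded initialisations.
* Empty inputs raise: no segments / no informative SNPs (purity), empty
  variant list (clonality), empty cohort or zero synonymous variants
  (dN/dS), unknown evidence level (knowledgebase).

## Problem sizes

The test and analysis workloads use the mini-genome (≈103 Mb, 86 genes)
with cohorts of 10–20 samples, 250–2,000 point mutations per sample, and
dN/dS cohorts of 50–200 samples × 40 coding mutations — sizes chosen so
the full pipeline runs in seconds per cohort on one core while every
decision rule is still exercised across its boundary.  Full-length
chromosome mode is available (`build_mini_genome(scale=1)`).

## Known limitations

* The purity objective, clonality peak model and driver-likelihood form
  are declared surrogates for unpublished production internals; they
  preserve the printed decision rules and monotonicities, not the exact
  numerics of those tools.
* dN/dS lacks covariate shrinkage, so per-gene expectations on small
  cohorts are noisy; the excess-based likelihood then tends toward 1 for
  singleton hits in otherwise quiet genes.
* The balanced-genome purity degeneracy is reported, not resolved.
* Signature fixtures are synthetic; contributions are identifiable only
  because the columns are well separated.
* A cohort of fixture knowledgebase records, not live OncoKB/CGI/CIViC
  content, backs actionability; conclusions about real drug matching do
  not transfer.
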