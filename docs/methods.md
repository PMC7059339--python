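# Methods

`saltlnc` reimplements, as a tested library, a discovery-and-function
pipeline for salt-responsive long noncoding RNAs (lncRNAs) in a plant
sampled over a salt time course (0, 6, 12 and 24 h; three biological
replicates per time point). The pipeline starts from assembled transcript
models and runs five stages: basic filtering, coding-potential exclusion,
positional classification, differential expression, and three modes of
functional prediction (trans co-expression, cis proximity, miRNA
targeting). A synthetic-data generator with planted ground truth carries
the statistical structure each stage assumes, so every stage can be
validated against known answers.

## Coordinates and formats

Internally all intervals are 0-based half-open. GFF3/GTF (1-based closed)
are converted exactly once at the I/O boundary; BED shares the internal
convention. Gene records are span-level: a gene's extent is the union of
its transcripts including introns. Assembler read coverage and the number
of samples a transcript was assembled in are not standard GTF attributes,
so they travel in a TSV sidecar keyed by transcript id.

## Basic filtering cascade

A transcript survives iff it

1. was assembled in ≥ 2 samples (recurrence),
2. overlaps no annotated gene on the same strand (span-level, ≥ 1 bp),
3. is ≥ 200 nt long (spliced),
4. has assembler coverage ≥ 3,
5. has no open reading frame longer than 300 nt.

Discard thresholds are strict (`< 200`, `< 3`, `> 300`), so boundary
values survive. The ORF convention: ATG-to-stop on the spliced sense
strand only (the emulated libraries are strand-specific), all three
frames, length in nucleotides including the stop codon; an ATG without an
in-frame stop before the sequence end is not an ORF (this keeps ORF
length well defined). Filters are evaluated independently, so the
retained set is order-independent; the failure report lists violated
filters in the canonical cascade order above.

## Coding potential

Three scorers vote; a transcript is kept as noncoding only if **all**
call it noncoding (the conservative reading of a multi-tool exclusion):

- **Fickett TESTCODE** — the classic weighted sum of eight looked-up
  probabilities (per-base position asymmetry max/(min+1) over the three
  codon phases, and per-base content), with the published lookup tables
  embedded as constants. Threshold 0.95 (the published "probably coding"
  bound).
- **In-frame hexamer bias** — mean log(f_coding/f_noncoding) over the
  hexamers of the longest ORF stepping by codons; coding tables are
  trained on in-frame CDS hexamers, noncoding tables on sliding hexamers.
  Threshold 0 (any net coding-like usage votes coding). Sequences
  shorter than one hexamer score 0 by convention.
- **Logistic combiner** — logistic regression on standardized
  (ORF length, ORF coverage, Fickett, hexamer), fit by iteratively
  reweighted least squares (convergence `max|Δw| < 1e-8`, ≤ 100
  iterations, ridge 1e-8 so separable training data cannot break the
  Newton step — on such data the MLE diverges and the fit stops at the
  iteration cap with saturated, correctly ordered probabilities).
  Threshold p = 0.5.

The default model trains on 800 synthetic codon-biased CDS vs 800
AT-rich noncoding sequences per class; 200 per class left the 4096-cell
hexamer tables sparse enough that short-ORF bias estimates were noisy.
Users can supply species-specific training sequences instead. A
final, orthogonal filter removes transcripts with precomputed
protein-domain hits supplied as a table (domain search itself is outside
the package).

## Classification

Span-level and strand-aware: a surviving candidate overlapping a gene on
the opposite strand (≥ 1 bp) is **antisense** (the most-overlapped gene
is recorded; ties break to the smaller gene id); otherwise it is
**intergenic**. Same-strand overlappers cannot reach this stage; finding
one raises an error rather than silently reclassifying. A consequence of
the span-level convention is that intronic transcripts are not a separate
class: on the same strand they were already removed, on the opposite
strand they are antisense.

## Expression and differential expression

FPKM is computed against raw per-sample totals
(`count / (length/1e3 · total/1e6)`); normalization for testing uses
median-of-ratios size factors (median over all-positive features of the
count over the feature's geometric mean), rescaled to geometric mean 1.

Differential expression between two conditions uses an exact
negative-binomial test: conditioning on the summed count of both groups,
the p-value is the total probability of all splits (a, b) of that sum no
more probable than the observed one, where each group total is NB with
moment-matched mean and variance (variance `Σ_j μ_j + α μ_j²` over the
group's samples). The log2 fold change compares size-factor-normalized
group means with a pseudocount of 1 (the pseudocount affects only the
reported fold change, not the test). A feature is DE at |log2FC| > 1
and BH-FDR < 0.05.

**Dispersion.** The per-feature estimate is method-of-moments on
normalized counts, pooled over the *within*-group replicate variances and
floored at 0 (Poisson). With three replicates per group this estimator is
extremely noisy: near-zero estimates make the test anti-conservative
(measured type-I error 0.12 at nominal 0.05 on NB(α = 0.05) nulls).
`pairwise_de` therefore moderates it by flooring each per-feature
estimate at the median estimate across all features of that comparison —
a minimal shrinkage in the spirit of common-dispersion estimators, which
restores calibration (measured 0.049) without costing power (recall 1.0
for planted |log2FC| = 3 at mean 500). The unmoderated estimator remains
available (`moderate=False`, or `nb_exact_test` on a single feature).

## Trans co-expression

DE lncRNAs and DE genes are pooled; their four condition means are
Z-scored per feature and correlated. Unsigned soft-threshold adjacency
`|cor|^6` is smoothed into a topological overlap matrix (TOM), and
average-linkage clustering of 1 − TOM with a static cut at 0.25 yields
modules (minimum size 10; smaller clusters merge into the best-correlated
retained module). Full soft-threshold selection by scale-free fit and
dynamic tree cutting are deliberately out of scope.

Each module is labelled with one of six temporal archetypes by maximal
Pearson correlation of its centroid against the canonical Z-scored
shapes; below 0.7 it stays unassigned. The archetypes (condition-mean
multipliers over H0/H6/H12/H24) are M1 (1,2,4,8) gradually induced;
M2 (1,6,6,2) transiently induced; M3 (8,6,2,1) monotone repressed;
M4 (4,8,2,1) peak at 6 h; M5 (8,3,2,0.5) and M6 (8,3,2,2) repressed,
differing at 24 h. Note that several of these shapes are strongly
correlated on four points (|cor(M5, M6)| ≈ 0.98, M1 vs M3 ≈ −0.97), and
unsigned adjacency also links anti-correlated profiles, so static-cut
clustering merges look-alike archetypes; archetype labelling is therefore
exercised on known co-varying groups, while cluster recovery is
demonstrated on well-separated planted blocks.

Per-module functional-category enrichment uses one-sided Fisher's exact
tests on the 2×2 table of (in module, in category) against the background
of all DE features with category assignments, BH-adjusted across
categories within the module, significant at FDR < 0.05.

## Cis pairing

For each DE lncRNA, DE genes on the same chromosome are candidates when
their span lies within 10 kb on the lncRNA's 5′ (upstream) side or
100 kb on its 3′ (downstream) side — sides follow the lncRNA's strand,
boundaries inclusive. Distance is the number of bases strictly between
the two spans (0 when they touch or overlap; overlap also forces
side = downstream). TSS-to-TSS anchoring was rejected because reported
pair geometries in this literature mix lncRNA- and gene-relative
phrasing. A candidate passes as a cis pair when the Pearson correlation
of the two 12-sample FPKM vectors reaches |r| ≥ 0.8 ("highly
co-expressed" is never quantified in the source literature; the gate is
configurable).

## miRNA targeting

The mature miRNA is aligned ungapped and antiparallel at every offset of
the target: miRNA position k pairs with window position L−1−k. A:U and
G:C are matches, G:U (either orientation) is a wobble, everything else a
mismatch; T ≡ U throughout. A site is accepted with ≤ 2 mismatches
(the "< 3 mismatches" rule) and ≤ 4 wobbles (wobbles are tolerated but
capped to avoid degenerate GU-rich hits; configurable). No seed-region
weighting, bulges or thermodynamic scoring. miRNA families collapse by
identifier prefix through the number (miR156a-5p → miR156). Accepted
hits feed degree histograms and a directed miRNA → target network
exported as SIF.

## Synthetic data

One seed fixes everything; each stage draws from its own named RNG
stream, so adding a stage never perturbs earlier ones. Defaults emulate a
scaled-down version of the study conditions:

- 2 chromosomes × 7 Mb carrying 2000 non-overlapping coding genes whose
  CDS is drawn from a fixed biased codon-usage table (one preferred codon
  per amino acid, weight 6:1), so hexamer and position-asymmetry signals
  are real. The scale matters: DE features must carry a minority of the
  reads (as in real data, where ~10% of features respond), otherwise
  per-sample totals swing with the condition and FPKM vectors of *flat*
  features become mutually correlated, corrupting the cis correlation
  gate.
- 15 antisense lncRNAs (inside a host gene, opposite strand) and 25
  intergenic lncRNAs (overlapping nothing), lengths log-normal with
  median ≈ 430 nt, ~84% single-exon; sequences are AT-rich with ORFs
  longer than 300 nt suppressed by in-frame stop injection.
- 10 junk transcripts, each violating exactly one basic filter.
- NB counts with dispersion α = 0.05 (shared across features; no public
  dispersion estimate exists for the emulated data), baseline abundance
  log-normal (median 500), mild library-size variation; 24 DE lncRNAs
  and 48 DE genes split evenly over the six archetypes.
- 6 planted cis pairs: an intergenic DE lncRNA placed at a recorded gap
  (50–1500 bp, within the windows) from a DE gene sharing its archetype.
- 8 miRNAs (21 nt); 10 accepted-site plants cycling through
  mismatch/wobble combinations within the rule, 5 decoys with ≥ 3
  mismatches, edited into DE lncRNA sequences with an ORF re-check.

Transcript spliced sequences are authoritative in `transcripts.fa`; the
genome FASTA is consistent for gene CDS only — an antisense lncRNA's
sequence cannot equal the reverse complement of its host CDS without
acquiring long ORFs, which would contradict its planted noncoding status.

What the generator does **not** emulate: read-level sequencing noise and
mapping ambiguity, assembly artifacts, isoform complexity, per-feature
dispersion trends, GC or length biases in quantification, and real codon
usage of any particular species. Passing the planted-truth suite
therefore demonstrates the correctness and calibration of the
algorithms under their stated assumptions, not end-to-end performance on
real sequencing data.

## Problem sizes and numerical choices

The validation suite runs ten simulations at the default scale (~2050
transcripts each) for recovery rates, and dedicated two-group experiments
(2000 null + 200 DE features, 3 vs 3) for power and type-I error; the
Poisson-limit check uses 10⁴ draws at mean 1000. Ties in the exact test's
outcome ranking are included in the rejection set with a 1e-12 log-scale
tolerance. Zero-variance expression profiles are excluded from networks
(with a warning), score r = NaN and fail the cis gate rather than
propagating NaNs. Fisher enrichment of an empty category or a module
equal to the background returns p = 1.
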