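# Methods

This note documents the models, defaults and numerical choices behind
`mcltools`, and what the synthetic cohort does and does not emulate.

## Synthetic cohort model

Counts are gamma-Poisson (negative binomial) per gene with a shared
dispersion θ (default 10): `count ~ Poisson(Gamma(θ, μ/θ))`, with per-cell
lognormal(0, 0.15) size factors. Per-gene baseline means are
lognormal(−0.7, 1.2) for filler genes; mitochondrial (13 `MT-` genes) and
ribosomal (40 `RPL/RPS` genes) pseudo-gene groups get fixed means so that
typical cells carry ≈ 6% mitochondrial and ≈ 17% ribosomal counts and QC
rules apply verbatim. Lineage markers (CD19/MS4A1/CD79A, CD3D/E/G, …) take
an elevated mean (default 6.0) in their home type. Immunoglobulin constant
genes are set by each cell's light chain: kappa cells express IGKC
strongly, lambda cells IGLC1/IGLC2; malignant cells inherit their
clonotype's chain, normal B cells are kappa with probability 0.6.

CNV segments multiply the NB mean of the spanned genes — exactly the
signal that window-smoothing of relative expression detects. The default
cohort (3 samples × 2,000 cells × 2,000 genes over 22 autosomes + chrMT)
plants a chr3 gain (ratio 2.0, all malignant cells) and a chr9 loss (ratio
0.5, clonotype ct1 only); whole-chromosome segments keep the planted
per-gene truth unambiguous under smoothing. CCND1 is raised 4-fold in
malignant cells. QC-failing cells are planted as extras: library-collapsed
cells (μ × 0.04), high-mito cells (mito means × 8) and T+B doublets
(sum of one malignant-B and one T expression profile).

BCR tables carry one heavy and one light contig per captured B cell
(capture 0.9), with 3% heavy-only and 2% non-productive rows to exercise
the quality filters. Clonotype heavy sequences are the germline IGHV
(a deterministic pseudo-sequence per V-gene name) with exactly the
configured number of substitutions.

Variants derive from a planted 4-clone tree whose per-sample CCFs satisfy
the sum rule and whose alternative topologies are all excluded by at least
one sample (so the recovery check has a unique answer). Read counts are
`alt ~ Binomial(depth, p·CCF·m / (p·CN + (1−p)·2))` at Poisson(200) depth.
Five callers detect a present variant (≥ 2 alt reads) with sensitivity 0.9
and add private false positives at 1e−6/bp over a 3e7 bp effective genome;
five panel artifacts are planted into 4 of 10 germline samples and into the
tumor tables, and probe variants sit in high-GDI and low-FPKM genes so the
gene filters have planted targets.

What the generator does **not** emulate: batch/chemistry effects (hence
Harmony-style correction is out of scope), ambient RNA, gene-length or
GC bias, BCR allele diversity and within-clonotype SHM evolution,
subclonal copy-number heterogeneity beyond clonotype-level segments,
sequencing artifacts with positional structure, and indel representation
issues. Passing tests therefore demonstrate correctness of the procedures
under a clean generative model, not robustness to every failure mode of
real data.

## Preprocessing

QC keeps cells with 500 ≤ detected genes ≤ 5,000, total counts ≤ 40,000,
mitochondrial fraction ≤ 20% and ribosomal fraction ≥ 5%, after removing
genes detected in fewer than 3 cells (gene filter first; cell statistics
recomputed on the reduced matrix). The ribosomal rule removes *low*-ribo
cells, which is unusual; it is implemented as stated and flagged here for
users. Normalization is library-size log1p at 10,000 counts per cell —
deliberately simple and exactly invertible, standing in for
variance-stabilizing transforms. Clustering is PCA (30 components, fewer
when rank-limited, arpack solver) → SNN graph (15 neighbors) → Leiden
modularity at resolution 0.6, all seeded. Cell typing is per-cluster
argmax of mean z-scored marker expression with a fixed tie-break order.
Differential expression is the two-sided Wilcoxon rank-sum (asymptotic,
tie-corrected) with Benjamini-Hochberg adjustment.

## Malignant-cell classification

Defaults, all exposed on `Thresholds`: dominant-clonotype fraction ≥ 0.5
within a cluster's BCR-assigned cells (≥ 5 of them required); light-chain
consistency |mean ratio − 0.5| ≥ 0.3 with SD ≤ 0.15; CCND1 log2
fold-change ≥ 1 against the normal-B reference; CNV confirmation median
score > the reference's 95th percentile. The CNV channel only demotes
(malignant → ambiguous), never promotes. The normal-B reference is taken
from non-doublet B subclusters without a dominant clonotype; clusters with
clonal BCR but reference-level CNV remain exposed as ambiguous rather than
forced to a label.

Doublet flagging scores each cluster by mean log-normalized B-marker and
T-marker expression and flags clusters whose scores both lie in the upper
half of the cohort's observed range (midpoint of min and max across all
clusters of the full dataset). A median cut is unstable here: when B-high
clusters are the majority, the median lands inside the high group and
strict comparisons at it become noise-ordering; the range midpoint
separates the bimodal score groups robustly. The full-dataset cohort must
span genuine negatives (T/NK/myeloid clusters), which the pipeline
guarantees by computing thresholds before subsetting. B-compartment
extraction includes clusters typed B *or* co-expressing both marker sets,
since T+B doublets often land beside T cells at the global resolution.

## Expression-inferred CNV

Per gene: subtract the reference mean in log space, clip at ±3 reference
SDs, smooth with a centered 51-gene moving average within each chromosome
(edges shrink), re-center each cell at its median, zero residuals within
2.5 reference SDs of the smoothed reference profile (denoising — without
it, sampling noise alone puts most genes outside the 0.95/1.05 band at
desk-scale depth), and exponentiate. Window, clip, and denoise multipliers
are parameters; `denoise_sd=0` disables the step. Immunoglobulin genes are
excluded (clonal Ig expression mimics gain), mirroring the WGS-side rule.
The CNV score applies the 0.95/1.05 thresholds to the smoothed (denoised)
ratios, the object this procedure outputs.

## Consensus NMF

Input is the cNMF-style transform: per-gene z-scores with negatives
clipped at 0. Each K runs `n_restarts` random-initialization NMF fits
(scikit-learn coordinate descent, Frobenius loss, 300 iterations);
restarts default to 20 for desk-scale runtime (the procedure is defined up
to this count; raise it for production use). Stability per K is the
cophenetic correlation of the consensus (co-assignment) matrix under
average linkage; K* is the smallest K with coph(K) > coph(K+1) — the K
*before* the first decrease, with the strictly-never-decreasing case
falling back to max K. Meta-programs cut the average-linkage tree over
distance = 30 − shared-top-genes at height 27 (≥ 3 shared genes to merge);
the consensus gene set collects genes in ≥ 2 member programs.

## Variant cascade

The `(3/10)` panel rule is resolved toward the parenthetical: drop at
≥ ceil(0.3·N) panel samples (3 of 10), with `strict=True` implementing the
strictly-greater-than-30% prose reading. Presence in a panel sample means
≥ 1 high-quality alt read (VAF > 0). Variants in unannotated genes are
kept and flagged rather than dropped. The gene-level FPKM filter is
applied cascade-wide. Filter-trail records carry the dropped (sample, key)
tuples per stage, so `replay_trail` reproduces the output exactly from the
stage-0 table.

## Clonal reconstruction

The binomial mixture uses cluster-specific per-sample CCFs φ with
emissions `alt ~ Binomial(depth, f·φ)` where f is the variant's expected
VAF at CCF 1 (from purity and local CN; multiplicity 1 by default, with
`round(vaf·CN/purity)` available as an estimator). EM runs best-of-5
restarts per K with a fixed seed schedule; K minimizes BIC over 1..K_max;
the EM log-likelihood path is exposed and asserted non-decreasing in
tests. Tree enumeration prunes candidate parents by the crossing rule
(child ≤ parent + ε in every sample), then recursively enumerates parent
assignments, rejects cycles and applies the sum rule; ε defaults to 0.05.
Surviving trees are ranked by total residual slack ascending — the
tightest nesting explains the most CCF mass and ranks first. The founder
is the cluster with maximal CCF in the earliest sample, ties broken by
cluster size. Exhaustive enumeration is bounded at 10 clusters.

## Interactions

The permutation null shuffles the full label multiset across all cells
(the CellPhoneDB default); p = (1 + #{null ≥ observed})/(1 + n_perm) is
never 0. Expressed fractions use raw counts > 0, per component gene within
its own cell type, minimized over complex subunits.

## Problem sizes and determinism

Test and acceptance runs use the default cohort above, NMF K-selection
checks on 300 × 300 planted-program data (K 2..6, 10 restarts, 10 seeds),
and 100 random 4-6-cluster instances for the tree-enumeration oracle —
sizes chosen so the full suite runs on a laptop-class single core in a few
minutes. All randomness flows from explicit seeds through
`numpy.random.SeedSequence` spawning; identical configs and seeds give
byte-identical matrices and tables.

## Known limitations

Normal B subclusters that are homogeneous for one light chain satisfy the
light-chain-consistency channel on their own and surface as ambiguous
(not normal) unless other channels disagree — a faithful consequence of
the criteria under cluster-level evaluation. The binomial mixture has no
overdispersion (beta-binomial would be the extension). CCF estimation
assumes known purity and local copy number; purity/ploidy inference itself
is out of scope. The enumeration bound makes > 10 clone clusters
unsupported by design.
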