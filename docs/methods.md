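# Methods

This note documents the models, conventions and design choices behind
`dormantx`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Study design assumed throughout

Five PDX models, each contributing exactly one pre-castration ("active")
and one 12-week post-castration ("dormant") RNA-seq library — ten samples,
no biological replication within a model/stage cell. Every container and
rule in the package enforces this pairing. With n = 1 per cell, the
analysis is built on consensus threshold rules across models rather than
per-gene hypothesis tests; no p-values or multiple-testing corrections are
attached to the DE or persistence calls by design.

## Species partition

A read's record lists all its hits in a combined human+mouse reference
with species tags and alignment scores. Classification is set-based:
human-only, mouse-only, both, unmapped. The default **strict** mode keeps
exactly the human-only reads — the conservative reading of
"reads only mapped to the human genome" — because any read with a mouse
hit may be stromal. The **score_margin** mode additionally rescues
dual-mapping reads whose best human score exceeds the best mouse score by
at least `margin`; ties are dropped (conservative toward
human-specificity). Category counts always sum to the input size; this
conservation is asserted at run time. SAM input maps reference-name
prefixes (default `GRCh38_` / `GRCm38_`) to species and takes the score
from the `AS` tag, falling back to mapping quality.

## Quantification

* **Counting**: a retained read increments a gene iff its human hits name
  exactly one gene; multi-gene reads are discarded, mirroring
  unique-assignment (htseq-style) counting.
* **TPM** is computed directly from gene counts and effective lengths.
  No EM re-assignment of multi-mapping reads is attempted: TPM is used
  downstream only for thresholding at 1, where EM refinements are
  immaterial. All-zero input yields all-zero TPM by convention.
* **Size factors** are median-of-ratios over genes positive in all
  samples, then rescaled to geometric mean exactly 1. The rescale changes
  nothing that depends on between-sample ratios (fold changes,
  clustering) and makes normalization idempotent: re-deriving factors
  from a normalized matrix returns all ones to machine precision. A
  pseudocount offset (suggested 0.5) is available for sparse toy matrices
  with no all-positive gene. Note that a *global* rescale of all samples
  leaves median-of-ratios factors unchanged — the factors capture
  relative, not absolute, depth.
* **Fold change** is the per-model ratio of normalized counts with a
  pseudocount of 1 in numerator and denominator: finite for zeros, equal
  to 1 when both stages are zero, monotone in the dormant count and
  antitone in the active count. With one library per stage per model,
  shrinkage estimators are undefined; the plain ratio convention is
  isolated in `model_fold_changes` so an alternative could be swapped in.

## The three classification rules

All comparisons are inclusive at their thresholds (a gene with stage
means exactly 1024/1024 is persistent). Defaults: TPM ≥ 1, count ≥ 10,
expressed in ≥ 3 models; |log₂ fc| ≥ 1 in ≥ 3 models, same direction;
persistence floor 1024 normalized counts in both stages.

Two points were genuinely open and are settable:

* the "either stage" of the expression rule is evaluated within each
  model's own pair (per-model reading), not across the pooled stage;
* the persistence average is across models per stage
  (`persistence_scope="across"`); a stricter per-model mode exists, as
  does a raw-count mode (`persistence_on_normalized=False`). Normalized
  counts are the default because the persistence threshold is quoted as a
  power of two on the normalized scale used for the heatmaps.

A gene qualifying in both directions (possible only when the support
threshold is ≤ half the models) is called `none` with a warning, since a
consensus direction is the point of the rule.

## Immune gene groups and signatures

The packaged 20-group immunomodulatory curation (`immune_groups.gmt`)
covers chemokines and their receptors, interferons and receptors,
interleukins and receptors, TNF superfamily ligands and receptors, the B7
family, BMPs and their receptors, MHC and related genes, complement and
its regulators, mucins, colony-stimulating factors, toll-like receptors,
prostaglandin-E₂ metabolism, and TGF-β ligands/receptors. It is a
configurable input, not a canonical list: published appendix gene lists
are not publicly available, so the shipped curation is the package's own
and any GMT with unambiguous (one group per gene) membership can replace
it. The proliferation signature placeholder is sized at 131 genes to
match the published proliferation set's size — the per-model signature
median scales as 1/√(n genes), so the set size matters for recovery
precision — and the androgen-responsive placeholder has 15 genes; both
files carry `synthetic` in their names and descriptions.

Signature summaries use log₂(x+1) on normalized counts (standard for
count heatmaps and violins). The per-model paired shift is the median
over signature genes of log₂ dormant − log₂ active; negative means
reduced in dormancy. Two small biases are worth knowing: the +1 offset
compresses shifts for genes with modest baselines, and median-of-ratios
normalization absorbs part of a shift carried by a non-negligible
fraction of the matrix. Under the default generator (baseline 2⁷ counts,
signature ≈ 7% of 2000 genes) these add ≈ +0.07–0.09 log₂ to a planted
−2 shift; the recovery checks therefore evaluate the across-model
estimate, whose sampling noise (≈0.03 log₂) is far smaller than the
±0.2 recovery band, while single-model medians add ≈0.06 log₂ of noise.
The optional Wilcoxon signed-rank comparison pairs *genes* (not
biological replicates) within one model and is an interpretive add-on,
not a calibrated test of the study design.

## Discriminative gene selection

A `RandomForestClassifier` (1000 trees, unlimited depth,
`max_features=None`, fixed seed) is trained on all ten samples over
log₂-normalized immune-gene expression; genes are ranked by impurity
importance (normalized to sum 1, ties broken lexicographically) and the
top k = 54 are selected — 54 being the size of the published
discriminative set; the cut rule is configurable. `max_features=None` is
deliberate: with ten samples, restricting the split-candidate set makes
impurity importance reflect bootstrap luck (pure-noise genes can
perfectly separate a bootstrap sample) rather than marginal
discriminative power, and destabilizes the ranking. Permutation
importance is offered as an alternative because impurity importance is
biased under correlated features. No held-out evaluation is meaningful at
n = 10; the contract is procedural fidelity and determinism, not an
error estimate.

## Clustering

Canberra distance uses the 0/0-term-contributes-0 convention. Ward.D2
applies the Lance–Williams recurrence to squared dissimilarities,

    d²(k, i∪j) = [(nᵢ+nₖ)d²(k,i) + (nⱼ+nₖ)d²(k,j) − nₖd²(i,j)] / (nᵢ+nⱼ+nₖ),

reporting heights as √d² — the `hclust ward.D2` convention, stated here
formulaically so the implementation stands alone. Ties are broken by the
smallest pair of cluster creation indices, making dendrograms
deterministic; heights are non-decreasing by reducibility of the Ward
criterion. Tests verify the merge sequence against an independent
per-step evaluation of the Ward criterion computed from the *original*
squared distances (centroid identity), and against scipy's `ward`
linkage through cophenetic distances. Rows are clustered on
log₂(normalized + 1) without z-scaling by default (the heatmaps this
mirrors are described as built on normalized counts); a z-scale flag
exists in the plotting helper because practice varies. Leaf order places
the earlier-created cluster left at each merge.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not any real PDX's expression profile.

* **Counts**: negative binomial with shared dispersion φ
  (Var = μ + φμ²; Poisson at φ ≤ 1e−8). Default φ = 0.05, a typical
  bulk-RNA-seq biological-replicate scale. Per-gene log₂ baselines are
  Normal(7, 1.5) — median 128 counts for expressed genes — shared across
  models, so planted ratios are exact in expectation.
* **Planted classes** (disjoint, recorded in `GroundTruth`): up/down DE
  genes with the dormant mean multiplied/divided by `de_fold` (default 4)
  in a configurable number of models (default all 5; planting in only 2
  of 5 exercises the consensus boundary); persistent genes pinned at
  `persistence_floor × margin` (default 2048) in both stages; signature
  genes (named from the packaged placeholder sets) reduced by
  `signature_reduction_log2` (default 2) post-castration. A signature
  reduction at or beyond the fold-change threshold is, by construction,
  consensus-down, and the ground truth labels it so.
* **Reads**: category proportions are unmapped, dual-mapping ("both"),
  and the remainder split human : mouse; human-unique mass is therefore
  `human_fraction · (1 − ambiguous − unmapped)`. Human reads carry one
  gene target (optionally a second, to exercise the counting ambiguity
  rule); "both" reads carry a human and a mouse hit with scores for the
  margin-rescue path. Effective lengths are log-uniform on
  [300, 10 000] nt.

What passing recovery tests shows — and does not. The generator has no
model-specific effects, no library-size imbalance, no isoform structure,
no correlated gene modules beyond the planted classes, and no
low-count/high-dropout regime. Recovery results (e.g. consensus-DE
sensitivity ≥ 0.95 at 4-fold/φ = 0.05) certify that the implementation
applies its rules correctly under the model's assumptions, not that the
rules achieve those operating characteristics on real tissue.

## Determinism and numerics

All pipeline randomness flows from one master seed, split per stage via
`numpy.random.SeedSequence` (children reduced mod 2³¹). Outputs contain
no timestamps; floats are written at six significant digits; two runs
with the same config and seed are byte-identical, and the test suite
asserts this. Degenerate inputs are handled explicitly: empty read sets
are an error for partitioning, all-zero counts give all-zero TPM,
matrices with no all-positive gene need the pseudocount fallback, and
Ward linkage validates symmetry/non-negativity before clustering.

## Problem sizes in the checks

The recovery suites run on 300-gene × 10-sample simulations (20–60
replicates per property) and 2000-gene simulations where the signature
fraction must be realistically small; the partition checks use 10⁴ reads
× 10 seeds; the linkage oracle covers n ≤ 6 exhaustively and n = 8
against scipy. These sizes give the quoted rates sampling errors well
inside the asserted margins while keeping the default test run fast.

## Known limitations

* The shipped gene-group curation and signature placeholders are
  package-defined stand-ins; analyses of real data should supply the
  lab's own GMTs.
* Fold changes are unshrunken ratios; genes with tiny counts in one
  stage can show large, noisy fold changes (mitigated, not removed, by
  the pseudocount and the expression filter).
* The species partition operates on per-read alignment summaries; it
  does not re-align, and cannot rescue reads whose aligner reported only
  the mouse hit.
* The discriminative ranking is a descriptive ordering at n = 10; it
  carries no generalization guarantee.
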