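# Methods

## Problem and model

The TCGA molecular taxonomy of endometrial carcinoma defines four
prognostic biotypes: POLE (ultramutated, best prognosis), MSI
(hypermutated), copy-number low (CNL) and copy-number high (CNH, worst
prognosis, TP53-driven). Genome-wide copy-number profiling is rarely
available in routine pathology, so this package reconstructs the four
groups from two affordable assays — a 13-gene targeted mutation panel and
8-marker microsatellite fragment analysis — with a supervised surrogate
for the copy-number split.

Classification is a fixed precedence hierarchy, mirroring biology: a
retained *POLE* exonuclease-domain mutation defines POLE regardless of
microsatellite status (ultramutation is upstream; POLE tumors may also be
MSI-High); otherwise MSI-High defines MSI; every remaining sample is
assigned CNL or CNH by a random forest over the 12 non-POLE gene
indicators. The hierarchy is total: every sample receives exactly one
label.

## Variant retention filter

A variant row is retained when all of the following hold:

* depth ≥ 600 reads and VAF ≥ 0.05 (closed bounds: "minimum" thresholds
  are read as inclusive);
* it is not benign: ClinVar assertions take precedence (pathogenic,
  likely-pathogenic and VUS kept; benign and likely-benign discarded even
  when an in-silico predictor disagrees); for ClinVar-unreported variants a
  damaging PolyPhen **or** deleterious SIFT call retains; when both
  predictors are unknown, protein-altering consequences (missense,
  nonsense, frameshift, in-frame, splicing) are kept as VUS and
  synonymous/intronic/regulatory rows discarded.

The either-predictor rule and the protein-altering tie-break are design
choices: the filter's intent is to drop only (likely) benign calls, and a
deterministic rule is needed where annotations are silent. Rejections are
counted by reason, so a sample filtered to zero is distinguishable from a
sample with no data. Gene status is the indicator of ≥ 1 retained variant;
off-panel genes are ignored with a logged count. Cohort medians use the
mean-of-central-pair convention so half-integral values (9.5
mutations/patient) are exact.

## MSI calling

Expert reading of capillary electropherograms is replaced by a
deterministic dominant-allele shift rule. For each STR locus the tumor and
normal traces are integer bp → peak-height histograms. Dominant alleles
are peaks reaching `rel_peak_frac` (default 0.2) of the tallest peak; a
marker is **unstable** when some dominant tumor allele lies more than
`shift_tol` (default 2 bp) from every dominant normal allele, **failed**
when either trace's total signal is below `min_signal` (default 100
units), **stable** otherwise. Failed markers shrink the denominator; a
sample with fewer than 5 evaluable markers is *indeterminate* rather than
microsatellite-stable (calling MSS from missing data would be
anti-conservative). MSI-High requires an unstable fraction ≥ 0.30 — with
all 8 markers evaluable that is ≥ 3 unstable, since 2/8 = 0.25 falls
short. Pre-made marker calls can be supplied directly for labs that export
calls only. Indeterminate samples fall through to the copy-number branch
with a warning, keeping the partition total.

## The copy-number surrogate forest

Training data are n × 12 binary matrices (panel genes minus POLE) labeled
CNL/CNH. The protocol: stratified 62/86 train/validation split
(deterministic per seed, class proportions within one sample of the full
set); mtry tuned over {1..12} by stratified 5-fold cross-validation
maximizing mean accuracy, ties broken toward the smaller mtry; final model
of 1000 bagged trees (uniform bootstrap, no class weighting) at the tuned
mtry. Cross-validation forests use 200 trees — a tuning-economy choice;
accuracy rankings over mtry stabilize well below 1000 trees on 12 binary
features, and the final model is always 1000 trees. The forest is
scikit-learn's `RandomForestClassifier`; predictions expose the vote
fraction, and models refuse to predict when the feature order differs from
the panel's.

Variable importance is mean decrease in Gini impurity
(`feature_importances_`, normalized to sum to 1); only ranks are
interpreted, as absolute Gini totals are data- and implementation-scale
dependent. Validation is summarized by the confusion-matrix suite with
exact small-sample forms: Clopper–Pearson 95% CI for accuracy, and McNemar
as the exact two-sided binomial test on discordant pairs (p = 1 for
balanced or absent discordance). κ = (p_o − p_e)/(1 − p_e) with chance
agreement from the marginal products.

## Statistics layer

Pearson chi-square (uncorrected by default — it reproduces the recomputed
TP53 × histology p ≈ 0.020 better than the Yates form, which is available
by flag) with zero margins rejected by name. Mutational-load comparisons
use the Wilcoxon rank-sum for two groups (exact for small tie-free
samples, tie-corrected normal approximation otherwise) and Kruskal–Wallis
for more. Survival uses the lifelines Kaplan–Meier estimator — median
survival is the first time S(t) ≤ 0.5, absent when unreached — and the
k-group log-rank test with hypergeometric expectations per event time;
fully censored input returns the null result with a warning rather than an
error.

## Synthetic data

The stochastic generators emulate the study conditions: a 96-patient
cohort in proportions 16/12/48/20 (POLE/MSI/CNL/CNH) and 148-sample
TCGA-like CNL/CNH training matrices (CNH fraction 0.395, matching a
no-information rate near 0.60). Per-group gene-mutation probabilities use
the observed group-conditional frequencies (e.g. CNH: TP53 0.75, PTEN
0.05, PPP2R1A 0.45; CNL: PTEN 0.604, TP53 0.146, PIK3R1 0.354, ARID5B
0.417, CTCF 0.313, RPL22 0.396; MSI: PTEN 0.75, ARID1A 0.583, RPL22
0.833). Frequencies not reported group-conditionally (PIK3CA, CTNNB1,
FBXW7 and several per-group cells) are filled once with values typical of
TCGA endometrial series — e.g. CNL CTNNB1 0.50 and PIK3CA 0.50 reflecting
endometrioid biology, near-zero CNH frequencies for endometrioid-type
genes. Raw variant loads are discretized log-normals matched to each
group's median (94/40/37/32) and clipped to the observed ranges; roughly a
quarter of rows are retained-grade, the rest engineered to fail exactly
one filter each. Survival is exponential, median-parameterized per group
(DFS 55.40/38.33/34.43/27.70; OS 55.40/38.60/42.57/30.53 months) with a
15% censoring fraction; censored subjects report a uniformly earlier
follow-up time.

The deterministic 96-sample reference cohort lays the constrained
quantities out combinatorially (gene memberships by greedy least-loaded
assignment inside each group; retained/raw count sequences chosen so group
and cohort medians and ranges are exact; 3 of the 16 POLE samples MSI-High
for 15 MSI-High overall; 5 POLE-hotspot carriers of 96; covariate margins
83/13, 79/17, 45/28/23 with every serous sample PTEN-negative) and draws
only cosmetic fields (positions, depths, VAFs) from the seeded generator,
so rebuilds are byte-identical per seed. A file-level checker re-reads the
emitted TSVs and recounts every constraint through the actual pipeline;
the build fails listing violations rather than relaxing anything silently.
Gene × covariate cross-tabs beyond PTEN × histology keep exact margins but
not exact cells; the manifest records them as best-effort.

What the generators do **not** emulate: linkage/co-occurrence structure
between genes (draws are independent Bernoulli given the group), real
allele sequences or repeat-length distributions, inter-marker correlation
in MSI, non-exponential survival shapes, and covariate–survival
confounding. Passing tests therefore demonstrate that the pipeline's
logic, conventions and protocol are correct under the stated marginal
structure, not that classification performance transfers to any real
cohort.

## Numerical choices and degenerate inputs

Seeds are taken modulo 2³¹ before reaching any RNG. Multi-allelic VCF rows
split into one record per ALT with per-allele VAF (lossless for gene-level
dichotomization); coordinates are 1-based as in VCF; unknown annotation
values normalize to unknown/unreported, never dropped silently. Malformed
HGVS-p on a POLE variant excludes it from the domain test (logged), so a
bad annotation can never assign POLE. Empty cohorts, zero contingency
margins, single-class training sets and empty rank-test groups are
explicit errors; empty or weak fragment traces are *failed* markers, not
exceptions.

## Scale of the shipped analyses

Protocol-level properties are measured at desk scale: 20 seeded 148-sample
cohorts for the forest protocol, 200 simulations for the log-rank
type-I-error check and 50 seeds for the group-separation analogue, sizes
chosen to keep the full suite in a few minutes on one CPU while leaving
binomial noise well inside the asserted bands.

## Known limitations

* The copy-number labels of the surrogate's training data are taken as
  ground truth; no copy-number segmentation is performed or validated.
* ClinVar/PolyPhen/SIFT annotations are consumed, never computed; the
  filter is only as good as the upstream annotation.
* Multivariate Cox modeling and the clinicopathological-feature model
  variant are out of scope, as are raw `.fsa` trace parsing and
  alignment/variant calling.
* With the group survival medians above, exponential event times and
  n = 96, the 4-group log-rank has only ≈ 34% power at α = 0.05
  (Schoenfeld noncentrality ≈ 3.8 with ~82 events; ~270 subjects would be
  needed for 80%), so significant group separation should not be expected
  from a single synthetic cohort of this size.
* Under the generator's frequency structure TP53 and PTEN are nearly
  equally informative (single-split Gini gains 0.176 vs 0.148), so the top
  importance rank alternates between them across seeds; a stable TP53-first
  ordering additionally requires the stronger TP53 dominance seen in real
  TCGA copy-number-high tumors.
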