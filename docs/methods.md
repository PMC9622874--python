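# Methods

This note documents the models and procedures implemented in `crosstalk`,
the parameters that matter, the numerical choices made where the design
was genuinely open, what the synthetic-data generator does and does not
emulate, and known limitations.

## Hub selection on bipartite layers

Each interaction layer (mRNA–miRNA, miRNA–lncRNA, drug–lncRNA) is an
unweighted bipartite graph whose node sets are exactly the identifiers
observed in the (deduplicated) edge list, plus any explicitly supplied
isolated nodes kept at degree 0.  "Significant" nodes are selected by
whole degree tiers: tiers are scanned in descending degree order and
accumulated while the cumulative count stays within `hub_max_nodes`
(default 15).  A tier is taken whole or not at all — ties are never
broken, mirroring how a degree threshold behaves in practice.  If even
the top tier exceeds the budget it is returned whole with an overflow
flag.  Isolated nodes never qualify.  At the study's scale this rule
yields 7 miRNAs (one degree-4 tier, since the next tier is large) and 11
lncRNAs (a degree-7 tier of 3 plus a degree-6 tier of 8).

Identifiers are compared case-insensitively after trimming, because the
upstream databases mix spellings (e.g. `hsa-miR-17-5p`); the first-seen
spelling is preserved in output.

## Drug sign logic

A lncRNA enters labeling only when its regulation direction is known and
identical in both diseases.  For such a lncRNA, a drug effect is
*therapeutic* iff it opposes the disease direction — (up, decrease) or
(down, increase) — and *exacerbating* otherwise.  Effects on unknown or
disease-discordant lncRNAs are skipped with a warning, not treated as
contradictions, and a drug whose every edge is unsignable is excluded
rather than guessed.  Drugs with both signs among their signable edges
are contradictory and removed before partitioning; a mixed-sign drug
reaching the partition step is a hard invariant error.  Duplicate
(drug, lncRNA) records with opposite effect verbs are refused outright —
conflicting multi-study reports need manual curation, not a silent
majority vote.  Free-text verbs map onto increase/decrease through a
controlled vocabulary (`inhibit`, `silence`, `downregulate` → decrease;
`overexpress`, `elevate`, `upregulate` → increase), extensible per call.

The packaged drug-class table reports each drug's lncRNA partners and its
final class but not the individual effect verbs; the shipped
`table5_effect_records()` back-fills each verb as the unique direction
consistent with the class and the lncRNA's direction.  This
reconstruction is exact whenever the class is correct, because the sign
rule is deterministic per edge.

## Feature-selection cascade

Four filters, applied in a fixed order to the descriptor matrix of the
labeled drugs:

1. **Constant removal** — a column with at most one distinct non-missing
   value is dropped (missing entries are ignored when judging constancy).
2. **Correlation pruning** — pairwise-complete Pearson correlations are
   computed once; every upper-triangle pair with |r| above the cutoff
   (default 0.9) flags the member with the larger mean absolute
   correlation (ties flag the earlier column).  Correlations are *not*
   recomputed after drops.  This replicates the classic single-pass
   heuristic (the non-exact mode of caret's `findCorrelation`, which a
   test uses as an independent oracle); it can over-remove relative to an
   iterative re-check, and it is column-order dependent in the tie case —
   a regression test freezes the documented behaviour.
3. **Entropy filter** — plug-in Shannon entropy in nats over an
   equal-width histogram of the observed range (default 10 bins; a
   uniform 10-bin feature scores ln 10 ≈ 2.30, a balanced two-point
   feature ln 2 ≈ 0.69).  Features below the threshold (default 1.5 nats)
   are dropped.  Bin count and threshold are config-exposed because the
   histogram convention is a genuine free choice; natural logs match the
   common entropy-function default.
4. **t-test** — two-sample Welch t-test per descriptor between the two
   classes (pooled-variance optional), keeping raw p < alpha (default
   0.05).  No multiplicity correction by default, matching the original
   procedure; a Benjamini–Hochberg switch exists but is off.  Rows
   missing a value are excluded from that descriptor's test only.

The cascade is idempotent and row-permutation invariant.  With ~300
surviving null columns at alpha = 0.05, roughly a dozen noise columns are
expected to pass the t-test by chance alongside the truly informative
ones; the cascade controls the per-feature error rate, not the family-wise
one, by design.

## Random forest

scikit-learn's `RandomForestClassifier` supplies the ensemble; tree count
defaults to 100.  The out-of-bag error curve is grown with warm starts in
steps of 5, and the automatic choice is the smallest forest within 0.005
of the curve minimum — a concrete rule standing in for an
"error-vs-accuracy trade-off" judgement.  Cross-validation is stratified
(with 16/24 classes, unstratified 5-fold splits can be degenerate); every
drug is tested exactly once, and the pooled accuracy (correct/total over
all out-of-fold predictions) is the headline number, with the fold mean
reported alongside since the two conventions differ.  Fold models use
seed + fold-index so a fixed seed gives a bit-identical report.

## Applicability-domain screening

Stage order: atom-count filter (keep nATOM ≥ 7; the "remove below 7"
reading is adopted and the bound is config-exposed) → drop drugs missing
any selected descriptor → leverage cut → one-class SVM → probability
ranking.  Leverage is h_i = x_iᵀ(XᵀX)⁻¹x_i with no intercept column
appended; the +1 in p = |F| + 1 enters only the threshold
h* = 3p/n.  A rank-deficient Gram matrix falls back to the Moore–Penrose
pseudo-inverse with a logged warning.

By default the basis X and the count n are the screened library itself
(`ad_basis="screening"`), which reproduces the printed arithmetic
3·(6+1)/2304 = 0.0091; the textbook QSAR convention (training matrix as
basis) is available as `ad_basis="training"`.  The screening-basis choice
has a known weakness the synthetic experiments expose: a *cluster* of
extreme outliers dominates XᵀX and masks itself (each member's leverage
falls below h*), so the leverage stage removes few of them.  The
one-class SVM — trained on the training drugs only, on descriptors
standardized by training mean/SD, with nu = 0.1 and
gamma = 1/(w · pooled variance) by default — catches what leverage
misses; the end-to-end guarantee (planted far-outliers never reach
ranking) holds through the two filters jointly.

Ranking applies the probability threshold (default 0.95) to the larger
class probability — the original rule does not say which class's
probability is thresholded, and the max-class reading keeps every drug in
at most one list.

## Synthetic data

Generation is a pure function of (spec, seed) via
`numpy.random.default_rng` with per-component seed sequences; identical
spec + seed gives byte-identical outputs, and every generator returns its
ground truth.

* **Networks** — planted hubs receive `hub_degree` distinct left partners
  outright; every other right node gets exactly one uniform partner
  (databases only list interacting molecules) plus Bernoulli background
  edges.  Defaults (7 left, 412 right, background 0.01, 7 hubs of degree
  6) keep the hub tier cleanly above the background maximum, so hub
  recovery at a budget equal to the planted count is essentially
  deterministic.
* **Effect tables** — each drug is contradictory with probability ρ
  (one therapeutic plus one exacerbating edge); the remainder split
  positive/negative in a fixed proportion (default 0.4, the study's
  16/40) with 1–3 uniformly-signed edges each.
* **Descriptors** — informative columns are Gaussian with a class mean
  gap of δ pooled SDs (default 3); nuisance noise is log-normal to mimic
  the right-skew of real constitutional descriptors and to stress the
  entropy filter; duplicated pairs differ by 0.1% jitter (|r| > 0.95 by
  construction); low-entropy columns put ~95% of mass on one value; an
  integer atom-count column is appended.  The class labels can be
  supplied externally so the descriptor classes agree with a simulated
  effect table — the pipeline's stages then compose coherently.
* **Screen libraries** — in-domain drugs are jittered resamples of
  training rows (0.1 SD per column), carrying the source class as planted
  truth; far outliers sit `outlier_distance` SDs from the centroid *in
  every descriptor* (random sign per descriptor), so they remain extreme
  in any selected feature subset; a configured fraction gets atom counts
  below 7.

The `study_scale` preset mirrors the study's dimensions: 40 training
drugs (16/24), 1444 descriptor columns (6 informative, 293 constant, 300
duplicated pairs, 100 low-entropy, the rest log-normal noise, plus the
atom count), a 412-miRNA first layer, a 1700-lncRNA second layer, and a
2474-drug screen.

What the generator does **not** emulate: real PaDEL descriptor
distributions column-by-column (descriptor families are correlated in
blocks far richer than duplicated pairs), real interaction-network
topology beyond degree structure (no bipartite clustering or community
structure), dose/tissue context in drug effects, and structured
missingness.  Passing tests therefore demonstrate that the algorithms do
what they claim under the stated statistical structure — not that the
original biological conclusions are correct.

## Problem sizes used in checks

The acceptance script runs hub recovery over 50 seeds, cascade recovery
over 50 seeds, the null t-test rate over 100 seeds (600 null features),
the permutation baseline over 20 permutations, and the study-scale
end-to-end screen over 5 seeds; the test suite uses 100 seeds for hub and
cascade recovery, 200 for the null rate, and 20 for the end-to-end
screen.  These sizes make the binomial error of each rate small relative
to the asserted bands.

## Known limitations

* The leverage filter under the screening basis is vulnerable to outlier
  masking (see above); with `ad_basis="training"` it is not, at the cost
  of departing from the printed threshold arithmetic.
* The cascade's correlation stage inherits the single-pass heuristic's
  order dependence and over-removal; an exact iterative mode is a
  possible extension.
* Probability thresholds from a 100-tree forest are quantized to 1/100;
  the 0.95 cut is therefore effectively "at least 95 of 100 trees".
* The pipeline treats effect direction as binary and context-free; the
  source databases' cell-line and dose context is out of scope.
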