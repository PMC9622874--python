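# crosstalk

Diabetes mellitus (DM) and Alzheimer's disease (AD) share molecular
dysregulation anchored by brain insulin resistance, and several long
non-coding RNAs (NEAT1, XIST, H19, MALAT1, ...) are consistently
mis-expressed in both diseases.  `crosstalk` is a reusable implementation of
a drug-repurposing workflow built on that observation: it walks from layered
RNA interaction networks to a labeled drug set, selects molecular descriptors
that separate helpful from harmful drugs, trains a random-forest classifier,
and screens an external drug library inside the model's applicability domain
to propose repurposing candidates and adverse-drug warnings.

It is aimed at computational biologists and cheminformaticians who have
edge lists (mRNA–miRNA, miRNA–lncRNA, drug–lncRNA), per-disease lncRNA
regulation directions, and PaDEL-style descriptor matrices, and want the
whole chain — or any single stage — as tested, scriptable functions.

## The method

1. **Hub extraction.**  Bipartite networks are built per layer and
   "significant" nodes are whole top degree tiers, accumulated while the
   running total stays within a budget (default 15; reproduces 7 top-tier
   miRNAs and 11 top-two-tier lncRNAs at the study scale).
2. **Drug labeling.**  For a lncRNA with a consistent disease direction, a
   drug's effect is *therapeutic* iff it pushes expression against that
   direction: (up, decrease) or (down, increase).  Drugs with mixed signs
   across their lncRNA partners are contradictory and removed; the rest
   split into D⁺ (uniformly therapeutic) and D⁻ (uniformly exacerbating).
3. **Feature selection.**  A four-stage filter cascade over the descriptor
   matrix of the labeled drugs: drop constants → prune |Pearson r| > 0.9
   pairs by the mean-absolute-correlation heuristic → drop descriptors with
   histogram Shannon entropy < 1.5 nats (10 equal-width bins) → keep
   descriptors with two-sample t-test p < 0.05 between D⁺ and D⁻.
4. **Classification.**  A random forest (default 100 trees) over the
   selected descriptors F, with out-of-bag error curves for the tree-count
   choice and stratified 5-fold cross-validation for reporting.
5. **Screening.**  An external library passes an atom-count filter
   (nATOM ≥ 7), a missing-feature drop, the leverage applicability-domain
   cut h_i = x_iᵀ(XᵀX)⁻¹x_i against h* = 3(|F|+1)/n, and a one-class RBF
   SVM novelty filter, before drugs with class probability ≥ 0.95 are
   ranked as positive (repurposing) or negative (warning) candidates.

A synthetic-data module generates every input with planted ground truth
(hub nodes, contradiction rates, class-separating descriptors, in-domain
and far-outlier screen drugs), so the full pipeline is testable offline.

## Worked example

```bash
crosstalk simulate --out demo_in --seed 3          # study-scale synthetic tables
crosstalk run-all --in demo_in --out demo_out --seed 3
```

which prints (seed 3):

```
pipeline complete; manifest at demo_out/manifest.json
  n_mrna: 7
  n_mirna: 412
  n_lncrna: 1700
  n_mirna_hubs: 7
  n_lncrna_hubs: 7
  n_tripartite_edges: 56
  n_drugs_labeled: 40
  n_positive: 16
  n_negative: 24
  n_contradictory_removed: 0
  n_descriptors_input: 1444
  n_descriptors_selected: 26
  n_trees: 100
  oob_chosen_n_trees: 25
  cv_correct: 39
  n_screen_input: 2474
  n_screen_small: 138
  n_screen_missing: 0
  n_screen_high_leverage: 246
  n_screen_ocsvm: 873
  n_screen_retained: 1217
  n_candidates_positive: 273
  n_candidates_negative: 405
```

Reading: from a synthetic world shaped like the study (7 mRNAs, 412
miRNAs, 1700 lncRNAs; 40 drugs splitting 16 positive / 24 negative; 1444
descriptors), the cascade keeps 26 descriptors (the 6 planted informative
ones plus chance t-test survivors), the forest classifies 39 of the 40
training drugs correctly out-of-fold, and of 2474 screened drugs 1217
survive the applicability-domain stages, 273 of which are confident
(p ≥ 0.95) repurposing candidates.  `demo_out/` holds the per-stage TSV reports
(`feature_selection.tsv`, `cv_report.tsv`, `screening_report.tsv`,
`candidates.tsv`) and the reproducibility manifest.

The same stages are available as library functions
(`crosstalk.networks.select_hubs`, `crosstalk.labeling.label_drugs`,
`crosstalk.features.select_features`, `crosstalk.classify.cross_validate`,
`crosstalk.screening.run_screening`) and as individual subcommands
(`network`, `label`, `select-features`, `train`, `screen`).

Reference tables transcribed from the study (selected nodes and degrees,
lncRNA disease directions, the 40-drug class table) ship with the package:

```python
from crosstalk import load_fixture
from crosstalk.core_io import table5_effect_records
from crosstalk.labeling import label_drugs

labels = label_drugs(table5_effect_records(), load_fixture("table4_directions"))
len(labels.negatives), len(labels.positives)   # (24, 16)
```

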