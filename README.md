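# tcrmotif

Sequence-based selection of the short peptide motifs that make a peptide a
strong binder of a specific T-cell receptor (TCR).

High-throughput screens of peptide-MHC libraries (e.g. yeast display with
deep sequencing) yield thousands of fixed-length peptides, each with a
post-selection read count that is a proxy for TCR binding strength. This
package implements the full analysis path from such a library to
position-resolved binding motifs, for immunologists and computational
biologists studying TCR specificity and cross-reactivity:

1. **Labeling** — peptides are scored with a residue-level contact-energy
   model, E(s) = Σ_{(t,p)∈C} J[type(t), s_p], where C is the TCR-peptide
   contact map (pairs within r_max = 8.5 Å) and J a 20x20 pairwise energy
   matrix (both inputs). Energies are standardized against an ensemble of
   1,000 randomized decoys per strong binder, Z = (E − μ)/σ; the
   strong/weak threshold is the midpoint between the class peaks of the
   Z-score histograms, mapped back to a read-count threshold; classes are
   balanced by undersampling the weak binders.
2. **Featurization** — amino-acid / dipeptide / tripeptide composition
   (f_i = N_i/L, f_ij = N_ij/(L−1), f_ijk = N_ijk/(L−2); 20 / 400 / 8000
   features), combined N-gram vectors (8420 columns), or global
   physicochemical descriptors via an adapter; min-max normalization to
   [0,1] fitted on training rows only.
3. **Selection** — LASSO, minimizing (1/2n)‖y − Xw − b‖² + λ‖w‖₁ with λ
   chosen by cross-validated held-out MSE; nonzero weights ranked by |w|
   are the discriminative motifs.
4. **Evaluation** — repeated stratified 80/20 splits, logistic-regression
   baseline on the selected features; Accuracy, Recall, F1, MCC, AUC.
5. **Mutation scan** — each selected di/tripeptide motif is substituted at
   every position of a baseline peptide; positive energy gains, weighted by
   |w|, are aggregated into a 20 x L amino-acid-by-position heatmap that
   localizes the motif.

A synthetic-data module generates libraries with planted motifs and matched
energy systems so every stage can be verified against known ground truth.
See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Run the whole pipeline on a synthetic library (140 strong / 1400 weak
13-mers, tripeptide `AFF` planted at positions 3–5 with probability 0.9,
per-contact energy boost δ = 3):

```
$ tcrmotif all --n-strong 140 --n-weak 1400 --seed 1 --out demo
INFO tcrmotif.pipeline: labeling: z threshold 3.583 (peaks 7.484 / -0.318) -> read threshold 56
category repeat  accuracy  recall       f1     mcc     auc
   ngram   mean     0.934   0.934 0.933863 0.87109 0.93752
all: artifacts in demo
```

Reading the output: the strong-binder Z peak (7.48) and the background peak
(−0.32) are split at their midpoint 3.58, which corresponds to a
read-count threshold of 56; on the balanced, labeled library the logistic
baseline on LASSO-selected N-gram features reaches mean accuracy 0.93 and
AUC 0.94 over 10 stratified splits. (With 10% of strong binders carrying no
motif by construction, the attainable AUC is capped at 0.95 — see
`docs/methods.md`.) The ranking in `demo/ranked_features_ngram.csv` puts
the planted motif first:

```
feature,weight,rank
NG3_AFF,0.8243380432598941,1
```

and the scan heatmap (`demo/heatmap.csv`) peaks exactly on the planted
cells — F at positions 4 and 5 (value 1.00) and A at position 3 (0.75).

Each stage is also available separately (`simulate`, `label`, `featurize`,
`select`, `evaluate`, `scan`), reading and writing plain CSV/TSV/FASTA, and
as library functions (`tcrmotif.run_study`, `tcrmotif.label_library`, ...).
Every run writes a JSON manifest with the config, seed and content hashes;
identical (config, seed) reproduce outputs byte for byte.

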