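# Methods

## Problem and model

`tcrmotif` identifies short peptide motifs that distinguish strong from weak
binders of a fixed T-cell receptor (TCR), given a post-selection peptide
library (sequences of fixed length *L*, default 13, each with a sequencing
read count) and a residue-level contact-energy model of the TCR-peptide
interface.

The energy model is deliberately coarse: a contact map *C* — the set of
(TCR residue, peptide position) pairs whose representative points (Cα when
derived from a structure) lie within *r*max = 8.5 Å, cutoff inclusive — and a
20x20 pairwise energy matrix *J* indexed by (TCR residue type, peptide
residue type), not assumed symmetric. A peptide *s* scores

    E(s) = Σ_{(t, p) ∈ C} J[type(t), s_p]

with the convention that higher *E* means stronger predicted binding. *J* and
*C* are inputs (for real systems they come from a trained pairwise-energy
model and a crystal structure); this package never trains *J*.

## Pipeline stages

**Labeling.** The *n*top highest-read peptides (default 500) are the
calibration cases; the top *n*train of those (default 140) are presumed
strong. Each presumed-strong peptide contributes 1,000 randomized decoys —
i.i.d. uniform draws over the 20-letter alphabet at every position, not
shuffles, so the decoys play the role of the unselected sequence background.
Case energies are standardized against the pooled decoy ensemble
(Z = (E − μ)/σ, population σ). The class threshold is the midpoint between
the two class peaks, where each peak is the center of the class's highest
histogram bin on a shared 50-bin grid spanning the pooled range (ties go to
the lowest such bin). The Z threshold is mapped to a read-count threshold
**rank-to-rank**: the cases are ranked by Z and by reads independently, and
the read count at the same rank as the Z-threshold cut becomes the read
threshold. A per-case map (take the reads of the single smallest-Z case
above threshold) is also provided, but the rank-aligned map is the pipeline
default: with i.i.d.-uniform decoy-like weak cases, roughly 0.7% of weak
calibration cases clear the midpoint threshold by chance (two lucky contact
matches), and under the per-case rule one such outlier with a read count of
1 collapses the threshold and destroys the labels. Labels are then assigned
to the whole library (reads ≥ threshold → class 1, boundary inclusive) and
classes are balanced by undersampling: all strong binders are kept and an
equal-size weak subset is drawn uniformly without replacement (if the weak
class is already smaller, it is kept whole with a warning — no
oversampling).

**Featurization.** Three feature families over the canonical alphabet
ACDEFGHIKLMNPQRSTVWY (column identity depends on this order):

* composition of order *k* ∈ {1,2,3}: overlapping-window *k*-mer fractions
  with denominators *L*, *L*−1, *L*−2 (names `AAC_A`, `DPC_AF`, `TPC_AFF`);
  each block sums to 1;
* combined N-gram vectors over the full fixed vocabularies (20 + 400 + 8000
  = 8420 columns; names `NG1_`/`NG2_`/`NG3_`), in frequency mode identical
  blockwise to the compositions, or as raw counts;
* an adapter for external global physicochemical descriptors. It calls the
  propy package when importable and passes descriptor names through
  verbatim; otherwise it falls back to the composition-based descriptor
  families propy defines (20 amino-acid + 400 dipeptide composition values,
  as percentages, under propy's names) and logs a warning once.
  Autocorrelation/CTD/sequence-order descriptor math is intentionally not
  reimplemented.

Features are min-max rescaled to [0,1] with extrema learned from training
rows only; test values outside the training range are clipped (the rescaling
formula is silent on extrapolation and clipping preserves the [0,1]
contract), and features constant in training map to 0 (the formula is
undefined there).

**Selection.** LASSO on the 0/1 label treated as a real response:
minimize (1/2n)‖y − Xw − b‖² + λ‖w‖₁, solved by scikit-learn coordinate
descent (tolerance 1e-10; coefficients below 1e-12 in magnitude snapped to
exact zero so sparsity semantics are clean). Squared loss — not logistic
loss — is used because λ is chosen by cross-validated held-out MSE. The
default grid is 30 log-spaced points in [1e-4, 1]; k = 5 folds; exact MSE
ties resolve to the larger (sparser) λ; a fixed λ can be supplied instead
(typical informative values on these data sit around 0.005–0.015). At
λ ≥ λmax = max_j |x_jᵀ(y − ȳ)|/n the zero vector is returned exactly
(KKT stationarity). Nonzero weights, ranked by |w| with a stable name
tie-break, are the selected motifs.

**Evaluation.** Repeated stratified shuffle splits (default 10 repeats,
80/20) on the balanced set; test sets may overlap across repeats but are
disjoint from their own training split. Per repeat, normalization and
feature selection are fitted on training rows only (a `select_once` mode
fits selection once on the full matrix for figure-style reproduction — it
is leakier and off by default). The baseline classifier is logistic
regression with a vanishing ridge stabilizer (C = 1e8) whose only purpose
is a finite optimum under complete separation; cutoff fixed at 0.5.
Metrics: Accuracy; class-weighted Recall and F1 (on balanced test sets
weighted Recall equals Accuracy exactly, which is why those columns pair
up); MCC with the 0-when-any-factor-is-0 convention; rank-based AUC with
half credit for ties, reported as missing when the test truth is
single-class. If selection returns no features, the repeat is scored by the
null model (constant probability 0.5) with a warning rather than aborting
the whole evaluation — this keeps label-shuffled controls well defined.

**Mutation scan.** Each selected di/tripeptide motif is written over a
baseline peptide at every feasible start (overwrite, never insertion —
peptide length is fixed) and the energy delta against the baseline is
recorded. Placements with positive delta are folded into a 20 x L heatmap:
H[a, p] sums |w_motif| · ΔE over placements putting residue *a* at position
*p* (`weighted` mode), or plain ΔE (`indicator` mode — both are provided
because the choice of whether selection weights enter the map is a
presentation decision); the matrix is divided by its maximum when positive.
Negative-ΔE rows stay in the exported scan table for weak-binder analysis.
In the synthetic study the scan baseline is the weakest homopolymer (the
letter whose *L*-fold repeat minimizes *E*): scanning against the optimal
binder itself yields no positive deltas by construction, whereas a
motif-free baseline localizes the planted positions.

## Synthetic study conditions

The generator emulates the post-selection structure of a yeast-display
screen. Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| peptide length L | 13 | fixed-length 13-mer libraries |
| planted motif | `AFF` at positions 3–5, plant probability 0.9 | the canonical enriched tripeptide; 0.9 leaves a realistic fraction of high-read peptides without the motif |
| background | uniform over 20 residues | the empirical library background is unknown; configurable |
| strong reads | negative binomial, mean 150, dispersion 2 | heavy-tailed counts, well separated from the excluded-read regime |
| weak reads | Bernoulli(0.5) over {0, 1} | excluded peptides in the real screens had reads of zero or one |
| energy boost δ | 3.0 per contact | "δ large" regime: carrier Z ≈ 7.5 vs decoy mode ≈ −0.4 |
| library | 140 strong / 1400 weak | 140 matches the presumed-strong training count; 10:1 imbalance exercises undersampling |

The matched energy system gives each planted-motif position one dedicated
TCR residue of a distinct residue type and sets exactly the entry (that TCR
type, the motif residue) to δ, zero elsewhere. Hence the wild type scores
δ x (number of motif positions), a motif-free peptide scores 0, and a
uniform decoy's expected energy is (number of contacts) x δ/20 — all used
as exact oracles in tests. Synthetic coordinate tables place the peptide
collinearly at 6 Å spacing and each TCR residue off-axis above the centroid
of its contacted positions, with contacting pairs at ≤ r_max − 0.5 Å and
all others at ≥ r_max + 0.5 Å; requests with no such placement (e.g. one
TCR residue contacting two positions that straddle an uncontacted one)
raise an error instead of silently violating the requested map.

**What the generator does not emulate:** selection-round dynamics, a
realistic amino-acid background, correlation between read depth and motif
quality *within* the strong class (reads are drawn per class), MHC-anchor
constraints, and real energy matrices (the synthetic *J* is one-hot per
contact). Passing tests therefore demonstrate that the machinery recovers
planted structure under known conditions, not that real libraries are this
clean.

## Determinism and seeds

One global seed fans out to per-stage child seeds through
`numpy.random.SeedSequence` (all below 2³¹), so library generation,
decoys, undersampling, CV folds and evaluation splits are independently
reproducible; identical (config, seed) reproduce artifacts byte for byte
(hashed in the CLI run manifests).

## Known limitations

* With a single planted motif at plant probability *p*, the fraction
  1 − *p* of strong-labeled peptides carry no signal at all, so any
  sequence-based score is exchangeable between them and weak-class
  background: the expected evaluation AUC is capped at *p* + (1 − *p*)/2
  (0.95 at *p* = 0.9), and the measured mean sits slightly below the cap
  because undersampling can draw a few low-read motif carriers into class
  0. Reported AUCs on the synthetic study (≈ 0.94) must be read against
  this ceiling, not against 1.
* The discrete synthetic energy spectrum (multiples of δ) makes ~0.7% of
  background sequences clear the midpoint threshold (two chance matches);
  this is why the rank-aligned read-threshold map is the default.
* The descriptor adapter exposes only composition-family descriptors when
  propy is absent; selected-descriptor names beyond those families are then
  unavailable.
* `fit_lasso` with `standardize_columns` applies fold-internal
  standardization during CV but the final refit is on the unstandardized
  matrix; the flag is off by default because columns arrive min-max
  normalized.
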