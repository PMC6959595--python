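# Methods

## The prediction problem

Given the amino-acid sequence of a transmembrane transport protein, the
task is to assign one of seven transported-substrate categories:
amino acid/oligopeptide, anion, cation, electron, protein/mRNA, sugar,
or other. The approach assumes that substrate specificity leaves a
signature in the residue composition of the protein family — stronger
in evolutionarily reliable alignment positions than in the raw sequence
— and that a set of pairwise discriminators can separate the classes
even when no single global decision boundary does.

## Composition encodings

All encodings operate on the 20-letter amino-acid alphabet in fixed
alphabetical order (ACDEFGHIKLMNPQRSTVWY); vector layouts are canonical
so feature tables are comparable across runs.

* **AAC** (length 20): `c_i = F_i / L`, the normalized residue
  frequencies over the `L` countable residues.
* **PAAC** (length 400): `d_ij = F_ij / (L − 1)`, normalized counts of
  ordered adjacent residue pairs, row-major over pairs. With `L`
  countable residues there are exactly `L − 1` pairs, so the vector
  sums to one.
* **PseAAC** (length `20 + λ`): the 20 frequencies plus λ sequence-order
  correlation factors
  `θ_k = (1/(L−k)) Σ_i Θ(R_i, R_{i+k})`, where `Θ(a, b)` is the mean of
  squared differences of three standardized residue properties:
  Tanford hydrophobicity, Hopp–Woods hydrophilicity and side-chain
  mass. Each property table is centred and divided by its population
  standard deviation over the 20 residues before use. The combined
  vector `s` weights the θ block by ω and divides everything by
  `Σ f + ω Σ θ`, so it sums to one; at `λ = 0` it reduces exactly to
  the AAC.

Parameters: `λ` (number of order factors) defaults to 10 — the value is
a package choice; it must stay below the countable sequence length and
10 retains meaningful order information for sequences of typical
transporter length. `ω` defaults to 0.05, the conventional weight; the
conventional admissible range 0.05–0.7 is accepted silently and values
outside it warn.

Non-standard residue codes (B, J, O, U, X, Z) are dropped from all
counts, as a gap would be, with a logged warning; a strict mode errors
instead. Composition formulas are defined only over the 20 natural
amino acids, so any numeric treatment of ambiguity codes would be
arbitrary.

## Alignment pooling and positional filtering

With evolutionary information, counts are gathered over **all rows** of
the protein's multiple sequence alignment: gaps and filtered cells are
ignored, the AAC denominator is the total number of counted residues
and the PAAC denominator the total number of counted pairs (pooled, not
per-row). Residues separated only by gaps or removed columns are
treated as adjacent — each row is compacted to its countable residues
before pairing; after a column is filtered its cells are
indistinguishable from gaps, and gaps are ignored when gathering
counts, so compaction is the only consistent reading. For PseAAC the
frequencies come from pooled counts while θ factors are computed per
row and averaged with equal weight; rows with countable length ≤ λ are
skipped with a warning. Pooling is invariant to row order and to
duplicating the full row set, and a one-row alignment encodes exactly
like the bare sequence (AAC/PAAC).

Positional filtering takes a per-column reliability index in [0, 9]
(the transitive-consistency-score convention) and **gaps out** every
cell of a column scoring below the threshold (default 4, the value at
which filtering helps most before discarding signal). Columns are
gapped in place rather than deleted so indices stay alignable to the
unfiltered alignment for positional analysis; for composition the two
are equivalent because gaps are never counted. Filtering is idempotent
at a fixed threshold, and raising the threshold never keeps more
columns.

Reliability normally comes from a T-Coffee `score_ascii` evaluation
report (the `cons` row; when absent, the rounded per-column mean of
per-residue digits). For fully offline runs a **fallback score** is
provided: round-half-up of 9 × (fraction of rows carrying the column's
modal non-gap residue), 0 for all-gap columns. The denominator is the
total row count, so sparsely populated columns score low. The fallback
is a plain conservation index, labelled as such in provenance metadata;
it is not a consistency score and numbers derived from it should not be
compared against consistency-based analyses.

External stages (homolog retrieval capped at 120 hits, TM-Coffee
alignment in PSI-Coffee mode with transmembrane templates, TCS
evaluation) are documented as exact command lines by
`external_msa_contract`; an opt-in runner executes them when the
binaries are present and reports a missing binary distinctly from a
tool failure. The package never requires them.

## The one-vs-one ensemble

For K classes, `K(K−1)/2` binary RBF-kernel SVMs are trained, one per
unordered class pair, each on the members of just those two classes.
Features are standardized (per-feature centre/scale fitted on the full
training set) before the kernel — RBF distances are scale-sensitive and
composition features span different magnitudes. A single (cost, γ)
pair is shared by all pairwise classifiers and selected by grid search
over whole-ensemble cross-validated accuracy on the grid
cost ∈ {2, 4, 8, 16}, γ ∈ {2e-5, 2e-4, 2e-3, 2e-2, 2e-1, 1}; grid ties
resolve to the smaller cost, then the smaller γ. When tuning is off,
the defaults are cost 8 and γ = 2e-3 (γ near 1/d for d = 400
standardized features).

Prediction applies every pairwise classifier and takes the modal class.
Vote ties are broken by the larger summed signed decision-function
margin accumulated over the tied class's pairwise classifiers, and any
residual tie by canonical class order — prediction is therefore fully
deterministic and invariant to classifier storage order. With K = 2
the ensemble is structurally a single binary SVM.

Cross-validation partitions the data uniformly at random (seeded, not
stratified, matching a plain random split; a stratified partition is
available behind a flag, off by default). Per fold, an
ensemble is trained on the other k−1 parts; results are per-fold
confusion matrices plus mean ± SD of overall accuracy and MCC across
folds. The default tuning protocol is **per-fold** grid search inside
each training split, which keeps the held-out fold untouched by
hyperparameter selection; "once" (tune on the full set first) and "off"
are available. `k = n` gives leave-one-out. A class missing from a
training split is logged and its pairs skipped for that fold rather
than aborting the fold.

## Evaluation metrics

From the K×K confusion matrix `C` (rows = actual, columns = predicted):
one-vs-rest marginals `tp = C_kk`, `fn = row_k − tp`, `fp = col_k − tp`,
`tn = N − tp − fn − fp` feed the classical sensitivity, specificity,
accuracy and binary MCC. Overall accuracy is `tr(C)/N`; macro averages
are unweighted per-class means. The overall multiclass MCC is
Gorodkin's

```
R_K = (N·tr(C) − Σ_k r_k c_k) / sqrt((N² − Σ_k c_k²)(N² − Σ_k r_k²))
```

which coincides with the binary MCC at K = 2 (verified numerically over
random 2×2 matrices against the closed form, and against
scikit-learn's implementation from label vectors). Zero denominators
yield a flagged NaN with a warning, never a silent zero — silent zeros
would distort macro averages. Percentages are printed with two
decimals; internal values keep full precision.

On the published seven-class benchmark matrix (120 independent test
proteins) this machinery reproduces the printed overall accuracy
(74.17%), overall MCC (0.69) and every per-class sensitivity and
specificity to two decimals, with one exception: the protein-class
specificity computes to 104/105 = 99.05 against a printed 99.07
(identical to the sugar row, suggesting a transcription slip). The
printed per-class accuracies and MCCs — and hence the macro averages
built from them — do not reconcile with the matrix under the standard
one-vs-rest definitions (e.g. amino-acid accuracy computes to 93.33
against a printed 91.75); the package asserts only the reconcilable
quantities and reports its own matrix-derived values for the rest.

## Positional analysis

Informative alignment columns (kept by the filter) are mapped to
ungapped positions of a chosen reference row by a gap-aware column
walk. Positions are partitioned relative to the TMS annotation
(1-based inclusive intervals on the ungapped sequence):

* **TMS interior** — the central `q = max(1, round(m/3))` positions of
  each TMS of length m, starting at `start + floor((m − q)/2)`. `m/3`
  never has fractional part 0.5, so the rounding rule is unambiguous.
* **TMS exterior** — remaining TMS positions.
* **non-TMS close** — within `margin` (default 10) positions of the
  nearest TMS residue, measured to the nearest residue, inclusive.
* **non-TMS far** — everything else.

Every position receives exactly one label; segment counts sum to the
sequence length, and `margin = 0` produces no close positions.
Per-protein informative rates (percentage of informative positions per
segment kind, NaN for empty segments) are compared between segment
kinds with a classical paired two-tailed Student t-test (t statistic
with n−1 degrees of freedom; p-value from the t distribution). Proteins
with an undefined rate in either member of a pair are dropped pairwise
— zero-filling would fabricate rates. All-zero differences give
t = 0, p = 1; a constant nonzero shift has zero difference variance and
is reported as degenerate rather than producing an infinite statistic.

The hydropathy profile is the per-column mean Kyte–Doolittle value over
non-gap residues (NaN for all-gap columns), carried together with the
reliability track and kept flags so informative columns can be
highlighted against membrane-spanning (positive-hydropathy) regions;
export is tab-delimited with optional matplotlib rendering.

## Synthetic data

The fixture generator emulates the structural features the pipeline
depends on, not real transporter families:

* **Class-biased dipeptide composition** — each class enriches a small
  disjoint set of ordered residue pairs (default 3 per class) in
  otherwise uniform random sequences; the enrichment factor scales the
  expected signature-pair frequency relative to the uniform 1/400
  baseline (factor 1 = indistinguishable classes; the default study
  condition is factor 20, 3 classes, 30 sequences per class, lengths
  120–200).
* **Alignments by mutation** — rows are independent per-cell mutations
  of a seed sequence (substitution rate 0.08, gap rate 0.03 by
  default); designated conserved blocks ("TMS-like") mutate at 0.2× the
  base rates, so their columns earn systematically higher fallback
  reliability.

All randomness flows through numpy's PCG64 generator under a mandatory
seed; identical specifications produce byte-identical files. Because
the class signal is planted in dipeptides, the generator guarantees
PAAC separability by construction — passing recovery tests demonstrate
that the encode–train–predict machinery preserves a real signal, not
that real transporter classes are this separable. Real data differ in
class imbalance, homology structure between sequences, composition
signals that are weaker and distributed, and alignment columns whose
reliability reflects consistency rather than simple conservation.

## Problem sizes and numerical choices

The test and acceptance workloads are sized for a desk machine: the
recovery benchmark uses 90 sequences (3 × 30) with per-fold grid search
over 24 points and 3 inner folds; the end-to-end pipeline check uses 18
proteins with 6-row alignments. The full published benchmark (780
training transporters plus Swiss-Prot-scale alignment construction) is
out of scope: its numbers depend on external databases and
alignment/consistency tools consumed here only via documented file
contracts.

Tolerances: probability-vector identities are asserted at 1e-9;
standardized property tables at 1e-9; metric reconciliations at the
two-decimal precision of the printed benchmark values. Determinism is
exact (seeded partitions, deterministic SVC fits, explicit tie-breaks).

## Known limitations

* The fallback reliability score is conservation-based; analyses of
  "informative positions" under the fallback measure conservation, not
  transitive consistency.
* PseAAC over an alignment (pooled frequencies + per-row averaged θ)
  is a package construction; alternative poolings are conceivable.
* λ for PseAAC is a package default (10); results are sensitive to it
  for short sequences.
* Uniform (unstratified) CV partitions can starve a small class in a
  fold; the affected pairs are skipped with a warning rather than
  re-balanced.
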