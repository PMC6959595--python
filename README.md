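# transub

Substrate-class prediction for transmembrane transport proteins.

Transporters move compounds — amino acids, anions, cations, electrons,
proteins/mRNA, sugars and others — across cell membranes, and roughly a
third of any proteome is membrane proteins, most of them poorly
characterized. `transub` predicts which of the seven substrate
categories a transporter handles from its sequence alone, by combining
three kinds of information:

* **Composition (C)** — the sequence is encoded as amino-acid
  composition (AAC, the 20 residue frequencies `c_i = F_i / L`), pair
  composition (PAAC, the 400 ordered dipeptide frequencies
  `d_ij = F_ij / (L − 1)`), or pseudo-amino-acid composition (PseAAC,
  the 20 frequencies plus λ sequence-order correlation factors
  `θ_k` built from standardized hydrophobicity, hydrophilicity and
  side-chain mass, weighted by ω and jointly normalized).
* **Evolution (E)** — instead of encoding the single sequence, the
  counts are pooled over all rows of a multiple sequence alignment of
  the protein's homologs (gaps never counted), so the vector describes
  the family.
* **Position (P)** — alignment columns carry a 0–9 reliability index
  (TCS-style); columns scoring below a threshold (default 4) are gapped
  out before pooling, restricting the encoding to informative positions.

The encoded vectors train a **one-vs-one SVM voting ensemble**: one
RBF-kernel binary classifier per unordered class pair — `K(K−1)/2 = 21`
for seven classes — each trained only on members of its two classes,
with prediction by majority vote (margin-based deterministic
tie-break). Evaluation implements the full multiclass suite: per-class
sensitivity/specificity/accuracy/MCC from one-vs-rest counts, overall
accuracy `tr(C)/N`, macro averages, and the Gorodkin multiclass MCC
`R_K` computed directly from the K×K confusion matrix.

A positional-analysis module maps informative columns back to ungapped
sequence positions, partitions positions by transmembrane segment (TMS)
geometry (interior third / exterior of a TMS, near / far from a TMS)
and compares informative-position rates between segment kinds with
paired two-tailed t-tests, alongside per-column Kyte–Doolittle
hydropathy profiles.

External tools (homolog search, TM-Coffee alignment, TCS evaluation)
are consumed via files; their exact command lines are documented by
`transub.msa_pipeline.external_msa_contract`, and a conservation-based
fallback reliability score lets the whole pipeline run offline.

## Worked example

Evaluate a predictor from its confusion matrix (tab-delimited with
class headers):

```sh
transub eval --confusion benchmark_cm.tsv
```

On the published independent-test confusion matrix of the seven-class
transporter benchmark (120 test proteins) this prints:

```
class            sens%   spec%    acc%     mcc
amino_acid       60.00   98.10   93.33    0.67
anion            58.33   96.30   92.50    0.57
cation           94.44   89.29   90.83    0.80
electron         80.00  100.00   98.33    0.89
protein_mrna     66.67   99.05   95.00    0.75
sugar            66.67   99.07   95.83    0.75
other            65.00   86.00   82.50    0.46
overall                          74.17    0.69
macro                            92.62    0.70
```

Row by row: the cation class is recovered with high sensitivity
(94.44% of true cation transporters found), while the electron class is
perfectly specific (no false electron calls). `overall` is the trace
fraction 89/120 = 74.17% and the overall MCC of 0.69 is the Gorodkin
multiclass correlation — the single most robust summary under the
benchmark's class imbalance.

Training and prediction on your own data:

```sh
transub train   --method PAAC --fasta seqs.fasta --labels labels.tsv \
                --cost 8 --gamma 2e-3 --out model.joblib
transub predict --method PAAC --model model.joblib \
                --fasta new_seqs.fasta --out predictions.tsv
transub cv      --method PAAC --fasta seqs.fasta --labels labels.tsv \
                --folds 5 --seed 1 --tune per-fold --out cv_summary.tsv
```

`--method` names the pipeline route: `AAC`/`PAAC`/`PseAAC` encode the
bare sequence, a `TMC-` prefix pools over per-protein alignments
(`--alignment`, one file per protein), and `TMC-TCS-` additionally
filters columns by reliability (`--scores`, T-Coffee `score_ascii`
files) before pooling. `predict` writes one row per sequence with the
winning class and the full 21-vote tally.

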