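# pssmrt — DNA-binding residue prediction from evolutionary profiles

`pssmrt` predicts which residues of a protein bind DNA, using only
sequence-derived information: the PSI-BLAST position-specific scoring
matrix (PSSM) of the chain, optionally augmented by predicted secondary
structure (PSIPRED) and solvent accessibility (SABLE).  It is aimed at
structural bioinformaticians who need interface predictions for
proteins without solved complex structures, and at anyone studying
which amino-acid pairings carry the protein–DNA recognition signal.

## Model

Each residue *i* is a sample described by a sliding window of size *w*
(default 13) over the chain's L×20 PSSM.  Raw log-odds scores *S* are
mapped to (0,1) with the logistic function S^(N) = 1/(1+e^(−S)), and the
window is encoded by the **PSSM relation transformation (PSSM-RT)**:

- **conservation** — the w×20 normalized window, flattened (20·w values);
- **pair relationships** — for every ordered amino-acid pair (r₁,r₂),
  Σⱼ S^(N)(i,r₂)·S^(N)(j,r₁) over the w−1 context positions j
  (20×20 = 400 values);
- **multi relationships** — Σ S^(N)(k,r) over the left and over the
  right half-window, target included (2×20 values);

giving 20·w + 400 + 40 dimensions (700 at w = 13).  Two further blocks
encode window composition / structure tracks / target identity, and
eight tabulated physicochemical properties per window position.

Non-binding residues outnumber binding residues roughly 5- to 14-fold,
so training is ensemble-based: the negatives are split into *n* disjoint
subsets of about the positive-set size, each subset plus all positives
trains an RBF-kernel SVM (grid-searched C, γ) and a random forest on
each of the three feature blocks (6·n base predictors), a committee is
grown greedily by disagreement rate on a held-out validation split
(stopping when the best candidate adds less than ε = 0.01 diversity),
and predictions are made by majority vote — ties go to the rare binding
class; the positive-vote fraction is the ROC score.

Binding labels come from complex structures: a residue is binding when
any of its atoms lies within 3.5 Å of any DNA atom.  Evaluation uses
SN, SP, ST = (SN+SP)/2, ACC, MCC and AUC under chain-level k-fold
cross-validation, with exact Wilcoxon signed-rank tests for paired
method comparisons.  Feature importance uses the discriminant weight
vector **W** = **A**ᵀ·**M**, where **A** aggregates signed SVM dual
coefficients per training instance and **M** is the PSSM-RT feature
matrix; the 400 pair-relationship weights are ranked and exported as a
20×20 grid.

## Worked example

The package ships a synthetic-fixture generator (no downloads needed)
that emulates the real inputs: background PSSMs, a planted
pair-relationship signal at binding positions, 1:5 class imbalance,
and a toy protein–DNA complex.

```bash
pssmrt fixtures --out-dir fx --chains 20 --length-min 30 --length-max 40 --seed 3
# INFO pssmrt: 20 chains, 680 residues (106 binding) -> fx

pssmrt train --fasta fx/chains.fasta --pssm-dir fx --labels fx/labels.tsv \
             --window 9 --seed 3 --model-dir model
# INFO pssmrt: partition sizes [103, 103, 102, 102, 102]; pool 30 predictors; selected 30; model -> model
```

With 106 positives and 512 training negatives the partition step built
n = 5 balanced subsets, hence 2 algorithms × 3 feature blocks × 5
subsets = 30 base predictors.

```bash
pssmrt predict --model-dir model --fasta fx/chains.fasta --pssm-dir fx | head -4
# chain     position  residue  label  score
# syn3_000  1         H        -      0.0667
# syn3_000  2         A        -      0.0667
# syn3_000  3         K        -      0.3667
```

`label` is '+' for predicted binding; `score` is the fraction of
committee votes for binding.  The labelling rule on the toy complex:

```bash
pssmrt label fx/toy_complex.pdb --out toy_labels.tsv
# A  1  R  +  3.000     (within 3.5 Å)
# A  2  K  +  3.500     (boundary is inclusive)
# A  3  A  -  3.600
```

And the discriminant-weight analysis recovers the planted pair (R,K) —
context rows enriched in R, target rows in K — as the top-ranked of the
400 pair relationships:

```bash
pssmrt analyze --model-dir model --fasta fx/chains.fasta --pssm-dir fx --out-dir analysis
# INFO pssmrt: top pair relationships: (R,K), (G,K), (P,K), (S,K), (V,K); ...
```

For real proteins, point `--pssm-dir` at PSI-BLAST ASCII PSSMs
(`psiblast -num_iterations 3 -evalue 0.001 -db nr -out_ascii_pssm ...`),
one `<chain_id>.pssm` per FASTA record, and derive labels with
`pssmrt label` from the complex PDB files.

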