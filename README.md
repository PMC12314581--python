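# homeval

A benchmarking toolkit for **remote-homology detection with protein
structures**, built for the question: if you search a query domain —
experimental structure or AlphaFold-style predicted model — against a
library of classified domains, how reliably does the best hit (or the
whole ranked list) recover the query's place in a hierarchical domain
taxonomy such as ECOD?

It is aimed at structural bioinformaticians who already have pairwise
similarity scores from a comparison tool (a structure aligner, BLAST,
an HMM–HMM search, Foldseek, ...) and need the evaluation machinery
around them: score normalization, taxonomy-aware statistics, honest
uncertainty estimates, and the dataset bookkeeping that makes a
benchmark blind.

## What it computes

**Score normalization** (`homeval.scoring`). Raw inter-residue-distance
log-odds scores S(a,b) grow with protein size and are normalized to

    Z(a,b) = (S(a,b) − m(x)) / σ(x),      x = √(N_a·N_b)
    m(x) = A_m·x + B_m,   σ(x) = A_σ·max(x, 40) + B_σ

with constants fitted on non-homologous pairs (defaults
A_m = 16.170350, B_m = −47.164564, A_σ = 23.503942, B_σ = −762.928232);
the clamp at x = 40 keeps σ positive for short peptides.  Also: the
self-score ratio R = 2S(a,b)/(S(a,a)+S(b,b)), the −log₁₀E transform for
sequence searches, the averaged TM-score, and a fitting routine to
re-estimate the constants from your own non-homolog scores.

**Evaluation** (`homeval.evaluation`). Over a query set Q and library L:

* **Top-1 accuracy** A(Q,L): the fraction of queries whose
  highest-scoring library domain (identical domain excluded) shares the
  query's taxonomy at the chosen level (H = homology, X = possible
  homology, F = family).
* **Restricted precision–recall**: R(S) = N(S_ql > S ∧ T_q = T_l)/N(T_q = T_l)
  and P(S) = N(S_ql > S ∧ T_q = T_l)/N(S_ql > S), counted only over
  ordered Q×L pairs with q = l excluded and strict `>` comparison; the
  F_β = (1+β²)PR/(β²P+R) summaries are maximized over all observed
  thresholds, and a threshold table reports the operating points at
  precision ≥ 0.99 / ≥ 0.90 and max F₀.₅ / F₁ / F₂.

**Bootstrap inference** (`homeval.bootstrap`). Percentile confidence
intervals and one-sided p-values by resampling the *query set only*
(B = 1000, α = 0.05 by default; CI endpoints at ranks ⌈Bα/2⌉ and
⌊B(1−α/2)⌋ of the sorted replicate values).  The library is never
resampled — a diagnostic function demonstrates the downward bias that
library resampling would introduce.

**Dataset operations** (`homeval.datasets`). The cohort rules of a blind
benchmark: a regularity filter (≥ 40 residues, ≥ 4 secondary-structure
elements, not obsolete), a predicted-model correspondence filter
(identity ≥ 95%, aligned ratio ≥ 95%, ≥ 40 aligned residues), the
train/test split at the 2021-02-15 template cutoff, "no sequence hit at
E < 0.001" query subsets, stratification by residue-averaged pLDDT
(bins 50–60 … 90–100) and by experimental method (X-ray/NMR/EM), and
secondary-structure composition/element counts.

**Synthetic benchmarks** (`homeval.synthetic`). A generator producing a
complete cohort — balanced X.H.T.F taxonomy, relation-dependent score
distributions, pLDDT-dependent degradation of predicted-structure
scores, methods, release dates, planted hit lists — together with the
ground truth needed to test every pipeline end to end, plus writers for
all on-disk fixtures (domain tables, score TSVs, AlphaFold-style PDB
files with pLDDT in the B-factor column, DSSP files).

## A worked example

`examples/worked_example.py` builds the canonical two-query toy
benchmark: queries q1 (family 1) and q2 (family 2) against a six-domain
library over three families.

```text
top-1 accuracy: 0.5
  q1 -> l1  same family: True
  q2 -> l5  same family: False
evaluated query-library pairs: 12
at threshold S = 5.0: precision = 0.4, recall = 0.5
F1 at that threshold: 0.44
```

q1's best hit is a family-1 domain (correct), q2's best hit is in
family 3 (wrong), so A = 1/2.  Of the 12 ordered query–library pairs,
4 share a family; at the threshold 5 pairs score above it, 2 of them
same-family, so P = 2/5 = 0.4 and R = 2/4 = 0.5, and
F₁ = 2PR/(P+R) = 0.44.  The other scripts in `examples/` cover score
normalization, full-benchmark evaluation, bootstrap inference,
pLDDT/method stratification, and dataset construction, each printing
and explaining its numbers.

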