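# Methods

This note documents the statistical procedures homeval implements, the
parameter choices that matter, the design decisions taken where more
than one reasonable convention exists, and what the synthetic benchmark
does and does not establish about real data.

## Evaluation statistics

**Setting.** A benchmark is a query set Q, a library set L, a table of
pairwise similarity scores S_ql (higher = more similar), and a taxonomy
level.  Taxonomy identifiers are 4-level dotted integers X.H.T.F; two
domains match at level H when X and H agree, at level X when X agrees,
and at level F when all four agree.  Only ordered Q×L pairs are ever
evaluated — never pairs within Q or within L — and the identical pair
(q = l, same domain identifier) is excluded from every count.  Q and L
may overlap (the all-vs-all case); each ordered pair is then counted
once and the diagonal never.

**Top-1 accuracy.** For each query q the assigned library domain is
l̂_q = argmax over l ∈ L, l ≠ q of S(q, l); the accuracy is the fraction
of queries whose l̂_q matches at the benchmark level.  Conventions:

* Equal top scores resolve to the lexicographically smallest library
  identifier, for determinism across runs and platforms.
* "Identical" means the identical domain identifier only.  Domains from
  the same PDB entry or the same UniProt protein are *not* excluded.
* A query with no scored non-identical partner is reported as
  unassigned and dropped from the denominator, with a warning.  Search
  tools emit only hits above internal cutoffs, so missing pairs are
  expected and treated as score −∞, never as errors.

**Restricted precision–recall.** At threshold S,
R(S) = N(S_ql > S ∧ match)/N(match) and
P(S) = N(S_ql > S ∧ match)/N(S_ql > S).  The comparison is strictly
`>`: a pair scoring exactly S is below the threshold.  The recall
denominator counts *all* matching Q×L pairs, scored or not, so a tool
that never scores a homologous pair is penalized in recall.  The curve
is evaluated at every distinct observed score plus a −∞ sentinel; there
is no interpolation.  At the zero-detection point (nothing above the
top threshold) precision is reported as 1 by the 0/0 convention, but
that point can never attain a precision-target criterion (recall > 0 is
required there), since a target met by an empty detection set is
vacuous.

**F_β and the threshold table.** F_β = (1+β²)PR/(β²P+R), zero when
either P or R is zero, maximized over curve points with ties broken
toward the higher threshold.  The threshold table reports, per curve:
the *lowest* threshold whose precision ≥ 0.99 (and ≥ 0.90) — i.e. the
most sensitive operating point still meeting the precision target — and
the argmax thresholds of F₀.₅, F₁, F₂.  Precision targets that the
curve never reaches are recorded as unattained rather than raised as
errors.

## Score normalization

The Z-score of a raw log-odds structural similarity uses linear
baselines in x = √(N_a·N_b): m(x) = A_m·x + B_m and
σ(x) = A_σ·max(x, 40) + B_σ.  The clamp is applied unconditionally; it
is the identity for x ≥ 40 and guarantees σ > 0 for short proteins
under the default constants (A_m = 16.170350, B_m = −47.164564,
A_σ = 23.503942, B_σ = −762.928232, fitted on all-vs-all non-homolog
comparisons of a 40% non-redundant domain set).  Raw pair scores are
expected from the comparison tool itself; the package does not compute
the underlying log-odds sum, which depends on the tool's internal
distance-probability tables.

`fit_regression` re-estimates the four constants from user-supplied
non-homolog scores with a two-stage scheme: pairs are grouped into
equal-count bins of x (default 20), and the per-bin mean and per-bin
standard deviation of the score are each regressed against the per-bin
mean x by ordinary least squares.  Binned estimation was chosen because
a scale (σ) regression needs a spread estimate at each abscissa;
residual-based alternatives exist, and the choice is deliberately
exposed through `n_bins`.  An optional pair mask lets callers exclude
known structurally-similar cross-group pairs from the fit.  Note the
identifiability caveat: both intercepts lie far below any realistic
length range, so with noisy scores they are recovered far less
precisely than the slopes or than the fitted baselines m(x), σ(x)
evaluated inside the data range; tests assert the latter.

Sequence and profile search scores enter as −log₁₀(E), a strictly
monotone transform preserving hit order; TM-score-based tools
contribute the average of the query- and target-normalized TM-scores.

## Bootstrap inference

Replicate query sets Q*¹ … Q*^B are drawn by sampling |Q| domains from
Q uniformly with replacement; the library is held fixed.  Resampling
the library would lower replicate top-1 accuracy almost surely, because
a resampled library loses diversity — each query's best hit can only
get worse when library domains drop out.  The package keeps a
deliberate diagnostic (`library_resampling_top1`) that reproduces this
bias; it is not part of the inference API.

The 95% CI (α = 0.05) is read off the sorted replicate values at
1-based ranks Bα/2 and B(1−α/2); with B = 1000 that is ranks 25
and 975.  When Bα/2 is not an integer the lower rank is rounded up and
the upper down, widening the interval conservatively.  Duplicated
queries contribute with multiplicity to both numerator and denominator
of every replicate metric.

One-sided p-values for "condition x beats condition y" are
1 − (1/B)ΣI(A^(x)_b > A^(y)_b) with a strict indicator, so ties count
against x and a condition compared with itself gives exactly p = 1.
When the two conditions share a query set the same replicate draws are
used for both (paired comparison, matching the shared replicate index
in the defining sum and reducing variance); with different query sets
the streams are independent — whether a paired or independent scheme is
"correct" for unequal query sets is underdetermined, and the choice is
exposed via `BootstrapPlan.paired`.

Replicates where a metric is undefined (e.g. a replicate with no
homologous pair) are recorded as missing; CIs are then taken over the
defined replicates and p-value averages adjust B accordingly, with a
warning when more than 1% of replicates are lost.

Reproducibility: replicate b's draws depend only on (seed, b), so
replicates are order-independent; the same seed and inputs give
bit-identical results.

## Dataset construction

Boundary semantics follow the construction rules' wording exactly:

* Regular set: n_residues ≥ 40 **and** n_sse ≥ 4 **and** not obsolete
  (both floors inclusive — a 40-residue, 4-element domain is kept).
* Model correspondence: identity ≥ 0.95, aligned/domain-length ratio
  ≥ 0.95, aligned residues ≥ 40, all inclusive.  The ratio is not
  capped at 1, since insertions can push the aligned count above the
  domain length.  The alignment statistics may come from any aligner; a
  global Needleman–Wunsch helper (Biopython `PairwiseAligner`, gap
  open −2, extend −0.5 by default) is provided.
* Date split: train = released strictly before 2021-02-15; the cutoff
  day itself goes to the test set, matching the template-cutoff
  phrasing "released before" the cutoff.  Undated domains are routed to
  a separate report.
* No-hit subsets: a query is excluded only by a hit with E strictly
  below 0.001 (a best hit at exactly 0.001 survives); queries absent
  from a hit list are kept; several hit lists combine conjunctively.
  Consequently the subset shrinks (never grows) as the threshold rises.
* pLDDT strata: half-open decade bins [50,60) … [80,90) with a closed
  top bin [90,100]; a mean of exactly 60.0 falls in 60–70.  Means below
  50 and domains without a model are reported separately.
* Methods: deposition strings normalize case-insensitively
  ("X-RAY DIFFRACTION" → XRAY, "SOLUTION NMR" → NMR,
  "ELECTRON MICROSCOPY" → EM), everything else → OTHER.
* Secondary-structure elements: 8-state DSSP codes collapse as
  H,G,I → H; E,B → E; rest → C; an element is a maximal run of ≥ 3
  consecutive identical H or E labels.  No universal counting rule
  exists, so `min_run` is a parameter and the default is the common
  three-residue convention.

pLDDT is read from the CA atom's B-factor only (AlphaFold-style models
repeat the residue value on every atom; CA is always present), giving
one value per residue.

## The synthetic benchmark

The generator emulates the statistical structure the analysis assumes,
not protein physics.  Per ordered pair, scores are drawn independently
from N(μ_rel, σ_rel) where rel ∈ {same family, same H-group (different
family), same X-group (different H), unrelated}; defaults
μ = 12/8/4/0, σ = 2, i.e. homologous and unrelated score distributions
separated by ~4σ, which puts H-level top-1 accuracy near 1 on a
few-hundred-domain cohort — the regime where the real evaluation
operates.  Scores are deliberately asymmetric in (q, l), as search
tools are.

Predicted-structure scores take the experimental draw and subtract
γ·(100 − pLDDT_q)·(1 + z), z ~ N(0,1), with γ = 0.05.  The mean shift
and the noise scale are tied to one coefficient on purpose: within a
pLDDT stratum a pure mean shift would be absorbed by the stratum's own
optimal threshold, so it is the heteroscedastic term that erodes
separability and produces the monotone decline of per-bin F1 from the
90–100 bin to the 50–60 bin.  With γ = 0 the "exp" and "pred" tables
are identical by construction (shared sub-seed).

Other planted structure: release dates Bernoulli(0.3) on the test side
of the 2021-02-15 cutoff, uniform within each side of 2019-01-01 …
2022-12-31; methods X-ray/NMR/EM at 0.7/0.1/0.2 (an X-ray-dominated
mix); mean pLDDT from a mixture over the five decade bins (default
weights 0.05/0.10/0.20/0.30/0.35, confidence-heavy like real model
archives), with NMR domains shifted down by 10 points (floor 30);
~16% of test domains planted without a sequence hit below E = 0.001
(half absent from the hit list, half with a distant hit);
5% of domains planted with exactly one regularity violation.  One
master seed spawns independent per-component streams (sizes, dates,
methods, pLDDT, scores, degradation, hits, flaws), so regenerating one
component does not perturb the others, and all planted memberships are
recorded in a truth object recomputable from the config alone.

The generative large-sample top-1 accuracy is also available in closed
simulation form: in a balanced taxonomy every query faces the same
library composition of relation classes, so the probability that the
best-scoring partner is a homolog is a fixed functional of the score
model, estimated by Monte Carlo (`top1_truth`).

**What passing synthetic tests shows — and does not.** The suite
establishes that the statistics, resampling and dataset pipelines
compute exactly what their definitions say on data with known truth.
It does not validate any claim about real proteins: real score
distributions are not Gaussian, not independent across pairs, and not
exchangeable within relation classes; real pLDDT degradation is not
linear; real taxonomies are heavily imbalanced.  Conclusions about
actual tools require their actual score tables.

## Problem sizes used in the shipped checks

The end-to-end suite exercises: the deterministic two-query worked
example; oracle equivalence against brute-force pair scans on 500
random instances (|Q| ≤ 8, |L| ≤ 12, tied and missing scores, all
three levels); CI coverage on 200 independently regenerated 60-domain
cohorts (10 families of 6, homolog/non-homolog means 2.5σ apart,
B = 1000) against the Monte-Carlo generative truth, with observed
coverage required within 95% ± 4 points; and the stratified-decline
property on a 560-domain cohort with ≥ 100 domains per pLDDT bin.
These sizes keep the full suite under a couple of minutes on one CPU
while leaving the binomial noise of each check well inside its
tolerance.

## Known limitations

* The raw log-odds similarity itself, and any tool-internal
  normalization (e.g. a third-order length regression of another
  aligner's Z-score), are out of scope: scores arrive already computed,
  and Z-normalization applies to tools whose raw scores are linear in
  √(N_aN_b).
* The ECOD-listing reader is a best-effort adapter for the public
  column convention; the canonical interchange format is the package's
  own TSV dialect.
* mmCIF models are not parsed (PDB format only), and DSSP files are
  consumed, not generated.
* Percentile CIs inherit the usual small-sample caveats of the
  percentile method for discrete metrics (top-1 accuracy on few queries
  takes values on a 1/|Q| grid); no BCa or studentized variants are
  provided.
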