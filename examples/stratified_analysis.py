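"""Stratified evaluation: does predicted-model confidence matter?

Generates a cohort with equal numbers of domains per pLDDT decade bin
and a confidence-dependent degradation of predicted-structure scores,
then computes per-bin F1 (each bin's queries against the full library)
and per-method pLDDT summaries.
"""

import numpy as np

from homeval.datasets import ss_composition, stratify_by_method, stratify_by_plddt
from homeval.evaluation import Benchmark, f_beta_max, pr_curve
from homeval.io import ExperimentalMethod, ScoreTable
from homeval.synthetic import SyntheticConfig, generate_benchmark

cfg = SyntheticConfig(
    n_x_groups=10, h_per_x=2, f_per_h=2, domains_per_f=8,
    plddt_bin_weights=(0.2, 0.2, 0.2, 0.2, 0.2),
    gamma=0.05, irregular_fraction=0.0, nmr_plddt_shift=10.0, seed=7,
)
synth = generate_benchmark(cfg)
strata = stratify_by_plddt(synth.domains)
frame = synth.scores_pred.frame

print("per-bin F1, predicted-structure queries vs full library (H level):")
for label in ("90-100", "80-90", "70-80", "60-70", "50-60"):
    doms = strata.bins[label]
    qids = {d.domain_id for d in doms}
    sub = ScoreTable(frame[frame["query_id"].isin(qids)].reset_index(drop=True))
    bench = Benchmark.from_collections(doms, synth.domains, sub, level="H")
    f1, _ = f_beta_max(pr_curve(bench), 1.0)
    print(f"  pLDDT {label:>6}: n = {len(doms):3d}  F1 = {f1:.3f}")
# F1 declines as confidence falls: low-pLDDT models carry noisier scores.

parts = stratify_by_method(synth.domains)
for method in (ExperimentalMethod.XRAY, ExperimentalMethod.NMR, ExperimentalMethod.EM):
    vals = [d.mean_plddt for d in parts[method]]
    print(f"{method.value}: {len(vals)} domains, mean pLDDT {np.mean(vals):.1f}")
# NMR-determined domains sit lower on the confidence scale, one reason
# their predicted models behave differently from their experimental ones.

print("secondary-structure composition of 'CCHHHHHHCCEEEEECC':",
      tuple(round(x, 3) for x in ss_composition("CCHHHHHHCCEEEEECC")))
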