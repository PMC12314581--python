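"""The two-query worked example: top-1 accuracy vs pair-based statistics.

A query set of two domains (families 1 and 2) is searched against a
six-domain library spanning three families.  q1's best hit shares its
family, q2's does not, so top-1 accuracy is 1/2; at the depicted score
threshold five pairs score above it, two of them same-family, giving
precision 2/5 and recall 2/4.
"""

from homeval.evaluation import f_beta, pr_curve, top1_accuracy
from homeval.synthetic import generate_figure2_fixture

example = generate_figure2_fixture()
bench = example.benchmark

result = top1_accuracy(bench)
print(f"top-1 accuracy: {result.accuracy}")
for a in result.assignments:
    print(f"  {a.query_id} -> {a.best_library_id}  same family: {a.matched}")

curve = pr_curve(bench)
p, r = curve.at_threshold(example.threshold)
print(f"evaluated query-library pairs: {curve.n_evaluated_pairs}")
print(f"at threshold S = {example.threshold}: precision = {p}, recall = {r}")
print(f"F1 at that threshold: {f_beta(p, r, 1.0):.2f}")
# Top-1 accuracy only sees each query's single best hit; the pair-based
# F score also credits the more remote same-family pairs further down
# the ranking, which is why the two statistics can disagree.
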