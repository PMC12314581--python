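"""Cohort construction: filters, the release-date split, and no-hit subsets.

Runs the full dataset pipeline on a generated cohort: drop irregular
domains (< 40 residues, < 4 secondary-structure elements, or obsolete),
split train/test at the 2021-02-15 template cutoff, and extract the
test queries with no sequence hit below E = 0.001 — the subset on which
structure comparison is the only route to a homolog.
"""

import tempfile
from pathlib import Path

from homeval.datasets import (
    SplitConfig,
    correspondence_filter,
    align_for_correspondence,
    filter_regular,
    no_hit_subset,
    split_by_release_date,
    write_id_list,
)
from homeval.io import parse_domain_table
from homeval.synthetic import SyntheticConfig, generate_benchmark, write_benchmark_files

synth = generate_benchmark(SyntheticConfig(seed=11))

report = filter_regular(synth.domains)
print(f"regular set: kept {len(report.kept)} / {len(synth.domains)} domains")
for domain_id, reasons in list(report.rejected.items())[:3]:
    print(f"  rejected {domain_id}: {'; '.join(reasons)}")

split = split_by_release_date(report.kept, SplitConfig())
print(f"train (released before 2021-02-15): {len(split.train)}")
print(f"test  (released on/after cutoff):   {len(split.test)}")

no_hit = no_hit_subset([d.domain_id for d in split.test], synth.hits, threshold=0.001)
print(f"no-hit test subset (no E < 0.001 sequence hit): {len(no_hit)}")

# the predicted-model correspondence check, on a toy alignment
seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSG"
aln = align_for_correspondence("d00001", seq, "model1", seq)
ok, reason = correspondence_filter(aln)
print(f"model correspondence for an exact-sequence model: {reason}")

with tempfile.TemporaryDirectory() as tmp:
    paths = write_benchmark_files(synth, tmp)
    write_id_list(no_hit, Path(tmp) / "no_hit_test.ids")
    reread = parse_domain_table(paths["domains"])
    print(f"round trip through {paths['domains'].name}: {len(reread)} records")
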