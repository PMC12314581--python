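"""Normalizing raw structural-similarity scores for protein length.

Raw inter-residue-distance log-odds scores grow with protein size, so a
score is only meaningful relative to what unrelated proteins of the same
lengths would get.  The Z-score subtracts the regressed non-homolog mean
m(x) and divides by the regressed spread sigma(x), where
x = sqrt(N_a * N_b); sigma is clamped at x = 40 so it stays positive for
short peptides.
"""

from homeval.scoring import (
    DEFAULT_REGRESSION,
    RawSimilarity,
    avg_tm_score,
    evalue_to_score,
    r_dis,
    regressed_mean,
    regressed_sigma,
    z_dis,
)

m = regressed_mean(100, 100)
s = regressed_sigma(100, 100)
print(f"non-homolog baseline for two 100-residue proteins: mean = {m:.6f}, sigma = {s:.6f}")
print(f"sigma for two 30-residue proteins (clamp active): {regressed_sigma(30, 30):.6f}")

for raw in (m, m + s, m + 4 * s):
    z = z_dis(RawSimilarity(raw, 100, 100))
    print(f"raw score {raw:10.1f}  ->  Z = {z:.2f}")
# Z = 0 means "looks like an unrelated pair"; Z of several sigma means
# the similarity is far beyond what chance and length alone produce.

print(f"self-normalized ratio R for S(a,b)=30, S(a,a)=40, S(b,b)=80: {r_dis(30, 40, 80)}")
print(f"sequence-search E-value 3.2e-5 as a score: {evalue_to_score(3.2e-5):.5f}")
print(f"average TM-score of (0.8, 0.6): {avg_tm_score(0.8, 0.6)}")
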