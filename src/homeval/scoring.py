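"""Similarity-score normalization and transforms.

Raw inter-residue-distance log-odds scores from rigid structural
comparison grow roughly linearly with the geometric mean of the two
protein lengths, so they are normalized to a Z-score

    Z(a, b) = (S(a, b) - m(x)) / sigma(x),   x = sqrt(N_a * N_b)

where the mean m(x) = A_m * x + B_m and standard deviation
sigma(x) = A_sigma * max(x, 40) + B_sigma are linear regressions fitted
on non-homologous pairs.  The clamp at x = 40 keeps sigma positive for
short proteins.  The default constants were fitted on an all-vs-all
comparison of a 40% non-redundant domain set.

Also provided: the self-score-normalized ratio R = 2 S(a,b)/(S(a,a)+S(b,b)),
the -log10 E-value transform for sequence/HMM search scores, the average
of query- and target-normalized TM-scores, and a two-stage least-squares
fit recovering (A_m, B_m, A_sigma, B_sigma) from non-homolog scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "RegressionParams",
    "RawSimilarity",
    "DEFAULT_REGRESSION",
    "regressed_mean",
    "regressed_sigma",
    "z_dis",
    "r_dis",
    "evalue_to_score",
    "avg_tm_score",
    "fit_regression",
]


@dataclass(frozen=True)
class RegressionParams:
    """Linear-regression constants for the length-dependent score baseline."""

    A_m: float = 16.170350
    B_m: float = -47.164564
    A_sigma: float = 23.503942
    B_sigma: float = -762.928232
    clamp_floor: float = 40.0

    def __post_init__(self) -> None:
        if self.A_sigma * self.clamp_floor + self.B_sigma <= 0:
            raise ValueError(
                "sigma at the clamp floor must be positive; "
                f"got {self.A_sigma * self.clamp_floor + self.B_sigma}"
            )


DEFAULT_REGRESSION = RegressionParams()


class RawSimilarity(NamedTuple):
    """An unnormalized log-odds score for a pair of proteins of given lengths."""

    s_dis: float
    n_a: int
    n_b: int


def _geom_mean(n_a: int, n_b: int) -> float:
    if n_a < 1 or n_b < 1:
        raise ValueError(f"protein lengths must be >= 1, got ({n_a}, {n_b})")
    return math.sqrt(n_a * n_b)


def regressed_mean(
    n_a: int, n_b: int, params: RegressionParams = DEFAULT_REGRESSION
) -> float:
    """Expected non-homolog score at lengths (n_a, n_b): A_m * sqrt(n_a n_b) + B_m."""
    return params.A_m * _geom_mean(n_a, n_b) + params.B_m


def regressed_sigma(
    n_a: int, n_b: int, params: RegressionParams = DEFAULT_REGRESSION
) -> float:
    """Non-homolog score standard deviation, clamped for short proteins.

    sigma = A_sigma * max(sqrt(n_a n_b), clamp_floor) + B_sigma.  The clamp
    is applied unconditionally; above the floor it is the identity, and it
    guarantees a positive sigma under the default constants.
    """
    x = max(_geom_mean(n_a, n_b), params.clamp_floor)
    sigma = params.A_sigma * x + params.B_sigma
    if sigma <= 0:
        raise ValueError(f"regressed sigma is non-positive ({sigma}) under {params}")
    return sigma


def z_dis(raw: RawSimilarity, params: RegressionParams = DEFAULT_REGRESSION) -> float:
    """Length-normalized Z-score of a raw log-odds similarity."""
    m = regressed_mean(raw.n_a, raw.n_b, params)
    s = regressed_sigma(raw.n_a, raw.n_b, params)
    return (raw.s_dis - m) / s


def r_dis(s_ab: float, s_aa: float, s_bb: float) -> float:
    """Self-score-normalized similarity ratio 2*S(a,b) / (S(a,a) + S(b,b))."""
    denom = s_aa + s_bb
    if denom == 0:
        raise ValueError("self-score sum is zero")
    return 2.0 * s_ab / denom


def evalue_to_score(e: float) -> float:
    """Transform an E-value to a higher-is-better score, -log10(E)."""
    if e <= 0:
        raise ValueError(f"E-value must be positive, got {e}")
    return -math.log10(e)


def avg_tm_score(q_tm: float, t_tm: float) -> float:
    """Average of the query-normalized and target-normalized TM-scores."""
    for v in (q_tm, t_tm):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"TM-score out of [0,1]: {v}")
    return 0.5 * (q_tm + t_tm)


def fit_regression(
    nonhomolog_scores: Sequence[tuple[float, int, int]],
    n_bins: int = 20,
    clamp_floor: float = 40.0,
    pair_mask: Callable[[int], bool] | None = None,
) -> RegressionParams:
    """Fit the length-baseline constants from non-homologous pair scores.

    The scores are binned into ``n_bins`` equal-count bins of the geometric
    mean x = sqrt(n_a * n_b); the per-bin mean and standard deviation of the
    score are regressed against the per-bin mean x by ordinary least squares.
    ``pair_mask``, when given, drops the pairs at the indices for which it
    returns True (e.g. cross-fold pairs known to be structurally similar).
    """
    data = [
        (s, na, nb)
        for i, (s, na, nb) in enumerate(nonhomolog_scores)
        if pair_mask is None or not pair_mask(i)
    ]
    if len(data) < 2:
        raise ValueError("need at least two non-homolog scores")
    s = np.array([d[0] for d in data], dtype=float)
    x = np.sqrt(np.array([d[1] for d in data], dtype=float)
                * np.array([d[2] for d in data], dtype=float))
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: all pairs share one geometric-mean length")

    n_bins = min(n_bins, np.unique(x).size)
    order = np.argsort(x, kind="stable")
    edges = np.array_split(order, n_bins)
    bin_x, bin_mean, bin_sd = [], [], []
    for idx in edges:
        if idx.size == 0:
            continue
        bin_x.append(float(x[idx].mean()))
        bin_mean.append(float(s[idx].mean()))
        bin_sd.append(float(s[idx].std(ddof=1)) if idx.size > 1 else 0.0)
    if len(bin_x) < 2:
        raise ValueError("fewer than two usable bins")

    mean_fit = stats.linregress(bin_x, bin_mean)
    sd_fit = stats.linregress(bin_x, bin_sd)
    return RegressionParams(
        A_m=float(mean_fit.slope),
        B_m=float(mean_fit.intercept),
        A_sigma=float(sd_fit.slope),
        B_sigma=float(sd_fit.intercept),
        clamp_floor=clamp_floor,
    )
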