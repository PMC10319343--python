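"""Cross-layer statistics: transcript–protein correlation and rank tests.

The transcript layer (qPCR log2 fold changes) and the protein layer
(differential-abundance log2 fold changes) are compared per gene ×
transition.  Pairs where either layer is absent are excluded pairwise and
the exclusion count reported.  Both a Pearson correlation and a
Mann–Whitney U comparison of the two layers are provided.
"""

from __future__ import annotations

import itertools
import math
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class CorrelationResult(NamedTuple):
    r: float
    p_value: float
    n_pairs: int
    n_excluded: int


class MannWhitneyResult(NamedTuple):
    u_stat: float
    p_value: float
    method: str


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Sample Pearson correlation with a two-sided t-based p-value.

    Pairs with a non-finite value in either vector are dropped and
    counted; at least three complete pairs are required, and either
    vector having zero variance is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y lengths differ")
    ok = np.isfinite(x) & np.isfinite(y)
    n_excluded = int((~ok).sum())
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), int(x.size), n_excluded)


def _exact_mann_whitney(a: np.ndarray, b: np.ndarray) -> MannWhitneyResult:
    """Exact two-sided Mann–Whitney by enumeration of group assignments.

    All C(n_a+n_b, n_a) assignments of the pooled midranks to group A are
    enumerated; ties are handled naturally through midranks.  The
    two-sided p doubles the smaller tail probability, capped at 1.
    """
    na = a.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    us = np.array(
        [ranks[list(combo)].sum() for combo in itertools.combinations(range(pooled.size), na)]
    ) - na * (na + 1) / 2
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    p = min(1.0, 2 * min(p_low, p_high))
    return MannWhitneyResult(float(u_obs), float(p), "exact")


def mann_whitney_u(
    group_a: Sequence[float], group_b: Sequence[float], exact_max_n: int = 8
) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    Uses exact enumeration when both groups have at most ``exact_max_n``
    observations, and the tie-corrected normal approximation (with
    continuity correction) otherwise.  The U statistic is reported for
    the first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size <= exact_max_n and b.size <= exact_max_n:
        return _exact_mann_whitney(a, b)
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(float(u), float(p), "normal_approx")


def correlate_layers(
    transcript: pd.DataFrame, protein: pd.DataFrame
) -> dict:
    """Compare transcript and protein log2 fold changes per gene × transition.

    Both inputs are long tables with columns (gene, transition, log2_fc).
    Returns the Pearson correlation over complete pairs together with a
    Mann–Whitney comparison of the two layers' fold-change distributions,
    plus the number of pairs excluded for a missing value.
    """
    merged = transcript.merge(
        protein, on=["gene", "transition"], suffixes=("_transcript", "_protein")
    )
    if merged.empty:
        raise ValueError("no gene x transition pairs shared between layers")
    x = merged["log2_fc_transcript"].to_numpy(float)
    y = merged["log2_fc_protein"].to_numpy(float)
    corr = pearson_correlation(x, y)
    ok = np.isfinite(x) & np.isfinite(y)
    mwu = mann_whitney_u(x[ok], y[ok])
    return {
        "pearson_r": corr.r,
        "pearson_p": corr.p_value,
        "n_pairs": corr.n_pairs,
        "n_excluded": corr.n_excluded,
        "mann_whitney_u": mwu.u_stat,
        "mann_whitney_p": mwu.p_value,
        "mann_whitney_method": mwu.method,
    }
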