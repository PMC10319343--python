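"""Germination indices and replicate-level group comparison.

A germination test records, per replicate dish, the number of newly
germinated seeds at each observation time.  The classical single-value
indices computed here are

* ``G`` — germinability, percent of sown seeds that germinated;
* ``MGT`` — mean germination time (days), the count-weighted mean of
  observation times;
* ``MGR`` — mean germination rate, ``1/MGT`` (day^-1);
* ``CVG`` — coefficient of velocity of germination, ``100/MGT`` (%);
* ``U`` — uncertainty (bits), the Shannon entropy of the distribution of
  germination events over observation intervals;
* ``Z`` — synchronization index in [0, 1], the probability that two
  randomly chosen germinated seeds germinated in the same interval;
* ``T50`` — time to reach half of the final germinated count, by linear
  interpolation between bracketing observations.

Indices are computed per replicate and then averaged; rate indices are
therefore *means of per-replicate rates*, not rates of the mean time
(the two differ by a Jensen gap whenever replicate MGTs differ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

INDEX_NAMES = ("G", "MGT", "MGR", "CVG", "U", "Z", "T50")


@dataclass(frozen=True)
class GerminationRecord:
    """One replicate of a germination time course."""

    replicate: str
    time_points: tuple[float, ...]
    new_germinations: tuple[int, ...]
    n_seeds: int

    def __post_init__(self) -> None:
        if self.n_seeds <= 0:
            raise ValueError("n_seeds must be positive")
        if len(self.time_points) != len(self.new_germinations):
            raise ValueError("time_points and new_germinations lengths differ")
        if any(t2 <= t1 for t1, t2 in zip(self.time_points, self.time_points[1:])):
            raise ValueError("time_points must be strictly increasing")
        if any(n < 0 for n in self.new_germinations):
            raise ValueError("germination counts must be non-negative")
        if sum(self.new_germinations) > self.n_seeds:
            raise ValueError("more germinations than seeds sown")

    @property
    def total_germinated(self) -> int:
        return sum(self.new_germinations)

    @property
    def cumulative(self) -> tuple[int, ...]:
        out, run = [], 0
        for n in self.new_germinations:
            run += n
            out.append(run)
        return tuple(out)


class T50Result(NamedTuple):
    time: float
    reached: bool  # False when the half count falls outside observations


def germinability(record: GerminationRecord) -> float:
    """Percent of sown seeds that germinated."""
    return 100.0 * record.total_germinated / record.n_seeds


def mean_germination_time(record: GerminationRecord) -> float:
    """Count-weighted mean of observation times (days); NaN if nothing germinated."""
    total = record.total_germinated
    if total == 0:
        return math.nan
    return sum(n * t for n, t in zip(record.new_germinations, record.time_points)) / total


def rate_indices(mgt_per_replicate: Sequence[float]) -> pd.DataFrame:
    """Per-replicate MGR (= 1/MGT) and CVG (= 100/MGT), with group means.

    Rates are computed per replicate before averaging, so the group mean
    rate is generally not the reciprocal of the group mean time.
    """
    mgts = np.asarray(mgt_per_replicate, dtype=float)
    mgr = np.where(np.isnan(mgts) | (mgts <= 0), np.nan, 1.0 / mgts)
    df = pd.DataFrame({"MGT": mgts, "MGR": mgr, "CVG": 100.0 * mgr})
    df.loc["group_mean"] = df.mean()
    return df


def uncertainty_index(record: GerminationRecord) -> float:
    """Shannon entropy (bits) of the germination-time distribution."""
    total = record.total_germinated
    if total == 0:
        return math.nan
    freqs = [n / total for n in record.new_germinations if n > 0]
    return -sum(f * math.log2(f) for f in freqs)


def synchrony_index(record: GerminationRecord) -> float:
    """Probability that two random germinated seeds share an interval (in [0, 1])."""
    total = record.total_germinated
    if total < 2:
        return math.nan
    pairs = sum(math.comb(n, 2) for n in record.new_germinations)
    return pairs / math.comb(total, 2)


def t50(record: GerminationRecord) -> T50Result:
    """Time to half of the final germinated count, linearly interpolated.

    The target is half of the *final* cumulative count.  If the first
    observation already meets it, that time is returned; interpolation
    otherwise runs between the bracketing observation times.
    """
    cum = record.cumulative
    final = cum[-1]
    if final == 0:
        raise ValueError("no germination: T50 undefined")
    half = final / 2.0
    for i, c in enumerate(cum):
        if c >= half:
            if i == 0:
                return T50Result(float(record.time_points[0]), True)
            t_prev, c_prev = record.time_points[i - 1], cum[i - 1]
            t_next, c_next = record.time_points[i], c
            frac = (half - c_prev) / (c_next - c_prev)
            return T50Result(t_prev + frac * (t_next - t_prev), True)
    return T50Result(float(record.time_points[-1]), False)


def percent_change(reference: float, value: float) -> float:
    """Signed percent change of ``value`` relative to ``reference``."""
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return 100.0 * (value - reference) / reference


def indices_table(records: Sequence[GerminationRecord]) -> pd.DataFrame:
    """All indices per replicate, plus group mean and SD rows."""
    rows = []
    for rec in records:
        mgt = mean_germination_time(rec)
        mgr = 1.0 / mgt if mgt and not math.isnan(mgt) else math.nan
        try:
            t50_val = t50(rec).time
        except ValueError:
            t50_val = math.nan
        rows.append(
            {
                "replicate": rec.replicate,
                "G": germinability(rec),
                "MGT": mgt,
                "MGR": mgr,
                "CVG": 100.0 * mgr,
                "U": uncertainty_index(rec),
                "Z": synchrony_index(rec),
                "T50": t50_val,
            }
        )
    df = pd.DataFrame(rows).set_index("replicate")
    df.loc["group_mean"] = df.mean()
    df.loc["group_sd"] = df.iloc[:-1].std(ddof=1)
    return df


def significance_stars(p: float) -> str:
    if math.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-tailed heteroscedastic (Welch) t-test; NaN for <2 values per group."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return math.nan, math.nan
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return (0.0, 1.0) if a.mean() == b.mean() else (math.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_groups(
    records_a: Sequence[GerminationRecord], records_b: Sequence[GerminationRecord]
) -> pd.DataFrame:
    """Welch t-test per index between two groups of replicates.

    Returns one row per index with group means, percent change of group B
    relative to group A, t, p, and significance stars.
    """
    if len(records_a) < 2 or len(records_b) < 2:
        raise ValueError("need at least 2 replicates per group")
    tab_a = indices_table(records_a)
    tab_b = indices_table(records_b)
    rows = []
    for name in INDEX_NAMES:
        va = tab_a[name].iloc[:-2].to_numpy(float)
        vb = tab_b[name].iloc[:-2].to_numpy(float)
        t, p = welch_t_test(va, vb)
        mean_a, mean_b = np.nanmean(va), np.nanmean(vb)
        rows.append(
            {
                "index": name,
                "mean_a": mean_a,
                "mean_b": mean_b,
                "pct_change": percent_change(mean_a, mean_b) if mean_a else math.nan,
                "t_stat": t,
                "p_value": p,
                "stars": significance_stars(p),
            }
        )
    return pd.DataFrame(rows).set_index("index")


def records_from_frame(df: pd.DataFrame) -> dict[str, list[GerminationRecord]]:
    """Group a long count table (see ``io.read_germination_counts``) by group label."""
    out: dict[str, list[GerminationRecord]] = {}
    for (group, rep), sub in df.groupby(["group", "replicate"], sort=False):
        sub = sub.sort_values("time_days")
        n_seeds = sub["n_seeds"].iloc[0]
        if (sub["n_seeds"] != n_seeds).any():
            raise ValueError(f"inconsistent n_seeds for replicate {rep!r}")
        out.setdefault(str(group), []).append(
            GerminationRecord(
                str(rep),
                tuple(sub["time_days"].astype(float)),
                tuple(sub["new_germinations"].astype(int)),
                int(n_seeds),
            )
        )
    return out
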