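"""Missing-value-aware label-free differential protein abundance.

The statistical chain for one pairwise comparison of conditions is

1. filter protein groups (peptide support, missing-value budget),
2. per-sample modified robust z-score normalization of log2 intensities,
3. equal-variance (pooled) two-sample t-test per protein,
4. log2 fold change of the second condition over the first, with a
   *pseudo* fold change when one condition is entirely unquantified,
5. Benjamini–Hochberg adjustment across proteins,
6. significance classing: accumulated / depleted / only-in-one-condition.

Fold changes follow the convention second condition over first condition,
so ``accumulated`` means more abundant in the second condition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import IntensityTable

logger = logging.getLogger(__name__)

#: consistency constant making the MAD estimate the SD of a normal sample
MAD_TO_SD = 1.4826
#: consistency constant for the interquartile-range fallback scale
IQR_TO_SD = 1.349

NOT_SIGNIFICANT = "not_significant"
ACCUMULATED = "accumulated"
DEPLETED = "depleted"
ONLY_IN_FIRST = "only_in_first"
ONLY_IN_SECOND = "only_in_second"
SIG_CLASSES = (NOT_SIGNIFICANT, ACCUMULATED, DEPLETED, ONLY_IN_FIRST, ONLY_IN_SECOND)


@dataclass(frozen=True)
class Comparison:
    """A pairwise transition; fold changes are second over first."""

    first: str
    second: str

    def __post_init__(self) -> None:
        if self.first == self.second:
            raise ValueError("comparison conditions must be distinct")

    @property
    def label(self) -> str:
        return f"{self.first}_vs_{self.second}"

    def reversed(self) -> "Comparison":
        return Comparison(self.second, self.first)


@dataclass
class ProteinStat:
    """Per-protein result of one pairwise comparison."""

    protein_id: str
    mean_log2_first: float | None
    mean_log2_second: float | None
    log2_fc: float
    is_pseudo_fc: bool
    t_stat: float | None = None
    df: int | None = None
    p_value: float | None = None
    adj_p: float | None = None
    sig_class: str = NOT_SIGNIFICANT


class TTestResult(NamedTuple):
    t_stat: float
    df: int
    p_value: float


def filter_proteins(
    table: IntensityTable,
    comparison: Comparison,
    min_peptides: int = 2,
    max_missing: int = 4,
) -> IntensityTable:
    """Keep proteins with peptide support and a bounded missing-value count.

    A protein is retained when its peptide count is at least
    ``min_peptides`` and the number of unquantified (zero) entries across
    the two conditions' samples is at most ``max_missing``.  The returned
    table is restricted to the comparison's samples.
    """
    samples = table.samples_of(comparison.first) + table.samples_of(comparison.second)
    sub = table.subset(samples=samples)
    n_missing = sub.missing_mask().sum(axis=1)
    keep = (sub.peptide_counts >= min_peptides) & (n_missing <= max_missing)
    if not keep.any():
        logger.warning("filter removed every protein for %s", comparison.label)
    return sub.subset(proteins=sub.intensities.index[keep])


def _robust_scale(x: np.ndarray, sample: str) -> float:
    """MAD-based scale with IQR fallback; 1.0 (center only) as last resort."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad > 0:
        return MAD_TO_SD * mad
    q75, q25 = np.percentile(x, [75, 25])
    if q75 > q25:
        return (q75 - q25) / IQR_TO_SD
    logger.warning("sample %s has zero spread; centering only", sample)
    return 1.0


def normalize_robust_z(table: IntensityTable) -> pd.DataFrame:
    """Modified robust z-score normalization of log2 intensities.

    Present values of each sample are log2-transformed and standardized to
    ``(x - median) / (1.4826 * MAD)``; the z-scores of all samples are then
    rescaled by the grand median and the grand (median per-sample) scale so
    values stay on a common, interpretable log2-intensity-like scale.
    Missing entries (zeros) become NaN and stay missing.
    """
    log2 = np.log2(table.intensities.where(table.intensities > 0))
    scales: list[float] = []
    z = pd.DataFrame(index=log2.index, columns=log2.columns, dtype=float)
    for sample in log2.columns:
        x = log2[sample].dropna().to_numpy()
        if x.size == 0:
            logger.warning("sample %s has no quantified proteins", sample)
            scales.append(1.0)
            continue
        scale = _robust_scale(x, sample)
        scales.append(scale)
        z[sample] = (log2[sample] - np.median(x)) / scale
    grand_median = float(np.median(log2.to_numpy()[~np.isnan(log2.to_numpy())]))
    grand_scale = float(np.median(scales))
    return z * grand_scale + grand_median


def pooled_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult | None:
    """Classical equal-variance two-sample t-test.

    Returns ``None`` when either group has fewer than two values (the
    result is *absent*, never an exception).  Identical constant groups
    give ``t = 0, p = 1``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        return None
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0:
        if diff == 0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(math.copysign(math.inf, diff), df, 0.0)
    t = diff / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), int(df), float(p))


def pseudo_floor(table: IntensityTable, condition: str, quantile: float = 0.10) -> float:
    """Detection-floor intensity for a condition.

    The mean of the smallest ``ceil(quantile * m)`` per-protein condition
    means (raw scale), over the ``m`` proteins quantified at least once in
    that condition.  This proxies the condition's limit of quantification
    and stands in for the group mean of a fully missing protein.
    """
    cols = table.samples_of(condition)
    sub = table.intensities[cols]
    means = sub.where(sub > 0).mean(axis=1).dropna()
    if means.empty:
        raise ValueError(f"no protein quantified in condition {condition!r}")
    k = max(1, math.ceil(quantile * means.size))
    return float(np.sort(means.to_numpy())[:k].mean())


def log2_fold_change(
    table: IntensityTable,
    protein_id: str,
    comparison: Comparison,
    pseudo_quantile: float = 0.10,
) -> tuple[float, bool]:
    """log2 fold change (second over first) with pseudo-FC imputation.

    The fold change is the difference of condition means of log2
    intensities over present values.  When one condition is entirely
    missing, its group average is replaced by the log2 of the condition's
    detection floor (see :func:`pseudo_floor`) and the result is flagged
    as a pseudo fold change.
    """
    row = table.intensities.loc[protein_id]
    means: dict[str, float | None] = {}
    for cond in (comparison.first, comparison.second):
        vals = row[table.samples_of(cond)]
        present = vals[vals > 0]
        means[cond] = float(np.log2(present).mean()) if len(present) else None
    m1, m2 = means[comparison.first], means[comparison.second]
    if m1 is None and m2 is None:
        raise ValueError(f"protein {protein_id!r} unquantified in both conditions")
    pseudo = m1 is None or m2 is None
    if m1 is None:
        m1 = math.log2(pseudo_floor(table, comparison.first, pseudo_quantile))
    if m2 is None:
        m2 = math.log2(pseudo_floor(table, comparison.second, pseudo_quantile))
    return m2 - m1, pseudo


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_significance(
    stat: ProteinStat, alpha: float = 0.05, lfc_threshold: float = 1.0
) -> str:
    """Apply the significance rules to a populated per-protein result.

    Pseudo fold changes class as detected-only-in-one-condition when the
    fold change clears the threshold toward the detected side; tested
    proteins class as accumulated / depleted when ``adj_p < alpha`` and
    ``|log2FC|`` meets the threshold.
    """
    if stat.is_pseudo_fc:
        if stat.mean_log2_first is None and stat.log2_fc >= lfc_threshold:
            return ONLY_IN_SECOND
        if stat.mean_log2_second is None and stat.log2_fc <= -lfc_threshold:
            return ONLY_IN_FIRST
        return NOT_SIGNIFICANT
    if stat.adj_p is None:
        return NOT_SIGNIFICANT
    if stat.adj_p < alpha and stat.log2_fc >= lfc_threshold:
        return ACCUMULATED
    if stat.adj_p < alpha and stat.log2_fc <= -lfc_threshold:
        return DEPLETED
    return NOT_SIGNIFICANT


@dataclass
class ComparisonResult:
    comparison: Comparison
    stats: list[ProteinStat]
    summary: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "protein_id": s.protein_id,
                    "comparison": self.comparison.label,
                    "mean_log2_first": s.mean_log2_first,
                    "mean_log2_second": s.mean_log2_second,
                    "log2_fc": s.log2_fc,
                    "is_pseudo_fc": s.is_pseudo_fc,
                    "t_stat": s.t_stat,
                    "df": s.df,
                    "p_value": s.p_value,
                    "adj_p": s.adj_p,
                    "sig_class": s.sig_class,
                }
                for s in self.stats
            ]
        )


def run_comparison(
    table: IntensityTable,
    comparison: Comparison,
    min_peptides: int = 2,
    max_missing: int = 4,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    pseudo_quantile: float = 0.10,
) -> ComparisonResult:
    """Full differential-abundance chain for one pairwise comparison.

    Proteins entirely missing in exactly one condition take the pseudo
    fold-change route and are exempt from the ``max_missing`` budget
    (which, with five replicates per condition, they could never satisfy);
    they still require the peptide filter and at least two quantified
    replicates on the detected side.  All other proteins are filtered,
    normalized, tested with the pooled t-test, BH-adjusted, and classed.
    """
    samples = table.samples_of(comparison.first) + table.samples_of(comparison.second)
    sub = table.subset(samples=samples)
    sub = sub.subset(proteins=sub.intensities.index[sub.peptide_counts >= min_peptides])

    first_cols = sub.samples_of(comparison.first)
    second_cols = sub.samples_of(comparison.second)
    present = ~sub.missing_mask()
    n_first = present[first_cols].sum(axis=1)
    n_second = present[second_cols].sum(axis=1)

    pseudo_ids = sub.intensities.index[
        ((n_first == 0) & (n_second >= 2)) | ((n_second == 0) & (n_first >= 2))
    ]
    both_ids = sub.intensities.index[(n_first > 0) & (n_second > 0)]
    n_skipped = len(sub.intensities.index) - len(pseudo_ids) - len(both_ids)
    if n_skipped:
        logger.warning(
            "%s: %d proteins with too little data in both conditions were skipped",
            comparison.label,
            n_skipped,
        )

    tested = filter_proteins(
        sub.subset(proteins=both_ids), comparison, min_peptides, max_missing
    )
    normalized = normalize_robust_z(tested) if len(tested.protein_ids) else pd.DataFrame()

    stats_out: list[ProteinStat] = []
    p_indices: list[int] = []
    for pid in tested.protein_ids:
        row = tested.intensities.loc[pid]
        m1 = float(np.log2(row[first_cols][row[first_cols] > 0]).mean())
        m2 = float(np.log2(row[second_cols][row[second_cols] > 0]).mean())
        lfc, _ = log2_fold_change(tested, pid, comparison, pseudo_quantile)
        zrow = normalized.loc[pid]
        res = pooled_t_test(
            zrow[first_cols].dropna().to_numpy(), zrow[second_cols].dropna().to_numpy()
        )
        stat = ProteinStat(pid, m1, m2, lfc, False)
        if res is not None:
            stat.t_stat, stat.df, stat.p_value = res
            p_indices.append(len(stats_out))
        stats_out.append(stat)

    if p_indices:
        adj = adjust_bh([stats_out[i].p_value for i in p_indices])
        for i, a in zip(p_indices, adj):
            stats_out[i].adj_p = float(a)

    for pid in pseudo_ids:
        lfc, _ = log2_fold_change(sub, pid, comparison, pseudo_quantile)
        row = sub.intensities.loc[pid]
        v1 = row[first_cols][row[first_cols] > 0]
        v2 = row[second_cols][row[second_cols] > 0]
        stats_out.append(
            ProteinStat(
                pid,
                float(np.log2(v1).mean()) if len(v1) else None,
                float(np.log2(v2).mean()) if len(v2) else None,
                lfc,
                True,
            )
        )

    for stat in stats_out:
        stat.sig_class = classify_significance(stat, alpha, lfc_threshold)

    summary = {
        "comparison": comparison.label,
        "total_quantified": len(stats_out),
        "tested": len(tested.protein_ids),
        "accumulated": sum(s.sig_class == ACCUMULATED for s in stats_out),
        "depleted": sum(s.sig_class == DEPLETED for s in stats_out),
        "only_in_first": sum(s.sig_class == ONLY_IN_FIRST for s in stats_out),
        "only_in_second": sum(s.sig_class == ONLY_IN_SECOND for s in stats_out),
        "skipped": n_skipped,
    }
    return ComparisonResult(comparison, stats_out, summary)
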