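"""qPCR efficiency estimation and efficiency-corrected relative expression.

Amplification efficiency ``E`` (fold increase per cycle, 2 = perfect
doubling) and the threshold cycle ``Ct`` are estimated per reaction from
background-subtracted fluorescence curves by fitting a line to the
log-linear exponential phase (window-of-linearity approach).  Relative
expression between two conditions follows the efficiency-corrected ratio
model with one or more reference genes:

    ratio = E_target^dCt_target / E_ref^dCt_ref,   dCt = Ct_first - Ct_second

where the first condition of a comparison is the calibrator, so induction
in the second condition gives a ratio > 1.  Multiple reference genes are
combined by geometric mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .diff_abundance import Comparison
from .germination import significance_stars, welch_t_test

logger = logging.getLogger(__name__)


@dataclass
class QpcrFit:
    """Per-reaction efficiency/Ct estimate from the exponential phase."""

    efficiency: float
    ct: float
    fit_window: tuple[int, int]  # first and last cycle of the fitted window
    r_squared: float
    quality_ok: bool


def estimate_efficiency_ct(
    cycles: Sequence[int],
    fluorescence: Sequence[float],
    threshold_fraction: float = 0.2,
    min_window: int = 4,
    plateau_fraction: float = 0.8,
    min_r_squared: float = 0.99,
) -> QpcrFit:
    """Exponential-phase fit of one background-subtracted amplification curve.

    Candidate cycles have positive fluorescence below ``plateau_fraction *
    max(F)``; the fitting window is the maximal contiguous run of such
    cycles containing the amplification ramp (the run reaching the
    highest signal), with at least ``min_window`` cycles.  A log-linear
    regression of ``log2 F`` on cycle seeds a least-squares fit of ``F =
    F0 * E^c`` in linear fluorescence space — where the detector noise is
    additive — so near-baseline cycles do not dominate the slope.  ``Ct``
    is the fractional cycle where the fitted exponential crosses
    ``threshold_fraction * max(F)``.  Fits with linear-space r^2 below
    ``min_r_squared`` or a non-amplifying slope are flagged
    ``quality_ok=False``.
    """
    c = np.asarray(cycles, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if c.size != f.size:
        raise ValueError("cycles and fluorescence lengths differ")
    if np.any(np.diff(c) <= 0):
        raise ValueError("cycles must be strictly increasing")
    fmax = f.max()
    if fmax <= 0 or np.allclose(f, f[0]):
        raise ValueError("flat curve: no amplification signal")

    eligible = (f > 0) & (f < plateau_fraction * fmax)
    runs: list[tuple[int, int]] = []
    i, n = 0, c.size
    while i < n:
        if not eligible[i]:
            i += 1
            continue
        j = i
        while j < n and eligible[j]:
            j += 1
        if j - i >= min_window:
            runs.append((i, j))
        i = j
    if not runs:
        raise ValueError("no exponential-phase window of sufficient length below the plateau")
    lo, hi = max(runs, key=lambda r: f[r[0]:r[1]].max())
    x, y = c[lo:hi], f[lo:hi]

    slope, intercept, r, _, _ = stats.linregress(x, np.log2(y))
    f0, eff = 2.0 ** intercept, 2.0 ** slope
    if slope > 0:
        try:
            (f0, eff), _ = optimize.curve_fit(
                lambda cc, a, e: a * e ** cc, x, y, p0=[f0, eff], maxfev=10000
            )
        except RuntimeError:
            logger.warning("exponential refinement failed; keeping log-linear fit")
    fitted = f0 * eff ** x
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    quality_ok = bool(r2 >= min_r_squared and eff > 1)
    if not quality_ok:
        logger.warning("low-quality amplification fit (r2=%.4f, E=%.4f)", r2, eff)
    threshold = threshold_fraction * fmax
    ct = (
        math.log(threshold / f0) / math.log(eff)
        if eff > 0 and eff != 1 and f0 > 0
        else math.nan
    )
    return QpcrFit(float(eff), float(ct), (int(c[lo]), int(c[hi - 1])), float(r2), quality_ok)


def pfaffl_ratio(e_target: float, dct_target: float, e_ref: float, dct_ref: float) -> float:
    """Efficiency-corrected expression ratio E_t^dCt_t / E_ref^dCt_ref."""
    if e_target <= 1 or e_ref <= 1:
        raise ValueError("amplification efficiencies must exceed 1")
    return (e_target ** dct_target) / (e_ref ** dct_ref)


def combine_references(ratios_per_reference: Sequence[float]) -> float:
    """Geometric mean of per-reference expression ratios."""
    ratios = np.asarray(ratios_per_reference, dtype=float)
    if ratios.size == 0:
        raise ValueError("need at least one reference ratio")
    if (ratios <= 0).any():
        raise ValueError("expression ratios must be positive")
    return float(np.exp(np.log(ratios).mean()))


def analyze_curves(
    curves: pd.DataFrame,
    condition_of: Mapping[str, str],
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit every reaction in a long curve table (reaction, gene, sample, cycle, fluorescence).

    Returns one row per reaction with gene, sample, condition, E, Ct, the
    fitted window, r^2 and the quality flag.
    """
    rows = []
    for (reaction, gene, sample), sub in curves.groupby(
        ["reaction", "gene", "sample"], sort=False
    ):
        sub = sub.sort_values("cycle")
        fit = estimate_efficiency_ct(
            sub["cycle"].to_numpy(), sub["fluorescence"].to_numpy(), **fit_kwargs
        )
        rows.append(
            {
                "reaction": reaction,
                "gene": gene,
                "sample": sample,
                "condition": condition_of[sample],
                "efficiency": fit.efficiency,
                "ct": fit.ct,
                "window_start": fit.fit_window[0],
                "window_end": fit.fit_window[1],
                "r_squared": fit.r_squared,
                "quality_ok": fit.quality_ok,
            }
        )
    return pd.DataFrame(rows)


def assay_efficiencies(fits: pd.DataFrame) -> pd.Series:
    """Per-assay (per-gene) mean efficiency across reactions."""
    return fits.groupby("gene")["efficiency"].mean()


def per_replicate_expression(
    fits: pd.DataFrame,
    target: str,
    references: Sequence[str],
    baseline_condition: str,
    per_reaction_efficiency: bool = False,
) -> pd.DataFrame:
    """Reference-normalized expression of a target per sample, relative to a baseline.

    For each sample, ``dCt = mean Ct(baseline) - Ct(sample)`` per gene and
    the Pfaffl ratio of the target against each reference is combined by
    geometric mean.  Efficiencies are per-assay means unless
    ``per_reaction_efficiency`` is set.
    """
    eff = assay_efficiencies(fits)
    genes = [target, *references]
    missing = [g for g in genes if g not in set(fits["gene"])]
    if missing:
        raise ValueError(f"no reactions for genes: {missing}")
    ct = fits.pivot_table(index="sample", columns="gene", values="ct")
    cond = fits.drop_duplicates("sample").set_index("sample")["condition"]
    base_samples = cond.index[cond == baseline_condition]
    if base_samples.empty:
        raise ValueError(f"no samples for baseline condition {baseline_condition!r}")
    base_ct = ct.loc[base_samples].mean()
    rows = []
    for sample in ct.index:
        if per_reaction_efficiency:
            e_of = fits[fits["sample"] == sample].set_index("gene")["efficiency"]
        else:
            e_of = eff
        ratios = [
            pfaffl_ratio(
                e_of[target], base_ct[target] - ct.loc[sample, target],
                e_of[ref], base_ct[ref] - ct.loc[sample, ref],
            )
            for ref in references
        ]
        rows.append(
            {
                "sample": sample,
                "condition": cond[sample],
                "gene": target,
                "expression": combine_references(ratios),
            }
        )
    return pd.DataFrame(rows)


def transition_log2fc(
    expression: pd.DataFrame,
    transitions: Sequence[Comparison],
) -> pd.DataFrame:
    """Per gene × transition log2 fold change with Welch t-test stars.

    ``expression`` is long-format (gene, condition, expression) with one
    row per replicate.  The fold change is ``log2(mean second / mean
    first)``; the t-test compares replicate expression values between the
    two conditions.  A transition missing either condition for a gene
    yields a row flagged absent (NaN fold change).
    """
    rows = []
    for gene, sub in expression.groupby("gene", sort=False):
        by_cond = {c: g["expression"].to_numpy(float) for c, g in sub.groupby("condition")}
        for tr in transitions:
            a = by_cond.get(tr.first, np.array([]))
            b = by_cond.get(tr.second, np.array([]))
            if a.size == 0 or b.size == 0 or a.mean() <= 0 or b.mean() <= 0:
                rows.append(
                    {"gene": gene, "transition": tr.label, "log2_fc": math.nan,
                     "t_stat": math.nan, "p_value": math.nan, "stars": "",
                     "n_first": a.size, "n_second": b.size}
                )
                continue
            lfc = math.log2(b.mean() / a.mean())
            t, p = welch_t_test(a, b)
            rows.append(
                {"gene": gene, "transition": tr.label, "log2_fc": lfc,
                 "t_stat": t, "p_value": p, "stars": significance_stars(p),
                 "n_first": a.size, "n_second": b.size}
            )
    return pd.DataFrame(rows)
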