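"""Preranked gene-set enrichment and over-representation analysis.

Proteins are ranked by their group-comparison t-statistic (descending).
The enrichment score (ES) is the classic weighted Kolmogorov–Smirnov
running-sum statistic; significance comes from member-set permutation
with sign-matched normalization (NES).  A hypergeometric upper-tail test
provides the over-representation (ORA) counterpart for a discrete
selection of proteins against a background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diff_abundance import adjust_bh
from .io import GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    adj_p: float | None
    n_members_in_ranking: int


def rank_by_score(scores: pd.Series) -> pd.Series:
    """Sort a score vector descending (stable for ties); validate ranking invariants."""
    if scores.index.has_duplicates:
        raise ValueError("ranking has duplicate item IDs")
    if not np.isfinite(scores.to_numpy()).all():
        raise ValueError("ranking scores must be finite")
    return scores.sort_values(ascending=False, kind="stable")


def enrichment_score(
    ranked: pd.Series,
    members: Iterable[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted running-sum enrichment score of a member set in a ranking.

    Walking down the ranking, hits increment the running sum by
    ``|score|^weight / sum_hits |score|^weight`` and misses decrement it
    by ``1 / (N - n_hits)``; the ES is the extremum of largest magnitude.
    Returns ``(es, running_sum)``.
    """
    ranked = rank_by_score(ranked)
    member_set = set(members)
    is_hit = ranked.index.isin(member_set)
    n = len(ranked)
    n_hits = int(is_hit.sum())
    if n_hits == 0:
        raise ValueError("no gene-set member present in the ranking")
    if n_hits == n:
        # no misses: the running sum climbs monotonically to 1
        return 1.0, np.cumsum(np.abs(ranked.to_numpy()) ** weight_exponent
                              / np.sum(np.abs(ranked.to_numpy()) ** weight_exponent))
    weights = np.abs(ranked.to_numpy()) ** weight_exponent
    hit_total = weights[is_hit].sum()
    steps = np.where(is_hit, 0.0, -1.0 / (n - n_hits))
    if hit_total > 0:
        steps = np.where(is_hit, weights / hit_total, steps)
    else:  # all member scores are zero: fall back to equal hit weights
        steps = np.where(is_hit, 1.0 / n_hits, steps)
    running = np.cumsum(steps)
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def permutation_nes(
    ranked: pd.Series,
    members: Iterable[str],
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
    set_name: str = "",
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Permutation significance and sign-matched normalization of an ES.

    The null distribution is the ES of ``n_perm`` random member sets of
    equal size drawn from the ranking.  NES divides the observed ES by the
    mean magnitude of same-sign null scores; the permutation p-value is
    ``(1 + #{same-sign null at least as extreme}) / (1 + #{same-sign null})``,
    so it is uniform under the null and never below ``1/(n_perm+1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ranked = rank_by_score(ranked)
    member_set = set(members) & set(ranked.index)
    n_in = len(member_set)
    es, _ = enrichment_score(ranked, member_set, weight_exponent)
    if rng is None:
        rng = np.random.default_rng(seed)
    ids = np.asarray(ranked.index)
    null = np.empty(n_perm)
    for i in range(n_perm):
        draw = rng.choice(ids, size=n_in, replace=False)
        null[i], _ = enrichment_score(ranked, draw, weight_exponent)
    same_sign = null > 0 if es > 0 else (null < 0 if es < 0 else np.zeros(n_perm, bool))
    n_same = int(same_sign.sum())
    if es == 0 or (np.abs(null) == 0).all():
        return EnrichmentResult(set_name, es, float("nan"), 1.0, None, n_in)
    p = (1 + int((same_sign & (np.abs(null) >= abs(es))).sum())) / (1 + n_same)
    mean_same = np.abs(null[same_sign]).mean() if n_same else float("nan")
    nes = es / mean_same if n_same else float("nan")
    return EnrichmentResult(set_name, es, float(nes), float(p), None, n_in)


def gsea_preranked(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
    min_size: int = 5,
    max_size: int = 500,
) -> pd.DataFrame:
    """Run preranked enrichment for every gene set, with BH adjustment.

    Sets with fewer than ``min_size`` or more than ``max_size`` members
    present in the ranking are skipped.
    """
    ranked = rank_by_score(ranked)
    universe = set(ranked.index)
    rng = np.random.default_rng(seed)
    results: list[EnrichmentResult] = []
    for gs in collection:
        n_in = len(set(gs.members) & universe)
        if not (min_size <= n_in <= max_size):
            logger.debug("skipping %s: %d members in ranking", gs.name, n_in)
            continue
        results.append(
            permutation_nes(
                ranked, gs.members, n_perm, weight_exponent=weight_exponent,
                set_name=gs.name, rng=rng,
            )
        )
    df = pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "es": r.es,
                "nes": r.nes,
                "p_value": r.p_value,
                "n_members_in_ranking": r.n_members_in_ranking,
            }
            for r in results
        ]
    )
    if not df.empty:
        df["adj_p"] = adjust_bh(df["p_value"].to_numpy())
    return df


def hypergeometric_enrichment(
    selected_items: Sequence[str],
    background_items: Sequence[str],
    gene_sets: GeneSetCollection,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of gene sets.

    For each set with ``K`` members in the background, the p-value is the
    probability of drawing at least the observed ``k`` members in a random
    selection of ``n = |selected|`` items from the ``N``-item background.
    Fold enrichment is ``(k/n) / (K/N)``.
    """
    selected = set(selected_items)
    background = set(background_items)
    if not selected <= background:
        raise ValueError("selected items must be a subset of the background")
    n, N = len(selected), len(background)
    rows = []
    for gs in gene_sets:
        members = set(gs.members) & background
        K = len(members)
        k = len(members & selected)
        if k == 0 or K == 0 or n == 0:
            fold, p = 0.0, 1.0
        else:
            fold = (k / n) / (K / N)
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"set_name": gs.name, "k_selected": k, "K_background": K,
             "fold_enrichment": fold, "p_value": p}
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["adj_p"] = adjust_bh(df["p_value"].to_numpy())
    return df
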