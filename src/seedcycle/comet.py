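"""Comet-assay (single-cell gel electrophoresis) damage scoring.

Nucleoids are visually assigned to damage classes 0 (intact) through 4
(fully damaged).  A slide of ``N_tot`` scored nucleoids with ``N_c``
nucleoids in class ``c`` is summarized in arbitrary units:

    a.u. = 100 * sum_c(N_c * c) / N_tot

which ranges from 0 (all intact) to 400 (all class 4).  The per-slide
score is the replicate unit for group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .germination import significance_stars, welch_t_test

N_CLASSES = 5


@dataclass(frozen=True)
class CometSlide:
    slide_id: str
    class_counts: tuple[int, ...]  # counts for classes 0..4

    def __post_init__(self) -> None:
        if len(self.class_counts) != N_CLASSES:
            raise ValueError(f"expected exactly {N_CLASSES} class counts (classes 0-4)")
        if any(c < 0 for c in self.class_counts):
            raise ValueError("class counts must be non-negative")
        if self.n_total == 0:
            raise ValueError("slide has no scored nucleoids")

    @property
    def n_total(self) -> int:
        return sum(self.class_counts)


def score_slide(slide: CometSlide) -> float:
    """Arbitrary-unit damage score, 100 * sum(N_c * c) / N_tot, in [0, 400]."""
    weighted = sum(n * c for c, n in enumerate(slide.class_counts))
    return 100.0 * weighted / slide.n_total


def expected_score(class_probs: Sequence[float]) -> float:
    """Expected a.u. of a multinomial slide: 100 * sum(p_c * c)."""
    probs = np.asarray(class_probs, float)
    if probs.shape != (N_CLASSES,):
        raise ValueError(f"expected {N_CLASSES} class probabilities")
    return 100.0 * float((probs * np.arange(N_CLASSES)).sum())


def compare_damage(
    slides_a: Sequence[CometSlide], slides_b: Sequence[CometSlide]
) -> dict:
    """Two-tailed Welch t-test on per-slide a.u. scores between two groups."""
    if len(slides_a) < 2 or len(slides_b) < 2:
        raise ValueError("need at least 2 slides per group")
    au_a = [score_slide(s) for s in slides_a]
    au_b = [score_slide(s) for s in slides_b]
    t, p = welch_t_test(au_a, au_b)
    return {
        "mean_au_a": float(np.mean(au_a)),
        "mean_au_b": float(np.mean(au_b)),
        "t_stat": t,
        "p_value": p,
        "stars": significance_stars(p),
    }


def slides_from_frame(df: pd.DataFrame) -> dict[str, list[CometSlide]]:
    """Group a comet count table (see ``io.read_comet_counts``) by group label."""
    out: dict[str, list[CometSlide]] = {}
    for _, row in df.iterrows():
        counts = tuple(int(row[f"c{i}"]) for i in range(N_CLASSES))
        out.setdefault(str(row["group"]), []).append(CometSlide(str(row["slide"]), counts))
    return out
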