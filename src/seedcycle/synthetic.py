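"""Synthetic data generators emulating the study's data structures.

Every input the pipeline consumes can be generated here with the
statistical structure the analysis assumes, so the whole suite is
testable without any external download:

* protein-group intensity tables with log-normal replicate noise, group
  effects, sporadic (missing-completely-at-random) dropout, and forced
  condition-wise absence (five replicates per condition by default);
* germination time courses as per-interval binomial draws from the
  remaining ungerminated seeds (three dishes of twenty seeds);
* exponential-phase qPCR amplification curves with a known efficiency
  saturating at a plateau;
* multinomial comet-assay class counts (one hundred nucleoids per slide).

Each generator takes an explicit seed and owns a private random stream:
the same seed always reproduces the same data, and no global state is
touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import IntensityTable


@dataclass
class ProteomeSimConfig:
    """Parameters of a simulated label-free proteomics experiment.

    Intensities are generated on the log2 scale as ``baseline + effect +
    Normal(0, replicate_sd)`` and exponentiated; a baseline of 20 puts raw
    intensities near 10^6, typical of LFQ output.  ``log2_effect_sizes``
    maps protein → condition → log2 shift versus baseline.  Sporadic
    missingness is applied uniformly at random; ``absent_pairs`` forces
    complete missingness of a protein in a condition.
    """

    n_proteins: int
    conditions: Sequence[str]
    n_replicates_per_condition: int = 5
    log2_effect_sizes: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    baseline_log2_mean: float = 20.0
    baseline_log2_spread: float = 2.0  # protein-to-protein spread of baselines
    replicate_sd: float = 0.5
    sporadic_missing_rate: float = 0.0
    absent_pairs: Sequence[tuple[str, str]] = field(default_factory=list)
    max_peptides: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if len(self.conditions) < 1:
            raise ValueError("need at least one condition")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if self.n_replicates_per_condition < 2:
            raise ValueError("n_replicates_per_condition must be >= 2")
        if not 0.0 <= self.sporadic_missing_rate <= 1.0:
            raise ValueError("sporadic_missing_rate must lie in [0, 1]")
        if self.replicate_sd <= 0:
            raise ValueError("replicate_sd must be positive")
        for protein, condition in self.absent_pairs:
            if condition not in self.conditions:
                raise ValueError(f"absent pair references unknown condition {condition!r}")

    def protein_id(self, i: int) -> str:
        return f"P{i:05d}"


def simulate_intensity_table(cfg: ProteomeSimConfig) -> IntensityTable:
    """Draw a protein × sample intensity table under the configured model."""
    rng = np.random.default_rng(cfg.seed)
    proteins = [cfg.protein_id(i) for i in range(cfg.n_proteins)]
    samples, condition_of = [], {}
    for cond in cfg.conditions:
        for r in range(1, cfg.n_replicates_per_condition + 1):
            name = f"{cond}_{r}"
            samples.append(name)
            condition_of[name] = cond

    baselines = cfg.baseline_log2_mean + cfg.baseline_log2_spread * rng.standard_normal(
        cfg.n_proteins
    )
    log2 = np.empty((cfg.n_proteins, len(samples)))
    for j, s in enumerate(samples):
        cond = condition_of[s]
        effects = np.array(
            [cfg.log2_effect_sizes.get(p, {}).get(cond, 0.0) for p in proteins]
        )
        log2[:, j] = baselines + effects + cfg.replicate_sd * rng.standard_normal(
            cfg.n_proteins
        )
    intensities = 2.0 ** log2

    if cfg.sporadic_missing_rate > 0:
        drop = rng.random(intensities.shape) < cfg.sporadic_missing_rate
        intensities[drop] = 0.0
    mat = pd.DataFrame(intensities, index=pd.Index(proteins, name="protein_id"), columns=samples)
    for protein, condition in cfg.absent_pairs:
        cols = [s for s in samples if condition_of[s] == condition]
        mat.loc[protein, cols] = 0.0

    peptides = pd.Series(
        rng.integers(1, cfg.max_peptides + 1, size=cfg.n_proteins), index=mat.index
    )
    return IntensityTable(mat, peptides, condition_of)


@dataclass
class GerminationSimConfig:
    """Parameters of a simulated germination test.

    ``daily_germination_probs`` are per-interval hazards: at each
    observation time the still-ungerminated seeds germinate independently
    with that interval's probability.
    """

    n_replicates: int = 3
    n_seeds: int = 20
    daily_germination_probs: Sequence[float] = (0.5, 0.5, 0.3, 0.1)
    time_points: Sequence[float] = (1.0, 2.0, 3.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.n_seeds < 1:
            raise ValueError("n_replicates and n_seeds must be >= 1")
        if len(self.daily_germination_probs) != len(self.time_points):
            raise ValueError("one hazard per time point is required")
        if any(not 0.0 <= h <= 1.0 for h in self.daily_germination_probs):
            raise ValueError("hazards must lie in [0, 1]")
        if any(t2 <= t1 for t1, t2 in zip(self.time_points, self.time_points[1:])):
            raise ValueError("time_points must be strictly increasing")


def simulate_germination_counts(
    cfg: GerminationSimConfig, group: str = "group"
) -> pd.DataFrame:
    """Simulate per-interval germination counts for each replicate dish.

    Returns the long count-table schema (group, replicate, time_days,
    new_germinations, n_seeds) consumed by the germination module.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for r in range(1, cfg.n_replicates + 1):
        remaining = cfg.n_seeds
        for t, hazard in zip(cfg.time_points, cfg.daily_germination_probs):
            new = int(rng.binomial(remaining, hazard)) if remaining > 0 else 0
            remaining -= new
            rows.append(
                {
                    "group": group,
                    "replicate": f"{group}_r{r}",
                    "time_days": t,
                    "new_germinations": new,
                    "n_seeds": cfg.n_seeds,
                }
            )
    return pd.DataFrame(rows)


def simulate_qpcr_curve(
    e_true: float,
    f0: float,
    n_cycles: int = 45,
    noise_sd: float = 0.0,
    plateau: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential amplification curve saturating at a plateau.

    Fluorescence at cycle ``c`` is ``min(f0 * e_true**c, plateau)`` plus
    Gaussian noise, floored at 0.  ``e_true`` must lie in (1, 2]: a value
    of 2 is perfect per-cycle doubling.
    """
    if not 1.0 < e_true <= 2.0:
        raise ValueError("e_true must lie in (1, 2]")
    if f0 <= 0 or plateau <= 0:
        raise ValueError("f0 and plateau must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    cycles = np.arange(1, n_cycles + 1)
    clean = np.minimum(f0 * e_true ** cycles, plateau)
    noisy = clean + (noise_sd * rng.standard_normal(n_cycles) if noise_sd > 0 else 0.0)
    return pd.DataFrame({"cycle": cycles, "fluorescence": np.maximum(noisy, 0.0)})


def simulate_comet_counts(
    class_probs: Sequence[float], n_nucleoids: int = 100, seed: int = 0
) -> np.ndarray:
    """Multinomial draw of nucleoid damage-class counts (classes 0-4)."""
    probs = np.asarray(class_probs, dtype=float)
    if probs.shape != (5,):
        raise ValueError("class_probs must have exactly 5 entries (classes 0-4)")
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class probabilities must be non-negative and sum to 1")
    if n_nucleoids < 1:
        raise ValueError("n_nucleoids must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.multinomial(n_nucleoids, probs)
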