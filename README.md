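# seedcycle

A desk-side analysis suite for seed priming studies that combine
label-free quantitative proteomics with physiological and molecular
assays.  It covers the full post-acquisition computation of a
rehydration–dehydration (hydropriming + dry-back) experiment on
*Medicago truncatula* seeds: differential protein abundance from
MaxQuant-style intensity tables, preranked gene-set enrichment,
germination indices, comet-assay damage scoring, efficiency-corrected
qPCR relative expression, and transcript–protein integration — plus
synthetic-data generators that emulate each assay so every stage is
testable without any instrument data.

## Who it is for

Seed biologists and proteomics analysts who have a `proteinGroups.txt`
export (or any protein × sample intensity table with zeros for missing
values), germination count sheets, comet-assay class counts, or raw
qPCR fluorescence curves, and want the standard statistics for priming
experiments in one reproducible, scriptable package.

## The statistics at its core

**Differential abundance.**  For each pairwise comparison of conditions
(fold changes are always *second over first*):

1. filter protein groups to ≥ 2 peptides and ≤ 4 missing values across
   the comparison's samples;
2. per-sample modified robust z-score normalization of log2
   intensities, `z = (x − median) / (1.4826·MAD)`, rescaled to the
   grand median and scale so values stay on a log2-intensity-like scale;
3. equal-variance (pooled) two-sample t-test per protein,
   `df = n₁ + n₂ − 2`;
4. `log2FC = mean log2(second) − mean log2(first)`; when one condition
   is entirely unquantified, its group mean is replaced by the mean of
   the 10 % smallest per-protein condition means (a *pseudo* fold
   change, marking proteins detected only in one condition);
5. Benjamini–Hochberg adjustment;
6. classes: *accumulated* (adj. p < 0.05, log2FC ≥ 1), *depleted*
   (adj. p < 0.05, log2FC ≤ −1), *only-in-first* / *only-in-second*
   (pseudo FC beyond the threshold).

**Enrichment.**  Proteins are ranked by their comparison t-statistic;
the enrichment score is the weighted Kolmogorov–Smirnov running-sum
statistic, normalized (NES) and tested by member-set permutation with a
sign-matched null.  A hypergeometric upper-tail test provides the
over-representation counterpart.

**Germination.**  G (%), MGT = Σnᵢtᵢ/Σnᵢ (days), MGR = 1/MGT, CVG =
100/MGT, uncertainty U = −Σfᵢ·log2 fᵢ (bits), synchrony Z =
ΣC(nᵢ,2)/C(Σnᵢ,2), and T50 by linear interpolation — per replicate,
then averaged; groups compared with Welch's t-test.

**Comet assay.**  `a.u. = 100·Σ(N_c·c)/N_tot` over damage classes
0–4, range 0–400, compared per slide.

**qPCR.**  Per-reaction efficiency E and fractional Ct from an
exponential fit `F = F0·Eᶜ` to the window of linearity below the
plateau; relative expression by the efficiency-corrected ratio
`E_t^ΔCt_t / E_ref^ΔCt_ref` (ΔCt = control − sample), with multiple
reference genes combined by geometric mean.

## Worked example

```python
import seedcycle as sc

# a synthetic 2-condition LFQ experiment: 5 replicates each, one 8-fold
# induced protein, one protein absent from condition B
cfg = sc.ProteomeSimConfig(
    n_proteins=100, conditions=["A", "B"], replicate_sd=0.5,
    log2_effect_sizes={"P00001": {"B": 3.0}},
    absent_pairs=[("P00002", "B")], sporadic_missing_rate=0.05, seed=1,
)
table = sc.simulate_intensity_table(cfg)
res = sc.run_comparison(table, sc.Comparison("A", "B"))
print(res.summary)
for s in res.stats:
    if s.protein_id in ("P00001", "P00002"):
        print(s.protein_id, round(s.log2_fc, 2), s.is_pseudo_fc, s.sig_class)
```

prints

```
{'comparison': 'A_vs_B', 'total_quantified': 98, 'tested': 97,
 'accumulated': 1, 'depleted': 0, 'only_in_first': 1, 'only_in_second': 0,
 'skipped': 0}
P00001 2.71 False accumulated
P00002 -3.56 True only_in_first
```

The spiked protein is recovered as *accumulated* (measured log2FC 2.71
against a programmed 3.0 with replicate noise), and the protein forced
absent from condition B is flagged as a pseudo fold change and counted
as detected only in the first condition.

The germination arithmetic on the study-scale group means:

```python
>>> from seedcycle import percent_change
>>> round(percent_change(47.00, 73.00), 2)   # day-1 germination, primed vs not
55.32
>>> round(percent_change(1.64, 1.17), 2)     # mean germination time
-28.66
```

## Command line

```bash
seedcycle simulate --what proteome --seed 1 --out sim/
seedcycle diffabund --table sim/protein_groups.tsv --design sim/design.csv \
    --first A --second B --out results/
seedcycle gsea --ranks ranks.csv --gmt sets.gmt --nperm 999 --out gsea.csv
seedcycle germination --counts counts.csv --compare UP P --out germ/
seedcycle comet --counts comet.csv --compare UP_dI P_dI --out comet/
seedcycle qpcr --curves curves.csv --design design.csv --targets ITPA \
    --references ELF1a,ACT --transitions UP2:PRH2 --out qpcr/
seedcycle run --seed 7 --out pipeline_out/   # full synthetic pipeline
```

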