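"""End-to-end orchestration of the analysis suite on declarative configs.

``run_pipeline`` executes, from one config mapping and one seed:
simulation of every input (optional — file inputs can be supplied
instead), differential abundance per declared pairwise comparison,
preranked enrichment on the t-statistic ranking, germination indices and
group comparison, comet-assay scoring, qPCR relative expression, and the
transcript–protein fold-change correlation.  Each stage writes a CSV to
the output directory; a summary JSON mirrors the per-comparison count
table, and a run log records the config and derived seeds.  Outputs are
a pure function of (config, seed): rerunning reproduces them byte for
byte.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import comet as comet_mod
from . import diff_abundance as da
from . import enrichment as enr
from . import germination as germ
from . import integrate, io, qpcr, synthetic

logger = logging.getLogger(__name__)

#: the ten pairwise transitions of the rehydration–dehydration design
DEFAULT_COMPARISONS = [
    ("DS", "P"), ("P", "PDB2"), ("PDB2", "PDB4"), ("PDB4", "PRH2"),
    ("PRH2", "PRH8"), ("DS", "UP2"), ("UP2", "UP8"), ("DS", "PDB4"),
    ("UP2", "PRH2"), ("UP8", "PRH8"),
]


def default_config(seed: int = 7) -> dict:
    """Bundled synthetic configuration exercising every stage.

    Problem sizes are kept desk-scale (hundreds of proteins, three
    replicate dishes/slides, a four-gene qPCR panel) so a full run takes
    seconds while preserving the structure of the real design: eight
    conditions, ten pairwise transitions, five LFQ replicates per
    condition.
    """
    return {
        "seed": seed,
        "conditions": ["DS", "P", "PDB2", "PDB4", "PRH2", "PRH8", "UP2", "UP8"],
        "comparisons": [list(c) for c in DEFAULT_COMPARISONS],
        "proteome": {
            "n_proteins": 240,
            "n_replicates_per_condition": 5,
            "replicate_sd": 0.5,
            "baseline_log2_mean": 20.0,
            "sporadic_missing_rate": 0.04,
            "n_spiked": 24,
            "effect_size": 2.0,
            "n_absent": 6,
        },
        "gene_sets": {"n_sets": 8, "set_size": 20},
        "diff": {"min_peptides": 2, "max_missing": 4, "alpha": 0.05, "lfc_threshold": 1.0},
        "gsea": {"n_perm": 199, "min_size": 5, "max_size": 500, "weight_exponent": 1.0},
        "germination": {
            "n_replicates": 3,
            "n_seeds": 20,
            "time_points": [1.0, 2.0, 3.0, 4.0],
            "groups": {
                "UP": [0.45, 0.50, 0.40, 0.20],
                "P": [0.72, 0.65, 0.50, 0.30],
            },
        },
        "comet": {
            "n_slides": 3,
            "n_nucleoids": 100,
            "groups": {
                "UP_dI": [0.20, 0.30, 0.25, 0.15, 0.10],
                "P_dI": [0.45, 0.30, 0.15, 0.07, 0.03],
            },
        },
        "qpcr": {
            "n_replicates": 3,
            "n_cycles": 40,
            "noise_sd": 0.01,
            "plateau": 10.0,
            "f0_baseline": 1e-4,
            "references": ["ELF1a", "ACT"],
            "transitions": [["UP2", "PRH2"], ["DS", "PDB4"], ["UP8", "PRH8"]],
        },
    }


def validate_config(config: Mapping) -> None:
    """Raise a named error for structurally invalid configs."""
    for key in ("seed", "conditions", "comparisons", "proteome"):
        if key not in config:
            raise ValueError(f"config is missing required key {key!r}")
    conditions = set(config["conditions"])
    for pair in config["comparisons"]:
        if len(pair) != 2:
            raise ValueError(f"comparison {pair!r} must have exactly two conditions")
        for cond in pair:
            if cond not in conditions:
                raise ValueError(f"comparison references undeclared condition {cond!r}")
    qp = config.get("qpcr", {})
    for pair in qp.get("transitions", []):
        for cond in pair:
            if cond not in conditions:
                raise ValueError(f"qPCR transition references undeclared condition {cond!r}")


def _build_proteome(config: Mapping, rng: np.random.Generator, seed: int):
    """Assemble the simulation config: spiked effects, absences, gene sets."""
    p = config["proteome"]
    conditions = list(config["conditions"])
    n = p["n_proteins"]
    ids = [f"P{i:05d}" for i in range(n)]

    n_spiked = p.get("n_spiked", 0)
    effect = p.get("effect_size", 2.0)
    spiked = list(rng.choice(ids, size=n_spiked, replace=False)) if n_spiked else []
    effects: dict[str, dict[str, float]] = {}
    spike_conditions = [c for c in conditions if c != conditions[0]]
    for i, pid in enumerate(spiked):
        cond = spike_conditions[i % len(spike_conditions)]
        sign = 1.0 if i % 2 == 0 else -1.0
        effects[pid] = {cond: sign * effect}

    n_absent = p.get("n_absent", 0)
    unspiked = [i for i in ids if i not in effects]
    absent_pairs = []
    if n_absent:
        chosen = rng.choice(unspiked, size=n_absent, replace=False)
        for i, pid in enumerate(chosen):
            absent_pairs.append((str(pid), conditions[i % len(conditions)]))

    sim_cfg = synthetic.ProteomeSimConfig(
        n_proteins=n,
        conditions=conditions,
        n_replicates_per_condition=p.get("n_replicates_per_condition", 5),
        log2_effect_sizes=effects,
        baseline_log2_mean=p.get("baseline_log2_mean", 20.0),
        replicate_sd=p.get("replicate_sd", 0.5),
        sporadic_missing_rate=p.get("sporadic_missing_rate", 0.0),
        absent_pairs=absent_pairs,
        seed=seed,
    )

    gs_cfg = config.get("gene_sets", {})
    collection = io.GeneSetCollection()
    n_sets, set_size = gs_cfg.get("n_sets", 8), gs_cfg.get("set_size", 20)
    if spiked:
        # one set concentrated in perturbed proteins, the analogue of a
        # functionally coherent category responding to the treatment
        pad = list(rng.choice(unspiked, size=max(0, set_size - len(spiked)), replace=False))
        collection.add("GS_responsive", "perturbed proteins", [str(x) for x in spiked + pad])
    for k in range(n_sets):
        members = rng.choice(ids, size=set_size, replace=False)
        collection.add(f"GS{k:02d}", f"random set {k}", [str(m) for m in members])
    return sim_cfg, collection, effects


def _float_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format="%.10g")


def run_pipeline(config: Mapping, out_dir) -> Path:
    """Run every stage of the suite; returns the output directory.

    Any stage failure aborts with the stage name and the underlying
    cause.  All randomness derives from ``config['seed']``.
    """
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    rng = np.random.default_rng(seed)
    sub_seeds = {
        "proteome": seed * 100 + 1,
        "germination": seed * 100 + 2,
        "comet": seed * 100 + 3,
        "qpcr": seed * 100 + 4,
    }
    stage = "setup"
    try:
        # --- proteomics -----------------------------------------------
        stage = "simulate_proteome"
        sim_cfg, collection, effects = _build_proteome(config, rng, sub_seeds["proteome"])
        table = synthetic.simulate_intensity_table(sim_cfg)
        io.write_protein_groups(table, out / "protein_groups.tsv")
        io.write_design(table.condition_of, out / "design.csv")
        io.write_gmt(collection, out / "gene_sets.gmt")

        stage = "diff_abundance"
        dp = config.get("diff", {})
        all_stats, summaries = [], []
        rankings: dict[str, pd.Series] = {}
        for first, second in config["comparisons"]:
            cmp_ = da.Comparison(first, second)
            res = da.run_comparison(
                table, cmp_,
                min_peptides=dp.get("min_peptides", 2),
                max_missing=dp.get("max_missing", 4),
                alpha=dp.get("alpha", 0.05),
                lfc_threshold=dp.get("lfc_threshold", 1.0),
            )
            all_stats.append(res.to_frame())
            summaries.append(res.summary)
            scores = {
                s.protein_id: s.t_stat for s in res.stats if s.t_stat is not None
                and np.isfinite(s.t_stat)
            }
            rankings[cmp_.label] = pd.Series(scores)
        _float_csv(pd.concat(all_stats, ignore_index=True), out / "differential_abundance.csv")
        with open(out / "summary.json", "w") as fh:
            json.dump({"comparisons": summaries}, fh, indent=2, sort_keys=True)

        stage = "gsea"
        gp = config.get("gsea", {})
        gsea_frames = []
        for label, ranked in rankings.items():
            df = enr.gsea_preranked(
                ranked, collection,
                n_perm=gp.get("n_perm", 199),
                seed=seed * 100 + 10,
                weight_exponent=gp.get("weight_exponent", 1.0),
                min_size=gp.get("min_size", 5),
                max_size=gp.get("max_size", 500),
            )
            df.insert(0, "comparison", label)
            gsea_frames.append(df)
        _float_csv(pd.concat(gsea_frames, ignore_index=True), out / "gsea_nes.csv")

        # --- germination ----------------------------------------------
        stage = "germination"
        gc = config.get("germination", {})
        frames = []
        for i, (group, hazards) in enumerate(sorted(gc.get("groups", {}).items())):
            cfg = synthetic.GerminationSimConfig(
                n_replicates=gc.get("n_replicates", 3),
                n_seeds=gc.get("n_seeds", 20),
                daily_germination_probs=hazards,
                time_points=gc.get("time_points", [1.0, 2.0, 3.0, 4.0]),
                seed=sub_seeds["germination"] + i,
            )
            frames.append(synthetic.simulate_germination_counts(cfg, group=group))
        germ_counts = pd.concat(frames, ignore_index=True)
        _float_csv(germ_counts, out / "germination_counts.csv")
        by_group = germ.records_from_frame(germ_counts)
        idx_frames = []
        for group, records in by_group.items():
            tab = germ.indices_table(records).reset_index()
            tab.insert(0, "group", group)
            idx_frames.append(tab)
        _float_csv(pd.concat(idx_frames, ignore_index=True), out / "germination_indices.csv")
        groups = sorted(by_group)
        if len(groups) >= 2:
            cmp_df = germ.compare_groups(by_group[groups[1]], by_group[groups[0]])
            _float_csv(cmp_df.reset_index(), out / "germination_comparison.csv")

        # --- comet ----------------------------------------------------
        stage = "comet"
        cc = config.get("comet", {})
        slide_rows = []
        for i, (group, probs) in enumerate(sorted(cc.get("groups", {}).items())):
            for s in range(cc.get("n_slides", 3)):
                counts = synthetic.simulate_comet_counts(
                    probs, cc.get("n_nucleoids", 100), seed=sub_seeds["comet"] + 10 * i + s
                )
                slide_rows.append(
                    {"slide": f"{group}_s{s + 1}", "group": group,
                     **{f"c{k}": int(v) for k, v in enumerate(counts)}}
                )
        comet_counts = pd.DataFrame(slide_rows)
        _float_csv(comet_counts, out / "comet_counts.csv")
        slides = comet_mod.slides_from_frame(comet_counts)
        scores = [
            {"slide": s.slide_id, "group": g, "au": comet_mod.score_slide(s)}
            for g, ss in slides.items() for s in ss
        ]
        _float_csv(pd.DataFrame(scores), out / "comet_scores.csv")
        cgroups = sorted(slides)
        if len(cgroups) >= 2:
            cmp_res = comet_mod.compare_damage(slides[cgroups[0]], slides[cgroups[1]])
            with open(out / "comet_comparison.json", "w") as fh:
                json.dump(cmp_res, fh, indent=2, sort_keys=True)

        # --- qPCR -----------------------------------------------------
        stage = "qpcr"
        qp = config.get("qpcr", {})
        transitions = [da.Comparison(a, b) for a, b in qp.get("transitions", [])]
        panel = _qpcr_panel(effects, transitions, rng)
        curves, cond_of = _simulate_qpcr_panel(panel, effects, qp, sub_seeds["qpcr"])
        _float_csv(curves, out / "qpcr_curves.csv")
        fits = qpcr.analyze_curves(curves, cond_of)
        _float_csv(fits, out / "qpcr_fits.csv")
        references = qp.get("references", ["ELF1a", "ACT"])
        transcript_frames = []
        for tr in transitions:
            expr_frames = [
                qpcr.per_replicate_expression(
                    fits[fits["condition"].isin([tr.first, tr.second])],
                    target, references, baseline_condition=tr.first,
                )
                for target in panel
            ]
            ldf = qpcr.transition_log2fc(pd.concat(expr_frames, ignore_index=True), [tr])
            transcript_frames.append(ldf)
        transcript = pd.concat(transcript_frames, ignore_index=True)
        _float_csv(transcript, out / "qpcr_log2fc.csv")

        # --- integration ---------------------------------------------
        stage = "integrate"
        prot_stats = pd.concat(all_stats, ignore_index=True)
        prot_rows = []
        for gene, pid in panel.items():
            for tr in transitions:
                hit = prot_stats[
                    (prot_stats["protein_id"] == pid)
                    & (prot_stats["comparison"] == tr.label)
                ]
                prot_rows.append(
                    {
                        "gene": gene,
                        "transition": tr.label,
                        "log2_fc": float(hit["log2_fc"].iloc[0]) if len(hit) else np.nan,
                    }
                )
        protein_lfc = pd.DataFrame(prot_rows)
        corr = integrate.correlate_layers(
            transcript[["gene", "transition", "log2_fc"]], protein_lfc
        )
        with open(out / "correlation.json", "w") as fh:
            json.dump(corr, fh, indent=2, sort_keys=True)

        stage = "run_log"
        with open(out / "run_log.json", "w") as fh:
            json.dump(
                {"config": _jsonable(config), "derived_seeds": sub_seeds},
                fh, indent=2, sort_keys=True,
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _qpcr_panel(
    effects: Mapping[str, Mapping[str, float]],
    transitions: Sequence[da.Comparison],
    rng: np.random.Generator,
    n_genes: int = 4,
) -> dict[str, str]:
    """Map panel gene names to spiked protein IDs so layers can be paired."""
    spiked = sorted(effects)
    if len(spiked) < n_genes:
        raise ValueError("not enough perturbed proteins for the qPCR panel")
    chosen = [spiked[i] for i in sorted(rng.choice(len(spiked), size=n_genes, replace=False))]
    return {f"G{k + 1}_{pid}": pid for k, pid in enumerate(chosen)}


def _simulate_qpcr_panel(panel, effects, qp, seed):
    """Curves for panel + reference genes over every condition in the transitions.

    A gene's transcript abundance per condition follows the same log2
    effect its mapped protein carries, so the programmed transcript and
    protein fold changes agree up to noise.
    """
    transitions = qp.get("transitions", [])
    conds = sorted({c for pair in transitions for c in pair})
    references = qp.get("references", ["ELF1a", "ACT"])
    n_rep = qp.get("n_replicates", 3)
    f0_base = qp.get("f0_baseline", 1e-4)
    rng = np.random.default_rng(seed)
    rows = []
    cond_of = {}
    gene_eff = {g: 1.85 + 0.15 * rng.random() for g in [*panel, *references]}
    for gene, pid in [(g, p) for g, p in panel.items()] + [(r, None) for r in references]:
        for cond in conds:
            shift = 0.0
            if pid is not None:
                shift = effects.get(pid, {}).get(cond, 0.0)
            for rep in range(1, n_rep + 1):
                sample = f"{cond}_{rep}"
                cond_of[sample] = cond
                f0 = f0_base * (2.0 ** shift) * (2.0 ** (0.05 * rng.standard_normal()))
                curve = synthetic.simulate_qpcr_curve(
                    gene_eff[gene], f0,
                    n_cycles=qp.get("n_cycles", 40),
                    noise_sd=qp.get("noise_sd", 0.01),
                    plateau=qp.get("plateau", 10.0),
                    seed=int(rng.integers(2**31 - 1)),
                )
                curve.insert(0, "sample", sample)
                curve.insert(0, "gene", gene)
                curve.insert(0, "reaction", f"{gene}_{sample}")
                rows.append(curve)
    return pd.concat(rows, ignore_index=True), cond_of


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items() if not str(k).startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
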