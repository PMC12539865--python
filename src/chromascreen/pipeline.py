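"""End-to-end screening pipeline: config validation, stage orchestration,
artifact writing and a run manifest.

Stages run in order normalize -> compartments -> transitions -> tads ->
loops -> degs -> windows -> venn -> coexpression -> rank; every
intermediate is written through io_formats so any stage can be re-run from
saved artifacts. Given the same config and seed the run is deterministic
down to the bytes of the candidate report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io_formats as iof
from . import hic_core, compartments, tads, loops as loops_mod, coexpression, screening
from .io_formats import BinTable, ValidationError

log = logging.getLogger("chromascreen")


class ConfigError(ValueError):
    """Raised with every config violation listed, not just the first."""


_DEFAULTS = dict(
    study_dir=None,
    outdir=None,
    seed=0,
    window_bp=3_000_000,
    transition_types=["A2B", "B2A"],
    lowess_frac=0.3,
    insulation_window=5,
    min_boundary_strength=0.1,
    loop_min_sep_bins=2,
    loop_max_sep_bins=100,
    loop_p_thresh=0.01,
    loop_q_thresh=0.01,
    loop_min_enrichment=2.0,
    lfc_cut=1.0,
    alpha=0.05,
    target_r2=0.8,
    max_power=20,
    min_module_size=15,
    merge_r=0.75,
    mm_cut=0.8,
    candidate_flank_bp=100_000,
    require_known=True,
    coexpression_genes="all",  # 'all' or 'deg'
)


@dataclass
class PipelineConfig:
    """Pipeline parameters; defaults equal the study's stated settings
    (3-Mb transition window, loop P/Q thresholds 0.01, scale-free R^2
    target 0.8, minimum module size 15, eigengene merge r 0.75, hub
    |kME| cut 0.8)."""

    study_dir: str
    outdir: str
    seed: int = 0
    window_bp: int = 3_000_000
    transition_types: list = field(default_factory=lambda: ["A2B", "B2A"])
    lowess_frac: float = 0.3
    insulation_window: int = 5
    min_boundary_strength: float = 0.1
    loop_min_sep_bins: int = 2
    loop_max_sep_bins: int = 100
    loop_p_thresh: float = 0.01
    loop_q_thresh: float = 0.01
    loop_min_enrichment: float = 2.0
    lfc_cut: float = 1.0
    alpha: float = 0.05
    target_r2: float = 0.8
    max_power: int = 20
    min_module_size: int = 15
    merge_r: float = 0.75
    mm_cut: float = 0.8
    candidate_flank_bp: int = 100_000
    require_known: bool = True
    coexpression_genes: str = "all"


def _check(cfg: dict) -> list[str]:
    errors = []
    for key in cfg:
        if key not in _DEFAULTS:
            errors.append(f"unknown config key {key!r}")
    for key, typ in [
        ("seed", int), ("window_bp", int), ("insulation_window", int),
        ("loop_min_sep_bins", int), ("loop_max_sep_bins", int),
        ("max_power", int), ("min_module_size", int), ("candidate_flank_bp", int),
    ]:
        if key in cfg and not isinstance(cfg[key], int):
            errors.append(f"config key {key!r} must be an integer")
    for key in ("window_bp", "insulation_window", "loop_min_sep_bins",
                "max_power", "min_module_size", "candidate_flank_bp"):
        if key in cfg and isinstance(cfg[key], int) and cfg[key] < 1:
            errors.append(f"config key {key!r} must be >= 1, got {cfg[key]}")
    for key in ("loop_p_thresh", "loop_q_thresh", "alpha", "target_r2",
                "merge_r", "mm_cut", "lowess_frac"):
        if key in cfg:
            v = cfg[key]
            if not isinstance(v, (int, float)) or not (0 < float(v) <= 1):
                errors.append(f"config key {key!r} must be in (0, 1], got {v!r}")
    if "coexpression_genes" in cfg and cfg["coexpression_genes"] not in ("all", "deg"):
        errors.append("config key 'coexpression_genes' must be 'all' or 'deg'")
    if "transition_types" in cfg:
        bad = set(cfg["transition_types"]) - {"A2A", "A2B", "B2A", "B2B"}
        if bad:
            errors.append(f"config key 'transition_types': unknown types {sorted(bad)}")
    return errors


def validate_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML config; all violations reported together."""
    cfg: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        cfg.update(loaded)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    errors = _check(cfg)
    merged = dict(_DEFAULTS)
    merged.update(cfg)
    if merged["study_dir"] is None:
        errors.append("config key 'study_dir' is required")
    if merged["outdir"] is None:
        errors.append("config key 'outdir' is required")
    if errors:
        raise ConfigError("; ".join(errors))
    return PipelineConfig(**merged)


# ---------------------------------------------------------------------------
# Study loading
# ---------------------------------------------------------------------------

@dataclass
class Study:
    root: Path
    resolution: int
    chroms: dict[str, int]
    conditions: list[str]
    contacts: dict[str, dict[str, "iof.ContactMatrix"]]  # condition -> chrom -> combined matrix
    genes: list
    expr: "coexpression.ExpressionMatrix"
    known: set[str]

    def bin_table(self, chrom: str) -> BinTable:
        return BinTable(chrom, self.resolution, self.chroms[chrom])


def load_study(study_dir) -> Study:
    root = Path(study_dir)
    with open(root / "study.json") as fh:
        manifest = json.load(fh)
    resolution = int(manifest["resolution"])
    chroms = {k: int(v) for k, v in manifest["chroms"].items()}
    conditions = list(manifest["conditions"])
    if len(conditions) != 2:
        raise ValidationError("study must have exactly two conditions (treat, control)")
    contacts: dict[str, dict[str, iof.ContactMatrix]] = {}
    for cond in conditions:
        contacts[cond] = {}
        for chrom in sorted(chroms):
            bt = BinTable(chrom, resolution, chroms[chrom])
            reps = [
                iof.read_contact_matrix(root / rel, "coo", bt)
                for rel in manifest["contacts"][cond][chrom]
            ]
            combined = reps[0].counts.copy()
            for r in reps[1:]:
                combined += r.counts
            contacts[cond][chrom] = iof.ContactMatrix(bt, combined)
    genes = iof.read_genes(root / manifest["genes"], format="bed")
    expr = iof.read_expression(root / manifest["expression"], root / manifest["samples"])
    known = iof.read_gene_list(root / manifest["known_genes"])
    return Study(root, resolution, chroms, conditions, contacts, genes, expr, known)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def run_screening_pipeline(config: PipelineConfig):
    """Run the full differential 3D-genome + multi-omics screen.

    Returns the CandidateReport; every stage writes its artifacts under
    ``config.outdir`` and the manifest records per-stage counts.
    """
    out = Path(config.outdir)
    for sub in ("normalized", "compartments", "tads", "loops", "degs", "venn",
                "coexpression"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    study = load_study(config.study_dir)
    treat, control = study.conditions
    stage_counts: dict[str, int] = {}

    # --- normalize ---------------------------------------------------------
    normalized = {}
    oe = {}
    for cond in study.conditions:
        normalized[cond] = {}
        oe[cond] = {}
        for chrom in sorted(study.chroms):
            cm = study.contacts[cond][chrom]
            nm = hic_core.lowess_zscore_normalize(cm, frac=config.lowess_frac)
            normalized[cond][chrom] = nm
            oe[cond][chrom] = hic_core.oe_transform(cm)
            iof.write_dense_matrix(nm.values, out / "normalized" / f"{cond}_{chrom}_z.tsv")
    for chrom in sorted(study.chroms):
        diff = hic_core.differential_matrix(normalized[treat][chrom], normalized[control][chrom])
        iof.write_dense_matrix(diff.values, out / "normalized" / f"diff_{chrom}_z.tsv")
    stage_counts["normalize_matrices"] = 2 * len(study.chroms)
    log.info("normalize: %d matrices", stage_counts["normalize_matrices"])

    # --- compartments ------------------------------------------------------
    comp_tracks = {}
    for cond in study.conditions:
        comp_tracks[cond] = {}
        for chrom in sorted(study.chroms):
            bt = study.bin_table(chrom)
            track = compartments.call_compartments(oe[cond][chrom], study.genes, bt)
            comp_tracks[cond][chrom] = track
            iof.write_track(track.pc1, bt, out / "compartments" / f"{cond}_{chrom}_pc1.bedgraph")
    for cond in study.conditions:
        fractions = compartments.compartment_fraction_per_chrom(comp_tracks[cond])
        iof.write_table(fractions, out / "compartments" / f"{cond}_fractions.tsv")
    stage_counts["compartment_tracks"] = 2 * len(study.chroms)
    log.info("compartments: %d tracks", stage_counts["compartment_tracks"])

    # --- transitions -------------------------------------------------------
    transitions = {}
    summaries = []
    for chrom in sorted(study.chroms):
        tt, summary = compartments.classify_transitions(
            comp_tracks[treat][chrom], comp_tracks[control][chrom]
        )
        transitions[chrom] = tt
        summary.insert(0, "chrom", chrom)
        summaries.append(summary)
        with open(out / "compartments" / f"transitions_{chrom}.bed", "w") as fh:
            for seg in tt.segments:
                fh.write(f"{chrom}\t{seg.start_bp}\t{seg.end_bp}\t{seg.label}\n")
    transition_summary = pd.concat(summaries, ignore_index=True)
    iof.write_table(transition_summary, out / "compartments" / "transition_counts.tsv")
    stage_counts["transition_segments"] = sum(len(t.segments) for t in transitions.values())
    log.info("transitions: %d segments", stage_counts["transition_segments"])

    # --- tads --------------------------------------------------------------
    insulation = {}
    boundary_calls = {}
    for cond in study.conditions:
        insulation[cond] = {}
        boundary_calls[cond] = {}
        for chrom in sorted(study.chroms):
            bt = study.bin_table(chrom)
            track = tads.insulation_score(
                study.contacts[cond][chrom], window_bins=config.insulation_window
            )
            track.boundaries = tads.call_boundaries(
                track, min_strength=config.min_boundary_strength
            )
            insulation[cond][chrom] = track
            boundary_calls[cond][chrom] = track.boundaries
            iof.write_track(track.score, bt, out / "tads" / f"{cond}_{chrom}_insulation.bedgraph")
            with open(out / "tads" / f"{cond}_{chrom}_boundaries.bed", "w") as fh:
                for b, strength in track.boundaries:
                    fh.write(
                        f"{chrom}\t{bt.bin_start(b)}\t{bt.bin_end(b)}\tboundary\t{strength:.4g}\n"
                    )
    boundary_rows = []
    for chrom in sorted(study.chroms):
        shared, ua, ub = tads.compare_boundaries(
            boundary_calls[treat][chrom], boundary_calls[control][chrom]
        )
        boundary_rows.append(
            {"chrom": chrom, "shared": len(shared),
             f"unique_{treat}": len(ua), f"unique_{control}": len(ub)}
        )
    iof.write_table(pd.DataFrame(boundary_rows), out / "tads" / "boundary_comparison.tsv")
    stage_counts["tad_boundaries"] = sum(
        len(b) for cond in boundary_calls.values() for b in cond.values()
    )
    log.info("tads: %d boundaries", stage_counts["tad_boundaries"])

    # --- loops -------------------------------------------------------------
    loop_calls = {}
    for cond in study.conditions:
        per_chrom = []
        for chrom in sorted(study.chroms):
            calls = loops_mod.call_loops(
                study.contacts[cond][chrom],
                min_sep_bins=config.loop_min_sep_bins,
                max_sep_bins=config.loop_max_sep_bins,
                p_thresh=config.loop_p_thresh,
                q_thresh=config.loop_q_thresh,
                min_enrichment=config.loop_min_enrichment,
            )
            per_chrom.extend(
                loops_mod.merge_loops_across_resolutions([(study.resolution, calls)])
            )
        loop_calls[cond] = per_chrom
        loops_mod.write_loops_bedpe(per_chrom, out / "loops" / f"{cond}_loops.bedpe")
        iof.write_table(
            pd.DataFrame(
                [
                    {"chrom": c.chrom, "midpoint1": c.midpoint1, "midpoint2": c.midpoint2,
                     "observed": c.observed, "expected": c.expected,
                     "enrichment": c.enrichment, "p": c.p_value, "q": c.q_value}
                    for c in per_chrom
                ]
            ),
            out / "loops" / f"{cond}_loops.tsv",
        )
    stage_counts["loops"] = sum(len(v) for v in loop_calls.values())
    log.info("loops: %d calls", stage_counts["loops"])

    # --- degs --------------------------------------------------------------
    meta = study.expr.metadata
    if meta is None:
        raise ValidationError("expression matrix has no sample metadata")
    stages = sorted(meta["stage"].unique())
    deg_tables = []
    for stage in stages:
        sa = list(meta.index[(meta["group"] == treat) & (meta["stage"] == stage)])
        sb = list(meta.index[(meta["group"] == control) & (meta["stage"] == stage)])
        table = screening.call_degs(
            study.expr, sa, sb, lfc_cut=config.lfc_cut, alpha=config.alpha,
            comparison=f"{treat}_vs_{control}_{stage}",
        )
        deg_tables.append(table)
        iof.write_table(table, out / "degs" / f"degs_{stage}.tsv")
    up, down = screening.deg_sets(deg_tables)
    stage_counts["degs_up"] = len(up)
    stage_counts["degs_down"] = len(down)
    log.info("degs: %d up, %d down", len(up), len(down))

    # --- windows -----------------------------------------------------------
    windowed: dict[str, tuple[str, int]] = {}
    for chrom in sorted(study.chroms):
        hits = screening.window_genes_around_transitions(
            transitions[chrom], study.genes,
            window_bp=config.window_bp, types=config.transition_types,
        )
        for gid, (label, dist) in hits.items():
            if gid not in windowed or dist < windowed[gid][1]:
                windowed[gid] = (label, dist)
    iof.write_table(
        pd.DataFrame(
            [{"gene_id": g, "segment": l, "distance_bp": d}
             for g, (l, d) in sorted(windowed.items())]
        ),
        out / "venn" / "windowed_genes.tsv",
    )
    stage_counts["windowed_genes"] = len(windowed)
    log.info("windows: %d genes", len(windowed))

    # --- venn --------------------------------------------------------------
    venn = screening.four_way_venn(study.known, up, down, set(windowed))
    iof.write_table(venn.region_sizes(), out / "venn" / "region_sizes.tsv")
    with open(out / "venn" / "region_members.json", "w") as fh:
        json.dump(
            {"&".join(n for n, s in zip(screening.SET_NAMES, sig) if s): sorted(m)
             for sig, m in venn.regions.items()},
            fh, indent=1, sort_keys=True,
        )

    # --- coexpression ------------------------------------------------------
    if config.coexpression_genes == "deg":
        expr_net = study.expr.subset_genes(sorted(up | down))
    else:
        expr_net = study.expr
    fit = coexpression.pick_soft_threshold(
        expr_net, powers=range(1, config.max_power + 1), target_r2=config.target_r2
    )
    adj = coexpression.adjacency(expr_net, fit.chosen)
    tom = coexpression.tom_similarity(adj)
    modules = coexpression.detect_modules(
        tom, expr_net.gene_ids, min_size=config.min_module_size
    )
    modules = coexpression.merge_modules(expr_net, modules, merge_r=config.merge_r)
    hubs = (
        coexpression.hub_genes(modules, mm_cut=config.mm_cut)
        if modules.module_ids
        else {}
    )
    trait_cols = [c for c in meta.columns if c not in ("sample", "group", "stage")]
    trait_cor = None
    if modules.module_ids and trait_cols:
        traits = meta.loc[list(expr_net.sample_ids), trait_cols].astype(float)
        trait_cor = coexpression.module_trait_correlation(modules.eigengenes, traits)
        iof.write_table(trait_cor, out / "coexpression" / "module_trait.tsv")
    iof.write_table(
        pd.DataFrame({"gene_id": modules.gene_ids, "module": modules.labels}),
        out / "coexpression" / "labels.tsv",
    )
    if modules.eigengenes is not None:
        modules.eigengenes.rename_axis("module").to_csv(
            out / "coexpression" / "eigengenes.tsv", sep="\t", float_format="%.6g"
        )
        modules.kme.rename_axis("gene_id").to_csv(
            out / "coexpression" / "kme.tsv", sep="\t", float_format="%.6g"
        )
    stage_counts["modules"] = len(modules.module_ids)
    stage_counts["hub_genes"] = sum(len(v) for v in hubs.values())
    log.info("coexpression: power %d, %d modules, %d hubs",
             fit.chosen, stage_counts["modules"], stage_counts["hub_genes"])

    # --- rank --------------------------------------------------------------
    module_label_map = {g: int(l) for g, l in zip(modules.gene_ids, modules.labels)}
    report = screening.rank_candidates(
        venn,
        hubs,
        insulation_tracks={
            chrom: (insulation[treat][chrom], insulation[control][chrom])
            for chrom in sorted(study.chroms)
        },
        loop_calls=(loop_calls[treat], loop_calls[control]),
        genes=study.genes,
        kme=modules.kme,
        module_labels=module_label_map,
        flank_bp=config.candidate_flank_bp,
        require_known=config.require_known,
    )
    iof.write_table(report.table, out / "candidates.tsv")
    with open(out / "candidates.txt", "w") as fh:
        for gid in report.candidates:
            fh.write(f"{gid}\n")
    stage_counts["candidates"] = len(report.candidates)
    log.info("rank: %d candidates", stage_counts["candidates"])

    manifest = {
        "config": asdict(config),
        "version": __version__,
        "soft_power": fit.chosen,
        "stage_counts": stage_counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return report
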