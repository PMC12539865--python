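"""Candidate-gene screening: differential expression, transition-window
gene retrieval, four-way Venn partition and evidence-ranked reporting.

The screen intersects four gene categories — a curated known-gene list,
up-regulated DEGs, down-regulated DEGs, and genes within a window around
A/B compartment transitions — then annotates surviving candidates with
coexpression hub status and locus-level 3D-feature differences (insulation
and loop counts) between the two conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .coexpression import ExpressionMatrix
from .io_formats import Gene, ValidationError
from .compartments import TransitionTrack
from .loops import count_loops_in_region
from .tads import InsulationTrack, insulation_at


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def _bh_adjust(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(np.clip(p, 0, 1))


def _resolve_samples(expr: ExpressionMatrix, group) -> list[int]:
    if isinstance(group, str):
        if expr.metadata is None:
            raise ValidationError("group label given but expression has no metadata")
        samples = list(expr.metadata.index[expr.metadata["group"] == group])
    else:
        samples = list(group)
    idx = {s: i for i, s in enumerate(expr.sample_ids)}
    missing = [s for s in samples if s not in idx]
    if missing:
        raise ValidationError(f"unknown samples: {missing}")
    return [idx[s] for s in samples]


def call_degs(
    expr: ExpressionMatrix,
    group_a,
    group_b,
    lfc_cut: float = 1.0,
    alpha: float = 0.05,
    comparison: str = "a_vs_b",
) -> pd.DataFrame:
    """Welch t-test DEGs between two sample groups.

    log2fc = log2((mean CPM_a + 0.5) / (mean CPM_b + 0.5)); the test is a
    Welch t on log2(CPM+1); padj is Benjamini-Hochberg within the
    comparison. direction is 'up' iff log2fc >= lfc_cut and padj <= alpha,
    'down' symmetrically, otherwise 'ns'.
    """
    ia = _resolve_samples(expr, group_a)
    ib = _resolve_samples(expr, group_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValidationError("need at least 2 samples per group")
    cpm = expr.cpm()
    log2fc = np.log2((cpm[:, ia].mean(axis=1) + 0.5) / (cpm[:, ib].mean(axis=1) + 0.5))
    la, lb = np.log2(cpm[:, ia] + 1.0), np.log2(cpm[:, ib] + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance genes: no evidence
    padj = _bh_adjust(p)
    direction = np.where(
        (log2fc >= lfc_cut) & (padj <= alpha),
        "up",
        np.where((log2fc <= -lfc_cut) & (padj <= alpha), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "gene_id": expr.gene_ids,
            "log2fc": log2fc,
            "p": p,
            "padj": padj,
            "direction": direction,
            "comparison": comparison,
        }
    )


def deg_sets(deg_tables: Iterable[pd.DataFrame]) -> tuple[set[str], set[str]]:
    """Union of up- and down-regulated gene ids across comparisons."""
    up: set[str] = set()
    down: set[str] = set()
    for table in deg_tables:
        up |= set(table.loc[table["direction"] == "up", "gene_id"])
        down |= set(table.loc[table["direction"] == "down", "gene_id"])
    return up, down


# ---------------------------------------------------------------------------
# Transition windows
# ---------------------------------------------------------------------------

def window_genes_around_transitions(
    tt: TransitionTrack,
    genes: list[Gene],
    window_bp: int = 3_000_000,
    types: Iterable[str] = ("A2B", "B2A"),
) -> dict[str, tuple[str, int]]:
    """Genes overlapping +-window_bp around switching transition segments.

    Each selected segment is expanded by window_bp on both sides (clipped to
    the chromosome) and genes with half-open interval overlap are collected.
    The recorded distance is 0 for genes overlapping the segment itself,
    otherwise the gap to the nearest segment edge. When a gene hits several
    segments, the closest one wins.
    """
    types = set(types)
    chrom_len = tt.bin_table.chrom_length
    segs = [s for s in tt.segments if s.label in types]
    out: dict[str, tuple[str, int]] = {}
    for seg in segs:
        win_start = max(0, seg.start_bp - window_bp)
        win_end = min(chrom_len, seg.end_bp + window_bp)
        for g in genes:
            if g.chrom != tt.bin_table.chrom:
                continue
            if g.start < win_end and g.end > win_start:  # half-open overlap
                if g.start < seg.end_bp and g.end > seg.start_bp:
                    dist = 0
                elif g.end <= seg.start_bp:
                    dist = seg.start_bp - g.end + 1
                else:
                    dist = g.start - seg.end_bp
                label = f"{seg.label}:{seg.start_bp}-{seg.end_bp}"
                if g.gene_id not in out or dist < out[g.gene_id][1]:
                    out[g.gene_id] = (label, dist)
    return out


# ---------------------------------------------------------------------------
# Four-way Venn
# ---------------------------------------------------------------------------

SET_NAMES = ("known", "up", "down", "windowed")


@dataclass
class VennPartition:
    """All 15 non-empty-signature regions of four gene sets.

    Regions are keyed by a 4-tuple of booleans in SET_NAMES order; they are
    disjoint and their union equals the union of the inputs.
    """

    sets: dict[str, set[str]]
    regions: dict[tuple[bool, bool, bool, bool], set[str]] = field(init=False)

    def __post_init__(self) -> None:
        universe = set().union(*self.sets.values())
        self.regions = {
            sig: set()
            for sig in product((False, True), repeat=4)
            if any(sig)
        }
        for gid in universe:
            sig = tuple(gid in self.sets[name] for name in SET_NAMES)
            self.regions[sig].add(gid)

    def region(self, *names: str) -> set[str]:
        """Exact region: members of exactly the named sets and no others."""
        unknown = set(names) - set(SET_NAMES)
        if unknown:
            raise ValidationError(f"unknown set names: {sorted(unknown)}")
        sig = tuple(name in names for name in SET_NAMES)
        if not any(sig):
            raise ValidationError("need at least one set name")
        return set(self.regions[sig])

    def region_sizes(self) -> pd.DataFrame:
        rows = []
        for sig, members in sorted(self.regions.items(), reverse=True):
            label = "&".join(n for n, s in zip(SET_NAMES, sig) if s)
            rows.append({"region": label, "size": len(members)})
        return pd.DataFrame(rows)


def four_way_venn(
    known: set[str], up: set[str], down: set[str], windowed: set[str]
) -> VennPartition:
    return VennPartition(
        {"known": set(known), "up": set(up), "down": set(down), "windowed": set(windowed)}
    )


# ---------------------------------------------------------------------------
# Candidate report
# ---------------------------------------------------------------------------

@dataclass
class CandidateReport:
    table: pd.DataFrame      # one annotated row per gene in the Venn universe
    candidates: list[str]    # final candidate set, evidence-ranked
    signature: str


def rank_candidates(
    venn: VennPartition,
    hubs: dict[int, list[str]],
    insulation_tracks: Optional[dict[str, tuple[InsulationTrack, InsulationTrack]]] = None,
    loop_calls: Optional[tuple[list, list]] = None,
    genes: Optional[list[Gene]] = None,
    kme: Optional[pd.DataFrame] = None,
    module_labels: Optional[dict[str, int]] = None,
    flank_bp: int = 100_000,
    require_known: bool = True,
) -> CandidateReport:
    """Build the evidence-annotated candidate report.

    The default candidate signature is windowed AND (up OR down) AND known;
    ``require_known=False`` relaxes it to windowed AND DEG. Each gene in the
    Venn universe is annotated with hub status, the treat-control insulation
    difference at its midpoint and the treat-control loop-count difference
    in gene +- flank_bp; rows sort by evidence count (descending) then
    gene_id.
    """
    sets = venn.sets
    windowed, up, down, known = sets["windowed"], sets["up"], sets["down"], sets["known"]
    deg = up | down
    candidates = windowed & deg & (known if require_known else deg)

    hub_of: dict[str, int] = {}
    for m, members in hubs.items():
        for g in members:
            hub_of[g] = m
    gene_by_id = {g.gene_id: g for g in (genes or [])}

    rows = []
    universe = set().union(*sets.values())
    for gid in sorted(universe):
        g = gene_by_id.get(gid)
        d_ins = np.nan
        d_loops = np.nan
        if g is not None and insulation_tracks and g.chrom in insulation_tracks:
            treat, control = insulation_tracks[g.chrom]
            try:
                d_ins = insulation_at(treat, g.midpoint) - insulation_at(control, g.midpoint)
            except ValidationError:
                pass
        if g is not None and loop_calls is not None:
            start = max(0, g.midpoint - flank_bp)
            end = g.midpoint + flank_bp
            d_loops = count_loops_in_region(
                loop_calls[0], g.chrom, start, end
            ) - count_loops_in_region(loop_calls[1], g.chrom, start, end)
        direction = "up" if gid in up else ("down" if gid in down else "ns")
        is_hub = gid in hub_of
        evidence = sum(
            (gid in windowed, gid in deg, gid in known, is_hub)
        )
        best_kme = np.nan
        if kme is not None and gid in kme.index:
            module = (module_labels or {}).get(gid, hub_of.get(gid))
            if module and module in kme.columns:
                best_kme = float(kme.loc[gid, module])
        rows.append(
            {
                "gene_id": gid,
                "in_transition_window": gid in windowed,
                "deg_direction": direction,
                "in_known_list": gid in known,
                "hub_module": hub_of.get(gid, 0),
                "kme": best_kme,
                "delta_insulation": d_ins,
                "delta_loop_count": d_loops,
                "is_candidate": gid in candidates,
                "evidence_count": evidence,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values(
            ["evidence_count", "gene_id"], ascending=[False, True]
        ).reset_index(drop=True)
    ranked = [r["gene_id"] for _, r in table.iterrows() if r["is_candidate"]]
    if not ranked:
        warnings.warn("candidate set is empty")
    sig = "windowed&deg&known" if require_known else "windowed&deg"
    return CandidateReport(table=table, candidates=ranked, signature=sig)
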