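"""A/B compartment calling and between-sample transition classification.

Compartments are called from the first principal component of the
correlation matrix of the observed/expected map: bins of the same
compartment are positively correlated (the plaid pattern), so PC1 separates
the two states. The eigenvector sign is arbitrary; it is oriented so that
positive values (compartment A) coincide with gene-dense bins, following the
convention that A compartments are open, gene-rich and transcriptionally
active.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import BinTable, Gene, ValidationError

LABELS = ("A", "B", "NA")
JOINT_LABELS = ("A2A", "A2B", "B2A", "B2B", "NA")


class DegenerateMatrixError(ValueError):
    """Correlation matrix carries no variance to decompose."""


@dataclass
class CompartmentTrack:
    """Per-bin oriented PC1 with A/B labels (A <=> pc1 > 0, B <=> pc1 < 0)."""

    bin_table: BinTable
    pc1: np.ndarray
    labels: np.ndarray  # per-bin 'A' / 'B' / 'NA'


@dataclass
class Segment:
    label: str
    start_bin: int
    end_bin: int  # half-open
    start_bp: int
    end_bp: int


@dataclass
class TransitionTrack:
    """Per-bin joint A/B state across two samples plus maximal segments."""

    bin_table: BinTable
    joint: np.ndarray  # per-bin joint label
    segments: list[Segment]


def gene_counts_per_bin(genes: list[Gene], bin_table: BinTable) -> np.ndarray:
    """Number of gene midpoints per bin (orientation covariate)."""
    counts = np.zeros(bin_table.n_bins)
    for g in genes:
        if g.chrom != bin_table.chrom:
            continue
        mid = g.midpoint
        if 0 <= mid < bin_table.chrom_length:
            counts[bin_table.bin_of(mid)] += 1
    return counts


def call_compartments(
    oe: np.ndarray, genes: list[Gene], bin_table: BinTable
) -> CompartmentTrack:
    """Call A/B compartments from an O/E matrix.

    PC1 is the leading right singular vector of the column-centered
    (NaN-aware Pearson) correlation matrix of unmasked O/E columns. The sign
    is fixed so PC1 correlates non-negatively with per-bin gene counts; on an
    exact tie the orientation with frac_A <= frac_B is chosen.
    """
    n = bin_table.n_bins
    oe = np.asarray(oe, dtype=float)
    if oe.shape != (n, n):
        raise ValidationError(f"O/E shape {oe.shape} != ({n}, {n})")
    finite = np.isfinite(oe)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_sd = np.nanstd(np.where(finite, oe, np.nan), axis=0)
    unmasked = (finite.sum(axis=0) >= 2) & np.isfinite(col_sd) & (col_sd > 0)
    if unmasked.sum() < 20:
        raise ValidationError("fewer than 20 unmasked bins")
    sub = oe[np.ix_(unmasked, unmasked)]
    corr = pd.DataFrame(sub).corr(min_periods=2).to_numpy()
    corr = np.where(np.isfinite(corr), corr, 0.0)
    centered = corr - corr.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 1e-12:
        raise DegenerateMatrixError("correlation matrix has zero variance")
    pc1_sub = vt[0]

    gc = gene_counts_per_bin(genes, bin_table)[unmasked]
    r = np.nan
    if gc.std() > 0 and pc1_sub.std() > 0:
        r = float(np.corrcoef(pc1_sub, gc)[0, 1])
    if np.isfinite(r) and r != 0:
        if r < 0:
            pc1_sub = -pc1_sub
    else:  # tie-break: orient so frac_A <= frac_B
        if (pc1_sub > 0).sum() > (pc1_sub < 0).sum():
            pc1_sub = -pc1_sub

    pc1 = np.full(n, np.nan)
    pc1[unmasked] = pc1_sub
    labels = np.full(n, "NA", dtype=object)
    labels[np.nan_to_num(pc1) > 0] = "A"
    labels[np.nan_to_num(pc1) < 0] = "B"
    return CompartmentTrack(bin_table, pc1, labels)


def classify_transitions(
    a: CompartmentTrack, b: CompartmentTrack
) -> tuple[TransitionTrack, pd.DataFrame]:
    """Joint per-bin A/B state of two samples (A2A, A2B, B2A, B2B).

    Returns the track plus a summary counting each category both in bins and
    in maximal same-label segments; 'stable' is A2A+B2B, 'switching' is
    A2B+B2A.
    """
    if a.bin_table != b.bin_table:
        raise ValidationError("bin tables differ between samples")
    bt = a.bin_table
    n = bt.n_bins
    joint = np.full(n, "NA", dtype=object)
    for i in range(n):
        la, lb = a.labels[i], b.labels[i]
        if la != "NA" and lb != "NA":
            joint[i] = f"{la}2{lb}"

    segments: list[Segment] = []
    i = 0
    while i < n:
        if joint[i] == "NA":
            i += 1
            continue
        j = i
        while j < n and joint[j] == joint[i]:
            j += 1
        segments.append(Segment(joint[i], i, j, bt.bin_start(i), bt.bin_end(j - 1)))
        i = j

    rows = []
    for lab in ("A2A", "A2B", "B2A", "B2B", "NA"):
        rows.append(
            {
                "category": lab,
                "n_bins": int((joint == lab).sum()),
                "n_segments": sum(1 for s in segments if s.label == lab),
            }
        )
    counts = pd.DataFrame(rows)
    stable = counts.set_index("category").loc[["A2A", "B2B"]].sum()
    switching = counts.set_index("category").loc[["A2B", "B2A"]].sum()
    summary = pd.concat(
        [
            counts,
            pd.DataFrame(
                [
                    {"category": "stable", "n_bins": int(stable["n_bins"]),
                     "n_segments": int(stable["n_segments"])},
                    {"category": "switching", "n_bins": int(switching["n_bins"]),
                     "n_segments": int(switching["n_segments"])},
                ]
            ),
        ],
        ignore_index=True,
    )
    return TransitionTrack(bt, joint, segments), summary


def compartment_fraction_per_chrom(tracks: dict[str, CompartmentTrack]) -> pd.DataFrame:
    """Fraction of A and B bins per chromosome (over non-NA bins)."""
    if not tracks:
        raise ValidationError("no chromosomes provided")
    rows = []
    for chrom in sorted(tracks):
        t = tracks[chrom]
        n_a = int((t.labels == "A").sum())
        n_b = int((t.labels == "B").sum())
        used = n_a + n_b
        if used == 0:
            warnings.warn(f"chromosome {chrom}: all bins NA")
            rows.append({"chrom": chrom, "frac_A": np.nan, "frac_B": np.nan, "n_bins_used": 0})
        else:
            rows.append(
                {"chrom": chrom, "frac_A": n_a / used, "frac_B": n_b / used,
                 "n_bins_used": used}
            )
    return pd.DataFrame(rows)
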