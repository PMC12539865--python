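"""Insulation-score TAD analysis: per-bin insulation tracks, boundary
calling at local minima, cross-sample boundary comparison, boundary
aggregate pileups and locus lookups.

The insulation score of bin i is the log2 ratio of the mean contact count
in the square window upstream x downstream of i to the chromosome-wide mean
of those window means. Contacts crossing a TAD boundary are depleted, so
boundaries appear as local minima of the score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import BinTable, ContactMatrix, ValidationError


@dataclass
class InsulationTrack:
    bin_table: BinTable
    score: np.ndarray                     # per-bin, NaN near edges
    window_bins: int
    boundaries: list[tuple[int, float]] = field(default_factory=list)


def insulation_score(cm: ContactMatrix, window_bins: int = 5) -> InsulationTrack:
    """Insulation (TAD separation) score per bin.

    ``w_i`` is the mean of counts over rows [i-w, i-1] x cols [i+1, i+w];
    ``score_i = log2(w_i / mean(w))``. Bins within one window of either edge
    are NaN; windows with zero contacts are NaN (log undefined).
    """
    if window_bins < 1:
        raise ValidationError("window_bins must be >= 1")
    n = cm.n_bins
    if n <= 2 * window_bins:
        raise ValidationError(f"need more than {2 * window_bins} bins")
    w = window_bins
    wmeans = np.full(n, np.nan)
    for i in range(w, n - w):
        wmeans[i] = cm.counts[i - w : i, i + 1 : i + w + 1].mean()
    overall = np.nanmean(wmeans)
    if not np.isfinite(overall) or overall <= 0:
        raise ValidationError("chromosome-wide window mean is not positive")
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.log2(wmeans / overall)
    score[np.isneginf(score)] = np.nan
    return InsulationTrack(cm.bin_table, score, window_bins)


def call_boundaries(
    track: InsulationTrack, min_strength: float = 0.1
) -> list[tuple[int, float]]:
    """Boundaries = strict local minima of the insulation score.

    Strength is the mean of the maximum score on each side within the
    insulation window minus the score at the minimum; only minima with
    strength >= min_strength are kept.
    """
    s = track.score
    n = len(s)
    w = track.window_bins
    out: list[tuple[int, float]] = []
    for i in range(1, n - 1):
        if not (np.isfinite(s[i]) and np.isfinite(s[i - 1]) and np.isfinite(s[i + 1])):
            continue
        if not (s[i] < s[i - 1] and s[i] < s[i + 1]):
            continue
        left = s[max(0, i - w) : i]
        right = s[i + 1 : i + 1 + w]
        left = left[np.isfinite(left)]
        right = right[np.isfinite(right)]
        if len(left) == 0 or len(right) == 0:
            continue
        strength = float((left.max() + right.max()) / 2.0 - s[i])
        if strength >= min_strength:
            out.append((i, strength))
    return sorted(out)


def compare_boundaries(
    a: list[tuple[int, float]] | list[int],
    b: list[tuple[int, float]] | list[int],
    tol_bins: int = 1,
):
    """Greedy nearest matching of two boundary lists within tol_bins.

    Each boundary is matched at most once; pairs are taken in order of
    increasing distance (ties by position). Returns (shared pairs,
    unique_a, unique_b) with |shared| + |unique_a| == |a|.
    """
    bins_a = [x[0] if isinstance(x, tuple) else int(x) for x in a]
    bins_b = [x[0] if isinstance(x, tuple) else int(x) for x in b]
    cand = []
    for ia, ba in enumerate(bins_a):
        for ib, bb in enumerate(bins_b):
            d = abs(ba - bb)
            if d <= tol_bins:
                cand.append((d, ba, bb, ia, ib))
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared: list[tuple[int, int]] = []
    for d, ba, bb, ia, ib in cand:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        shared.append((ba, bb))
    unique_a = sorted(bins_a[i] for i in range(len(bins_a)) if i not in used_a)
    unique_b = sorted(bins_b[i] for i in range(len(bins_b)) if i not in used_b)
    return sorted(shared), unique_a, unique_b


def aggregate_boundary_profile(
    oe: np.ndarray, boundaries, flank_bins: int = 10
) -> tuple[np.ndarray, int]:
    """Mean O/E pileup of (2*flank+1)^2 submatrices centered on boundaries.

    Boundaries without a full flank inside the matrix are skipped; raises if
    none are usable. Returns (pileup, n_used).
    """
    oe = np.asarray(oe, dtype=float)
    n = oe.shape[0]
    f = flank_bins
    stack = []
    for b in boundaries:
        i = b[0] if isinstance(b, tuple) else int(b)
        if i - f < 0 or i + f >= n:
            continue
        stack.append(oe[i - f : i + f + 1, i - f : i + f + 1])
    if not stack:
        raise ValidationError("no boundary with a full flank inside the matrix")
    return np.nanmean(np.stack(stack), axis=0), len(stack)


def insulation_at(track: InsulationTrack, chrom_pos: int) -> float:
    """Insulation score of the bin containing a bp position."""
    return float(track.score[track.bin_table.bin_of(chrom_pos)])
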