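"""Distance-decay models, O/E transform, lowess z-score normalization,
differential matrices and replicate reproducibility for contact matrices.

Hi-C contact frequency decays with genomic distance, so every comparison is
made within distance strata: the expected profile is the per-diagonal mean,
the O/E transform divides it out, and the lowess z-score normalization
standardizes each diagonal against smooth (lowess) fits of the per-distance
mean and standard deviation so that matrices from different samples can be
subtracted directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_formats import BinTable, ContactMatrix, ValidationError


@dataclass
class NormalizedMatrix:
    """Per-distance z-scores; masked (zero-coverage) bins are all-NaN."""

    bin_table: BinTable
    values: np.ndarray
    mask: np.ndarray  # per-bin bool, True = masked

    @property
    def n_bins(self) -> int:
        return self.bin_table.n_bins


def expected_by_distance(cm: ContactMatrix) -> np.ndarray:
    """Mean contact value at each separation d = 0..n_bins-1 (the expected
    profile); distance 0 is the diagonal mean."""
    n = cm.n_bins
    if n < 2:
        raise ValidationError("need at least 2 bins")
    e = np.empty(n)
    for d in range(n):
        e[d] = cm.counts.diagonal(d).mean()
    return e


def _distance_matrix(n: int) -> np.ndarray:
    idx = np.arange(n)
    return np.abs(idx[:, None] - idx[None, :])


def oe_transform(cm: ContactMatrix, pseudocount: float = 0.0) -> np.ndarray:
    """Observed/expected matrix: counts divided by the distance-matched
    expected; entries whose expected (plus pseudocount) is 0 are NaN."""
    e = expected_by_distance(cm)
    em = e[_distance_matrix(cm.n_bins)]
    denom = em + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(denom > 0, (cm.counts + pseudocount) / denom, np.nan)
    return oe


def lowess_zscore_normalize(
    cm: ContactMatrix, frac: float = 0.3, sigma_floor: float = 1e-8
) -> NormalizedMatrix:
    """Lowess z-score normalization of a contact matrix.

    Per-distance means and standard deviations are lowess-smoothed in
    log10 space against a log10(1+d) axis (a power-law decay is exactly
    linear there, so the local-linear smoother reproduces it without the
    short-range bias a raw-scale fit would have); each entry is z-scored
    against the smoothed curves:
    ``z[i,j] = (counts[i,j] - mu_hat(|i-j|)) / sigma_hat(|i-j|)``. Bins with
    zero marginal coverage are masked (all-NaN rows/columns). The smoother
    runs without robustifying iterations so it is linear in log-counts,
    which makes z exactly invariant to rescaling all counts (sequencing
    depth).
    """
    n = cm.n_bins
    if n < 10:
        raise ValidationError("need at least 10 bins for lowess normalization")
    marginal = cm.counts.sum(axis=0)
    mask = marginal == 0
    mu = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    for d in range(n):
        vals = cm.counts.diagonal(d)
        valid = ~(mask[: n - d] | mask[d:])
        if valid.any():
            v = vals[valid]
            mu[d] = v.mean()
            sd[d] = v.std()
    if int(np.isfinite(mu).sum()) < 3:
        raise ValidationError("fewer than 3 distinct distances with data")
    x_all = np.log10(1.0 + np.arange(n))

    def _log_smooth(y: np.ndarray) -> np.ndarray:
        usable = np.isfinite(y) & (y > 0)
        if usable.sum() < 3:
            return np.full(n, np.nan)
        fit = lowess(np.log10(y[usable]), x_all[usable], frac=frac, it=0,
                     return_sorted=False)
        # strata without a usable estimate take the interpolated smooth
        full = np.interp(x_all, x_all[usable], fit)
        return 10.0**full

    mu_full = _log_smooth(mu)
    mu_full[~np.isfinite(mu)] = np.nan
    sd_full = _log_smooth(sd)
    if np.all(~np.isfinite(sd_full)):  # all strata have zero spread
        sd_full = np.full(n, sigma_floor)
    sd_full = np.maximum(sd_full, sigma_floor)
    sd_full[~np.isfinite(mu)] = np.nan
    dm = _distance_matrix(n)
    with np.errstate(invalid="ignore"):
        z = (cm.counts - mu_full[dm]) / sd_full[dm]
    z[mask, :] = np.nan
    z[:, mask] = np.nan
    return NormalizedMatrix(cm.bin_table, z, mask)


def differential_matrix(treat: NormalizedMatrix, control: NormalizedMatrix) -> NormalizedMatrix:
    """Treatment minus control z-score matrices (NaN where either is masked)."""
    if treat.bin_table != control.bin_table:
        raise ValidationError("bin tables differ between treat and control")
    return NormalizedMatrix(
        treat.bin_table, treat.values - control.values, treat.mask | control.mask
    )


def reproducibility_score(
    cm1: ContactMatrix, cm2: ContactMatrix, max_dist_bins: int = 20
) -> float:
    """Distance-stratified replicate concordance in [-1, 1].

    Pearson correlation is computed separately at each separation
    d = 1..max_dist_bins and combined as a weighted mean with weights equal
    to the number of finite pairs in each stratum. Stratifying by distance
    prevents the universal distance decay from inflating the correlation.
    """
    if cm1.bin_table != cm2.bin_table:
        raise ValidationError("bin tables differ between replicates")
    n = cm1.n_bins
    num = 0.0
    den = 0.0
    for d in range(1, min(max_dist_bins, n - 1) + 1):
        v1 = cm1.counts.diagonal(d)
        v2 = cm2.counts.diagonal(d)
        ok = np.isfinite(v1) & np.isfinite(v2)
        v1, v2 = v1[ok], v2[ok]
        if len(v1) < 3 or v1.std() == 0 or v2.std() == 0:
            continue  # degenerate stratum
        r = np.corrcoef(v1, v2)[0, 1]
        num += len(v1) * r
        den += len(v1)
    if den == 0:
        warnings.warn("all distance strata degenerate; reproducibility undefined")
        return float("nan")
    return num / den
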