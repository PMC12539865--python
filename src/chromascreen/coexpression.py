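"""Weighted gene coexpression network analysis built from scratch.

The pipeline follows the classical WGCNA construction: an unsigned
adjacency ``a_ij = |cor(x_i, x_j)|^beta`` with the soft-thresholding power
beta chosen for approximate scale-free topology, topological overlap (TOM)
as the clustering similarity, average-linkage hierarchical clustering with
a static height cut for module detection, module eigengenes (first
principal component of the standardized member expression), eigengene-
correlation module merging, module-trait correlation and module membership
(kME) to define hub genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io_formats import ValidationError


@dataclass
class ExpressionMatrix:
    """Genes x samples expression counts plus sample metadata."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    metadata: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {v.shape} != ({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        self.values = v

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def cpm(self) -> np.ndarray:
        lib = self.values.sum(axis=0)
        if np.any(lib <= 0):
            raise ValidationError("sample with non-positive library size")
        return 1e6 * self.values / lib

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        wanted = [g for g in gene_ids if g in set(self.gene_ids)]
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in wanted]
        return ExpressionMatrix(wanted, self.sample_ids, self.values[rows], self.metadata)


@dataclass
class ScaleFreeFit:
    powers: list[int]
    r2_signed: list[float]
    chosen: int


@dataclass
class ModuleSet:
    """Module labels (0 = unassigned) with derived eigengene/kME artifacts."""

    gene_ids: list[str]
    labels: np.ndarray
    eigengenes: Optional[pd.DataFrame] = None  # modules x samples
    kme: Optional[pd.DataFrame] = None         # genes x modules
    merge_history: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(m) for m in np.unique(self.labels) if m != 0)

    def members(self, module: int) -> list[str]:
        return [g for g, l in zip(self.gene_ids, self.labels) if l == module]


def _log_expression(expr: ExpressionMatrix) -> np.ndarray:
    """Network analysis operates on log2(count+1)."""
    return np.log2(expr.values + 1.0)


def _drop_constant(values: np.ndarray, gene_ids: list[str]):
    sd = values.std(axis=1)
    keep = sd > 0
    if not keep.all():
        dropped = [g for g, k in zip(gene_ids, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} constant genes: {dropped[:5]}...")
    return values[keep], [g for g, k in zip(gene_ids, keep) if k]


def scale_free_r2(k: np.ndarray, k_bins: int = 10) -> float:
    """Signed scale-free topology fit index of a connectivity vector.

    Connectivity is discretized into equal-width bins; log10 frequency is
    regressed on log10 mean connectivity per bin. The R^2 is signed by the
    negated slope so that only decreasing frequency-connectivity
    relationships (the scale-free signature) score positively.
    """
    k = np.asarray(k, dtype=float)
    edges = np.linspace(k.min(), k.max(), k_bins + 1)
    edges[-1] += 1e-12
    which = np.digitize(k, edges) - 1
    xs, ys = [], []
    for b in range(k_bins):
        sel = which == b
        if sel.sum() == 0:
            continue
        mean_k = k[sel].mean()
        freq = sel.sum() / len(k)
        if mean_k > 0 and freq > 0:
            xs.append(np.log10(mean_k))
            ys.append(np.log10(freq))
    if len(xs) < 3:
        raise ValidationError("fewer than 3 usable connectivity bins")
    if np.std(ys) == 0:  # flat frequency: no relationship at all
        return 0.0
    res = stats.linregress(xs, ys)
    return float(res.rvalue**2 * (-np.sign(res.slope)))


def pick_soft_threshold(
    expr: ExpressionMatrix,
    powers: Iterable[int] = range(1, 21),
    target_r2: float = 0.8,
    k_bins: int = 10,
) -> ScaleFreeFit:
    """Choose the soft-thresholding power for the unsigned adjacency.

    The chosen beta is the smallest power whose signed scale-free R^2
    reaches target_r2, falling back to the argmax when none does.
    """
    if expr.n_genes < 30:
        raise ValidationError("need at least 30 genes")
    if expr.n_samples < 4:
        raise ValidationError("need at least 4 samples")
    values, _ = _drop_constant(_log_expression(expr), expr.gene_ids)
    cor = np.abs(np.corrcoef(values))
    powers = list(powers)
    fits = []
    for beta in powers:
        a = cor**beta
        np.fill_diagonal(a, 0.0)
        fits.append(scale_free_r2(a.sum(axis=1), k_bins=k_bins))
    chosen = None
    for beta, r2 in zip(powers, fits):
        if r2 >= target_r2:
            chosen = beta
            break
    if chosen is None:
        chosen = powers[int(np.argmax(fits))]
    return ScaleFreeFit(powers, fits, chosen)


def adjacency(expr: ExpressionMatrix, beta: int) -> np.ndarray:
    """Unsigned adjacency |cor|^beta with unit diagonal."""
    if beta < 1:
        raise ValidationError("beta must be >= 1")
    values = _log_expression(expr)
    sd = values.std(axis=1)
    if np.any(sd == 0):
        bad = [g for g, s in zip(expr.gene_ids, sd) if s == 0]
        raise ValidationError(f"constant genes have undefined correlation: {bad[:10]}")
    a = np.abs(np.corrcoef(values)) ** beta
    np.fill_diagonal(a, 1.0)
    return np.clip(a, 0.0, 1.0)


def tom_similarity(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an adjacency.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k_i = sum_{u != i} a_iu; TOM_ii = 1.
    """
    a = np.asarray(adj, dtype=float)
    k = a.sum(axis=1) - np.diag(a)
    # (A@A)_ij includes u=i and u=j terms a_ii*a_ij + a_ij*a_jj = 2*a_ij (diag=1)
    shared = a @ a - 2.0 * a
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray,
    gene_ids: list[str],
    min_size: int = 15,
    cut_height: float = 0.99,
) -> ModuleSet:
    """Detect modules by average-linkage clustering of TOM dissimilarity.

    The dendrogram is cut at the fixed dissimilarity height ``cut_height``
    (TOM dissimilarity lives in [0, 1]; unrelated genes sit at ~1, so the
    static cut just below 1 splinters them into unassigned singletons).
    Clusters with >= min_size genes become modules, numbered by decreasing
    size; all other genes get label 0.
    """
    n = len(gene_ids)
    if tom.shape != (n, n):
        raise ValidationError("TOM shape does not match gene ids")
    if n < min_size:
        return ModuleSet(gene_ids, np.zeros(n, dtype=int))
    d = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= min_size]
    # number by decreasing size; ties by first-gene order for determinism
    kept.sort(key=lambda c: (-sizes[c], int(np.nonzero(raw == c)[0][0])))
    for new_id, c in enumerate(kept, start=1):
        labels[raw == c] = new_id
    return ModuleSet(gene_ids, labels)


def module_eigengene(expr: ExpressionMatrix, labels: np.ndarray) -> pd.DataFrame:
    """Module eigengenes: first PC of standardized member expression.

    Each eigengene has unit variance and is sign-oriented to correlate
    positively with the module's mean standardized expression. Singleton
    modules return the standardized gene itself.
    """
    values = _log_expression(expr)
    modules = sorted(int(m) for m in np.unique(labels) if m != 0)
    if not modules:
        raise ValidationError("no modules to summarize")
    rows = {}
    for m in modules:
        x = values[labels == m]
        sd = x.std(axis=1, keepdims=True)
        mean = x.mean(axis=1, keepdims=True)
        xs = np.where(sd > 0, (x - mean) / np.where(sd > 0, sd, 1.0), 0.0)
        if xs.shape[0] == 1:
            eg = xs[0].copy()
        else:
            u, s, vt = np.linalg.svd(xs, full_matrices=False)
            eg = vt[0]
        profile = xs.mean(axis=0)
        if profile.std() > 0 and eg.std() > 0 and np.corrcoef(eg, profile)[0, 1] < 0:
            eg = -eg
        if eg.std() > 0:
            eg = (eg - eg.mean()) / eg.std()
        rows[m] = eg
    return pd.DataFrame.from_dict(rows, orient="index", columns=expr.sample_ids)


def merge_modules(
    expr: ExpressionMatrix, moduleset: ModuleSet, merge_r: float = 0.75
) -> ModuleSet:
    """Iteratively merge the module pair with the highest eigengene
    correlation while it exceeds merge_r, recomputing eigengenes after each
    merge. Final labels are renumbered by decreasing module size and the
    eigengenes and kME matrix of the merged set are attached.
    """
    labels = moduleset.labels.copy()
    history: list[tuple[int, int, float]] = []
    while len([m for m in np.unique(labels) if m != 0]) > 1:
        eg = module_eigengene(expr, labels)
        mods = list(eg.index)
        cor = np.corrcoef(eg.to_numpy())
        np.fill_diagonal(cor, -np.inf)
        a, b = np.unravel_index(int(np.argmax(cor)), cor.shape)
        best_r = float(cor[a, b])
        if best_r <= merge_r:
            break
        keep, absorb = sorted((mods[a], mods[b]))
        labels[labels == absorb] = keep
        history.append((keep, absorb, best_r))

    # renumber by decreasing size
    sizes = {m: int((labels == m).sum()) for m in np.unique(labels) if m != 0}
    order = sorted(sizes, key=lambda m: (-sizes[m], m))
    relabeled = np.zeros_like(labels)
    for new_id, m in enumerate(order, start=1):
        relabeled[labels == m] = new_id
    out = ModuleSet(moduleset.gene_ids, relabeled, merge_history=history)
    if order:
        out.eigengenes = module_eigengene(expr, relabeled)
        out.kme = module_membership(expr, out.eigengenes)
    return out


def module_trait_correlation(
    eigengenes: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r and two-sided Student t p per module x trait."""
    if len(traits) != eigengenes.shape[1]:
        raise ValidationError("trait length != number of samples")
    if len(traits) < 3:
        raise ValidationError("need at least 3 samples")
    rows = []
    for trait in traits.columns:
        t = traits[trait].to_numpy(dtype=float)
        if t.std() == 0:
            raise ValidationError(f"trait {trait!r} has zero variance")
        for m in eigengenes.index:
            r, p = stats.pearsonr(eigengenes.loc[m].to_numpy(), t)
            rows.append({"module": m, "trait": trait, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


def module_membership(expr: ExpressionMatrix, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """kME matrix: correlation of each gene with each module eigengene."""
    values = _log_expression(expr)
    sd = values.std(axis=1, keepdims=True)
    zg = np.where(sd > 0, (values - values.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0), 0.0)
    eg = eigengenes.to_numpy()
    esd = eg.std(axis=1, keepdims=True)
    ze = (eg - eg.mean(axis=1, keepdims=True)) / np.where(esd > 0, esd, 1.0)
    kme = zg @ ze.T / values.shape[1]
    kme = np.clip(kme, -1.0, 1.0)
    kme[sd[:, 0] == 0, :] = np.nan
    return pd.DataFrame(kme, index=expr.gene_ids, columns=list(eigengenes.index))


def hub_genes(moduleset: ModuleSet, mm_cut: float = 0.8) -> dict[int, list[str]]:
    """Hub genes per module: assigned genes with |kME| above mm_cut."""
    if moduleset.kme is None:
        raise ValidationError("moduleset has no kME matrix; run merge_modules first")
    hubs: dict[int, list[str]] = {}
    for m in moduleset.module_ids:
        members = set(moduleset.members(m))
        col = moduleset.kme[m]
        hubs[m] = sorted(g for g in members if abs(col.loc[g]) > mm_cut)
    return hubs
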