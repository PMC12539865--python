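"""Seeded synthetic-data generators with planted ground truth.

The generators emulate the features of a two-condition (red- vs
green-skinned) fruit-skin 3D-genome study that the downstream analysis is
designed to detect: power-law distance-decay contact maps with a plaid
compartment pattern, block TADs and point loops (Poisson counts);
module-structured expression over two conditions x three coloration
stages with planted differential genes and a trait-anticorrelated module;
gene annotations biased toward A compartments; and a full study fixture
whose evidence chain (compartment switch -> 3-Mb window -> DEG -> known
list -> hub confirmation) points at a single planted candidate gene.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io_formats as iof
from .io_formats import BinTable, ContactMatrix, Gene, ValidationError
from .coexpression import ExpressionMatrix

import pandas as pd


# ---------------------------------------------------------------------------
# Hi-C
# ---------------------------------------------------------------------------

@dataclass
class HiCTruth:
    compartment_profile: np.ndarray        # +1 (A) / -1 (B) per bin
    tad_boundaries: list[int]
    loops: list[tuple[int, int]]
    alpha: float
    compartment_strength: float
    tad_contrast: float
    loop_boost: float
    depth: float
    seed: int


def make_contact_matrix(
    n_bins: int,
    resolution: int = 100_000,
    alpha: float = 1.0,
    compartment_profile: Optional[Sequence[int]] = None,
    compartment_strength: float = 0.3,
    tad_boundaries: Optional[Sequence[int]] = None,
    tad_contrast: float = 2.0,
    loops: Optional[Sequence[tuple[int, int]]] = None,
    loop_boost: float = 5.0,
    depth: float = 50.0,
    seed: int = 0,
    chrom: str = "chrSim",
) -> tuple[ContactMatrix, HiCTruth]:
    """Poisson contact matrix with planted compartments, TADs and loops.

    The Poisson intensity for a bin pair (i, j) is
    ``depth * (|i-j|+1)^-alpha * (1 + strength*s_i*s_j)
    * (tad_contrast if same TAD else 1) * (loop_boost if near a loop else 1)``
    where s is the planted +-1 compartment profile and "near a loop" means
    within one bin of a planted anchor pair. Counts are drawn on the upper
    triangle and mirrored; everything is a pure function of parameters+seed.
    """
    if n_bins < 50:
        raise ValidationError("n_bins must be >= 50")
    if compartment_strength >= 1:
        raise ValidationError("compartment_strength must be < 1")
    if compartment_profile is None:
        s = np.zeros(n_bins)
    else:
        s = np.asarray(compartment_profile, dtype=float)
        if len(s) != n_bins:
            raise ValidationError("compartment profile length != n_bins")
    tad_boundaries = sorted(tad_boundaries or [])
    loops = list(loops or [])

    idx = np.arange(n_bins)
    dist = np.abs(idx[:, None] - idx[None, :])
    lam = depth * (dist + 1.0) ** (-alpha)
    lam *= 1.0 + compartment_strength * np.outer(s, s)
    if tad_boundaries:  # no boundaries = no domain structure at all
        tid = np.searchsorted(tad_boundaries, idx, side="right")
        lam *= np.where(tid[:, None] == tid[None, :], tad_contrast, 1.0)
    loop_factor = np.ones((n_bins, n_bins))
    for p, q in loops:
        p0, p1 = max(0, p - 1), min(n_bins, p + 2)
        q0, q1 = max(0, q - 1), min(n_bins, q + 2)
        loop_factor[p0:p1, q0:q1] = loop_boost
        loop_factor[q0:q1, p0:p1] = loop_boost
    lam *= loop_factor

    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n_bins)
    vals = rng.poisson(lam[iu, ju]).astype(float)
    counts = np.zeros((n_bins, n_bins))
    counts[iu, ju] = vals
    counts = counts + counts.T - np.diag(np.diag(counts))
    cm = ContactMatrix(BinTable(chrom, resolution, n_bins * resolution), counts)
    truth = HiCTruth(
        compartment_profile=s.astype(int),
        tad_boundaries=list(tad_boundaries),
        loops=[(int(p), int(q)) for p, q in loops],
        alpha=alpha,
        compartment_strength=compartment_strength,
        tad_contrast=tad_contrast,
        loop_boost=loop_boost,
        depth=depth,
        seed=seed,
    )
    return cm, truth


def block_profile(n_bins: int, block: int = 15, start_sign: int = 1) -> np.ndarray:
    """Alternating +-1 compartment profile in blocks of `block` bins."""
    s = np.empty(n_bins, dtype=int)
    sign = start_sign
    for i in range(0, n_bins, block):
        s[i : i + block] = sign
        sign = -sign
    return s


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class GroupDesign:
    conditions: tuple[str, ...] = ("red", "green")
    stages: tuple[str, ...] = ("S1", "S2", "S3")
    reps: int = 6

    def samples(self) -> list[tuple[str, str, str]]:
        out = []
        for cond in self.conditions:
            for stage in self.stages:
                for r in range(1, self.reps + 1):
                    out.append((f"{cond}_{stage}_r{r}", cond, stage))
        return out


@dataclass
class ModuleSpec:
    """One planted coexpression module.

    Member loadings on the module factor fall linearly from ``hub_loading``
    (the first ``n_hubs`` genes) to ``min_loading``; the loading gradient
    gives the network the heterogeneous connectivity spectrum that real
    coexpression data show (and that scale-free fitting expects)."""

    size: int
    min_loading: float = 0.6
    n_hubs: int = 5
    hub_loading: float = 0.95
    factor: str = "random"  # 'random', 'trait:<name>' or 'anti_trait:<name>'

    def loadings(self) -> np.ndarray:
        l = np.linspace(self.hub_loading, self.min_loading, self.size)
        l[: self.n_hubs] = self.hub_loading
        return l


# default redness trait: the red condition colors up across stages,
# the green condition stays green throughout
DEFAULT_TRAITS = {
    "redness": {
        ("red", "S1"): 0.1,
        ("red", "S2"): 0.6,
        ("red", "S3"): 1.0,
        ("green", "S1"): 0.0,
        ("green", "S2"): 0.0,
        ("green", "S3"): 0.0,
    }
}

DEFAULT_MODULES = [
    ModuleSpec(size=50, factor="anti_trait:redness"),
    ModuleSpec(size=40, factor="random"),
    ModuleSpec(size=30, factor="random"),
]


@dataclass
class ExpressionTruth:
    module_labels: dict[str, int]
    hub_genes: dict[int, list[str]]
    factors: dict[int, np.ndarray]
    de_table: pd.DataFrame
    traits: pd.DataFrame


def make_expression(
    n_genes: int = 300,
    module_spec: Optional[list[ModuleSpec]] = None,
    group_design: Optional[GroupDesign] = None,
    de_spec: Optional[list[tuple[str, str, float]]] = None,
    trait_spec: Optional[dict] = None,
    noise_sd: float = 0.3,
    background_loading: tuple[float, float] = (0.1, 0.3),
    seed: int = 0,
    gene_ids: Optional[list[str]] = None,
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Module-structured expression counts with planted group effects.

    Genes carry a log2-scale signal: baseline + loading * module factor
    (per sample) + a weak global background factor (loading drawn uniformly
    from ``background_loading``, giving every gene the low-level shared
    covariance real expression data show) + differential offsets (red minus
    green, per stage) + Gaussian noise; counts are 2^signal scaled by a
    mild per-sample library factor and rounded. de_spec entries are
    (gene_id, stage, log2fc) applied to the first condition of the design.
    """
    module_spec = DEFAULT_MODULES if module_spec is None else module_spec
    design = group_design or GroupDesign()
    trait_spec = DEFAULT_TRAITS if trait_spec is None else trait_spec
    de_spec = de_spec or []
    samples = design.samples()
    n_samples = len(samples)
    if design.reps < 2:
        raise ValidationError("need >= 2 replicates per group")
    if sum(m.size for m in module_spec) > n_genes:
        raise ValidationError("module sizes exceed n_genes")
    if gene_ids is None:
        gene_ids = [f"g{i:04d}" for i in range(1, n_genes + 1)]
    elif len(gene_ids) != n_genes:
        raise ValidationError("gene_ids length != n_genes")

    traits = pd.DataFrame(index=[s[0] for s in samples])
    for trait, table in trait_spec.items():
        vals = []
        for sid, cond, stage in samples:
            if (cond, stage) not in table:
                raise ValidationError(f"trait {trait!r} missing value for {(cond, stage)}")
            vals.append(table[(cond, stage)])
        traits[trait] = vals

    rng = np.random.default_rng(seed)
    labels = np.zeros(n_genes, dtype=int)
    loadings = np.zeros(n_genes)
    pos = 0
    hubs: dict[int, list[str]] = {}
    factors: dict[int, np.ndarray] = {}
    for mid, spec in enumerate(module_spec, start=1):
        labels[pos : pos + spec.size] = mid
        loadings[pos : pos + spec.size] = spec.loadings()
        hubs[mid] = gene_ids[pos : pos + spec.n_hubs]
        if spec.factor == "random":
            f = rng.normal(size=n_samples)
        elif spec.factor.startswith(("trait:", "anti_trait:")):
            kind, name = spec.factor.split(":", 1)
            t = traits[name].to_numpy(dtype=float)
            if t.std() == 0:
                raise ValidationError(f"trait {name!r} is constant; cannot drive a module")
            f = (t - t.mean()) / t.std()
            f = f + rng.normal(scale=0.15, size=n_samples)
            if kind == "anti_trait":
                f = -f
        else:
            raise ValidationError(f"unknown module factor spec {spec.factor!r}")
        f = (f - f.mean()) / f.std()
        factors[mid] = f
        pos += spec.size

    baseline = rng.uniform(4.0, 9.0, size=n_genes)
    signal = baseline[:, None] + np.zeros((n_genes, n_samples))
    for mid in factors:
        members = labels == mid
        signal[members] += np.outer(loadings[members], factors[mid])
    bg_factor = rng.normal(size=n_samples)
    bg_load = rng.uniform(*background_loading, size=n_genes)
    signal += np.outer(bg_load, bg_factor)

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    de_rows = []
    for gid, stage, lfc in de_spec:
        if gid not in gene_index:
            raise ValidationError(f"de_spec references unknown gene {gid!r}")
        if stage not in design.stages:
            raise ValidationError(f"de_spec references unknown stage {stage!r}")
        cols = [k for k, (_, cond, st) in enumerate(samples)
                if cond == design.conditions[0] and st == stage]
        signal[gene_index[gid], cols] += lfc
        de_rows.append({"gene_id": gid, "stage": stage, "log2fc": lfc})

    signal += rng.normal(scale=noise_sd, size=signal.shape)
    lib = np.exp(rng.normal(scale=0.1, size=n_samples))
    counts = np.round(2.0**signal * lib)

    meta = pd.DataFrame(
        {
            "sample": [s[0] for s in samples],
            "group": [s[1] for s in samples],
            "stage": [s[2] for s in samples],
        }
    ).set_index("sample", drop=False)
    for trait in traits.columns:
        meta[trait] = traits[trait].to_numpy()

    expr = ExpressionMatrix(list(gene_ids), [s[0] for s in samples], counts, meta)
    truth = ExpressionTruth(
        module_labels={g: int(l) for g, l in zip(gene_ids, labels)},
        hub_genes=hubs,
        factors=factors,
        de_table=pd.DataFrame(de_rows, columns=["gene_id", "stage", "log2fc"]),
        traits=traits,
    )
    return expr, truth


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def make_annotation(
    n_genes: int,
    chrom_lengths: dict[str, int],
    bin_weights: Optional[dict[str, np.ndarray]] = None,
    resolution: int = 100_000,
    gene_length: int = 2_000,
    gap: int = 500,
    seed: int = 0,
    fixed_genes: Optional[list[Gene]] = None,
) -> list[Gene]:
    """Place non-overlapping genes on chromosomes, optionally biased by
    per-bin weights (e.g. heavier on A-compartment bins for PC1
    orientation). ``fixed_genes`` are kept verbatim and their slots
    reserved. Deterministic under the seed; raises on over-packing.
    """
    rng = np.random.default_rng(seed)
    slot = gene_length + gap
    fixed_genes = list(fixed_genes or [])
    genes: list[Gene] = list(fixed_genes)
    total_len = sum(chrom_lengths.values())
    chroms = sorted(chrom_lengths)
    remaining = n_genes - len(fixed_genes)
    if remaining < 0:
        raise ValidationError("more fixed genes than n_genes")
    # apportion by chromosome length (largest remainder)
    quotas = {c: int(remaining * chrom_lengths[c] / total_len) for c in chroms}
    leftovers = sorted(
        chroms,
        key=lambda c: -(remaining * chrom_lengths[c] / total_len - quotas[c]),
    )
    for c in leftovers[: remaining - sum(quotas.values())]:
        quotas[c] += 1

    counter = 1
    for chrom in chroms:
        length = chrom_lengths[chrom]
        n_slots = length // slot
        occupied = set()
        for g in fixed_genes:
            if g.chrom == chrom:
                occupied.update(range(g.start // slot, g.end // slot + 1))
        free = [s for s in range(n_slots) if s not in occupied]
        if quotas[chrom] > len(free):
            raise ValidationError(f"cannot place {quotas[chrom]} genes on {chrom}")
        if bin_weights and chrom in bin_weights:
            w = np.asarray(bin_weights[chrom], dtype=float)
            pw = np.array([w[min(len(w) - 1, (s * slot) // resolution)] for s in free])
            pw = pw / pw.sum()
        else:
            pw = None
        chosen = rng.choice(len(free), size=quotas[chrom], replace=False, p=pw)
        for s in sorted(free[i] for i in chosen):
            start = s * slot
            genes.append(Gene(f"g{counter:04d}", chrom, start, start + gene_length, "+"))
            counter += 1
    return genes


# ---------------------------------------------------------------------------
# Full study fixture
# ---------------------------------------------------------------------------

@dataclass
class StudyTruth:
    chroms: dict[str, int]
    resolution: int
    conditions: tuple[str, str]
    profiles: dict[str, dict[str, list[int]]]   # condition -> chrom -> profile
    tad_boundaries: dict[str, list[int]]
    loops: dict[str, dict[str, list[tuple[int, int]]]]
    switching_region: tuple[str, int, int]      # chrom, start_bp, end_bp (B in red -> A in green)
    candidate_gene: str
    known_genes: list[str]
    expression: ExpressionTruth
    seed: int

    def to_json(self) -> str:
        d = {
            "chroms": self.chroms,
            "resolution": self.resolution,
            "conditions": list(self.conditions),
            "profiles": {c: {k: list(map(int, v)) for k, v in p.items()}
                         for c, p in self.profiles.items()},
            "tad_boundaries": self.tad_boundaries,
            "loops": self.loops,
            "switching_region": list(self.switching_region),
            "candidate_gene": self.candidate_gene,
            "known_genes": self.known_genes,
            "module_labels": self.expression.module_labels,
            "hub_genes": {str(k): v for k, v in self.expression.hub_genes.items()},
            "de_table": self.expression.de_table.to_dict(orient="records"),
            "seed": self.seed,
        }
        return json.dumps(d, indent=1, sort_keys=True)


SCALES = {
    # n_bins per chromosome, genes, expression reps, Hi-C depth
    "default": dict(n_bins=300, n_genes=600, reps=6, depth=50.0),
    "small": dict(n_bins=120, n_genes=240, reps=4, depth=50.0),
}


def make_study_fixture(
    outdir, seed: int = 0, scale: str = "default"
) -> tuple[dict, StudyTruth]:
    """Write a complete two-condition study to ``outdir`` and return its
    manifest (dict of paths) plus the planted StudyTruth.

    The study has two synthetic chromosomes; chr2 carries a region that is
    compartment B in the red condition and A in the green condition. A
    candidate gene planted inside that region is differentially expressed
    (higher in green), listed among the known genes and is a hub of the
    redness-anticorrelated coexpression module; known-list decoys are
    non-differential so the four-way intersection isolates the candidate.
    """
    if scale not in SCALES:
        raise ValidationError(f"unknown scale {scale!r}")
    p = SCALES[scale]
    n_bins, n_genes, reps, depth = p["n_bins"], p["n_genes"], p["reps"], p["depth"]
    resolution = 100_000
    outdir = Path(outdir)
    (outdir / "contacts").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    chroms = {"chr1": n_bins * resolution, "chr2": n_bins * resolution}
    conditions = ("red", "green")

    base1 = block_profile(n_bins, block=15, start_sign=-1)
    base2 = block_profile(n_bins, block=15, start_sign=1)
    # switching region on chr2: B in red, A in green
    sw_lo, sw_hi = n_bins // 2, n_bins // 2 + max(12, n_bins // 20)
    red2 = base2.copy()
    red2[sw_lo:sw_hi] = -1
    green2 = base2.copy()
    green2[sw_lo:sw_hi] = 1
    profiles = {
        "red": {"chr1": base1, "chr2": red2},
        "green": {"chr1": base1, "chr2": green2},
    }
    switching_region = ("chr2", sw_lo * resolution, sw_hi * resolution)

    boundaries = {c: list(range(12, n_bins - 6, 12)) for c in chroms}
    common_loops = [(20, 45), (70, 110), (n_bins - 60, n_bins - 20)]
    # red-only loops anchored at the candidate locus (locus-level evidence:
    # the red condition gains loops at the candidate gene)
    cand_mid_bin = (sw_lo + sw_hi) // 2
    extra_red = [(cand_mid_bin - 15, cand_mid_bin), (cand_mid_bin, cand_mid_bin + 18)]
    loops = {
        "red": {"chr1": common_loops, "chr2": common_loops + extra_red},
        "green": {"chr1": common_loops, "chr2": common_loops},
    }

    contact_files: dict[str, dict[str, list[str]]] = {}
    for cond in conditions:
        contact_files[cond] = {}
        for chrom in sorted(chroms):
            paths = []
            for rep in (1, 2):
                sub_seed = int(rng.integers(0, 2**31 - 1))
                cm, _ = make_contact_matrix(
                    n_bins=n_bins,
                    resolution=resolution,
                    alpha=1.0,
                    compartment_profile=profiles[cond][chrom],
                    compartment_strength=0.4,
                    tad_boundaries=boundaries[chrom],
                    tad_contrast=2.0,
                    loops=loops[cond][chrom],
                    loop_boost=5.0,
                    depth=depth,
                    seed=sub_seed,
                    chrom=chrom,
                )
                path = outdir / "contacts" / f"{cond}_{chrom}_rep{rep}.coo.tsv"
                iof.write_contact_matrix(cm, path, format="coo")
                paths.append(str(path.relative_to(outdir)))
            contact_files[cond][chrom] = paths

    # genes, biased toward A bins of the green profiles (A = gene-rich)
    weights = {
        chrom: np.where(profiles["green"][chrom] > 0, 4.0, 1.0) for chrom in chroms
    }
    candidate = Gene("cand0001", "chr2", cand_mid_bin * resolution + 10_000,
                     cand_mid_bin * resolution + 12_000, "+")
    genes = make_annotation(
        n_genes,
        chroms,
        bin_weights=weights,
        resolution=resolution,
        seed=int(rng.integers(0, 2**31 - 1)),
        fixed_genes=[candidate],
    )
    genes_sorted = sorted(genes, key=lambda g: (g.chrom, g.start))
    iof.write_genes(genes_sorted, outdir / "genes.bed")
    gene_ids = [g.gene_id for g in genes_sorted]

    window_bp = 3_000_000
    win_lo = max(0, switching_region[1] - window_bp)
    win_hi = min(chroms["chr2"], switching_region[2] + window_bp)
    in_window = [
        g.gene_id
        for g in genes_sorted
        if g.chrom == "chr2" and g.start < win_hi and g.end > win_lo
    ]
    out_window = [g for g in gene_ids if g not in set(in_window)]

    # module structure: candidate is a hub of the redness-anticorrelated
    # module; genes are assigned to modules in `ordered` order with the
    # candidate first so it lands in module 1 as a hub
    module_specs = [
        ModuleSpec(size=40, factor="anti_trait:redness", n_hubs=8),
        ModuleSpec(size=40, factor="random", n_hubs=5),
        ModuleSpec(size=40, factor="random", n_hubs=5),
    ]
    ordered = [candidate.gene_id] + [g for g in gene_ids if g != candidate.gene_id]
    module_members = set(ordered[: sum(m.size for m in module_specs)])

    # planted DE genes: candidate down in red at every stage; decoy DEGs
    # outside both the known list and the planted modules (module factors
    # already carry group structure, so clean decoys come from noise genes)
    de_spec: list[tuple[str, str, float]] = [
        (candidate.gene_id, stage, -2.0) for stage in ("S1", "S2", "S3")
    ]
    decoy_pool = [g for g in out_window
                  if g != candidate.gene_id and g not in module_members]
    de_up = [str(g) for g in rng.choice(decoy_pool, size=15, replace=False)]
    rest = [g for g in decoy_pool if g not in set(de_up)]
    de_down = [str(g) for g in rng.choice(rest, size=15, replace=False)]
    for g in de_up:
        de_spec.append((g, "S2", 2.0))
    for g in de_down:
        de_spec.append((g, "S2", -2.0))

    # known list: candidate + decoys that are neither differential nor in
    # trait-structured modules, some inside and some outside the window
    non_de = [g for g in gene_ids
              if g not in set(de_up) | set(de_down) | {candidate.gene_id}
              and g not in module_members]
    known_in = [g for g in in_window if g in set(non_de)][:3]
    known_out = [g for g in non_de if g not in set(in_window)][:4]
    known = sorted([candidate.gene_id] + known_in + known_out)
    iof.write_gene_list(known, outdir / "known_genes.txt")
    expr, expr_truth = make_expression(
        n_genes=n_genes,
        module_spec=module_specs,
        group_design=GroupDesign(reps=reps),
        de_spec=de_spec,
        noise_sd=0.3,
        seed=int(rng.integers(0, 2**31 - 1)),
        gene_ids=ordered,
    )
    iof.write_expression(expr, outdir / "expression.tsv")
    expr.metadata.to_csv(outdir / "samples.tsv", sep="\t", index=False)

    manifest = {
        "resolution": resolution,
        "chroms": chroms,
        "conditions": list(conditions),
        "contacts": contact_files,
        "genes": "genes.bed",
        "expression": "expression.tsv",
        "samples": "samples.tsv",
        "known_genes": "known_genes.txt",
        "seed": seed,
        "scale": scale,
    }
    with open(outdir / "study.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    truth = StudyTruth(
        chroms=chroms,
        resolution=resolution,
        conditions=conditions,
        profiles={c: {k: list(map(int, v)) for k, v in p.items()}
                  for c, p in profiles.items()},
        tad_boundaries=boundaries,
        loops={c: {k: [tuple(x) for x in v] for k, v in l.items()}
               for c, l in loops.items()},
        switching_region=switching_region,
        candidate_gene=candidate.gene_id,
        known_genes=known,
        expression=expr_truth,
        seed=seed,
    )
    with open(outdir / "truth.json", "w") as fh:
        fh.write(truth.to_json())
    return manifest, truth
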