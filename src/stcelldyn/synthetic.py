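"""Synthetic CosMx-like datasets with known ground truth.

Emulates an imaging-based spatial transcriptomics experiment on mouse
brain: a ~1,000-plex panel with negative-control probes, negative-binomial
(gamma-Poisson) per-cell counts, planted cell types with elevated marker
genes, a three-depth brain-region hierarchy with FOV structure, four
experimental groups (genotype AA/GG × treatment SAL/MOR),
treatment-responsive genes concentrated in chosen cell types, and
region-structured co-expression modules whose inter-regional correlation
can be rewired by treatment.

Counts for gene g in cell c are drawn NB with mean ``L_c · p_cg`` where
``L_c`` is a log-normal library size and ``p_cg`` the cell's expression
profile (gene baselines from a log-normal, markers multiplied by
``2**marker_log2fc`` in their type, module genes modulated by a
region-score × gene-loading term, treatment effects applied only in MOR
cells of the stated genotype).  Negative probes are Poisson with a rate a
small fraction of the mean real-probe rate, matching the low background of
imaging-based platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

GROUPS = ["AA_SAL", "AA_MOR", "GG_SAL", "GG_MOR"]

#: default region hierarchy: depth-3 meso-structure -> depth-5 -> depth-7 leaves
DEFAULT_REGION_TREE = {
    "CTX": {"Isocortex": ["MOp", "SSp"]},
    "CNU": {"STR": ["ACB", "CP"]},
    "IB": {"TH": ["PVT"], "HY": ["LHA"]},
    "MB": {"MBmot": ["VTA", "PAG"]},
}

#: identity assigned to each planted type, cycled when n_cell_types > 8.
#: Each entry: (identity name, genes seeded into the type's marker set so the
#: rule table in :mod:`stcelldyn.annotation` can recover the identity).
DEFAULT_TYPE_IDENTITIES = [
    ("Glutamatergic", ["Slc17a7"]),
    ("GABAergic", ["Slc32a1", "Gad1"]),
    ("Dopaminergic", ["Slc6a3", "Th", "Ddc"]),
    ("Cholinergic", ["Slc18a3", "Chat"]),
    ("Astrocytes", ["Gfap", "Slc1a3"]),
    ("Microglia", ["Cx3cr1", "C1qc"]),
    ("Oligodendrocytes", ["Plp1", "Olig1"]),
    ("Endothelial", ["Cldn5", "Flt1"]),
]


@dataclass
class PlantedDEG:
    """A treatment-responsive gene set.

    The log2 effect is applied only in MOR cells of ``genotype``; when
    ``cell_type`` is None the effect spans all types, otherwise that type
    only.  ``baseline_log2fc_in_type`` additionally elevates the genes'
    baseline in ``focus_type`` under both treatments, creating a
    transcriptionally hyper-responsive population for disproportionality
    recovery tests.
    """

    genotype: str = "AA"
    cell_type: int | None = None
    genes: list[str] = field(default_factory=list)
    log2fc: float = 1.5
    focus_type: int | None = 0
    baseline_log2fc_in_type: float = 2.0


@dataclass
class PlantedModule:
    """A region-structured co-expression module.

    Module genes share per-region scores ``s(r)``; gene g's expression at
    region r is multiplied by ``exp(loading_g · s(r))`` with gene loadings
    drawn N(0, 1).  Because module genes share a flat baseline, the
    inter-regional correlation over module genes approaches ``sign(s(r1)
    s(r2))``, giving strong, recoverable gene–gene co-expression across
    region × group samples.
    """

    genes: list[str] = field(default_factory=list)
    region_scores: dict[str, float] = field(default_factory=dict)
    scale: float = 1.0


@dataclass
class RewiredPair:
    """Flip the sign of ``module``'s region score at ``region_b`` in MOR
    cells, inverting the (region_a, region_b) module correlation under
    treatment."""

    region_a: str
    region_b: str
    module: int
    genotype: str | None = None  # None: both genotypes


@dataclass
class SimConfig:
    """Generator configuration; defaults define the standard study-scale
    fixture: 8 cell types × 200 cells per group, ~1,000-plex panel."""

    n_cells_per_group: int = 1600
    n_genes: int = 1000
    n_negative_probes: int = 20
    n_cell_types: int = 8
    markers_per_type: int = 40
    marker_log2fc: float = 2.0
    #: canonical rule genes are highly expressed in their type; baseline on
    #: the median-relative scale of the log-normal gene baselines
    rule_gene_base: float = 3.0
    #: markers are depleted in other types by this log2 factor
    marker_background_log2fc: float = 2.0
    libsize_mean: float = 500.0  # natural-scale median library size
    libsize_sd: float = 0.35  # sd of log library size
    nb_dispersion: float = 0.1  # var = mu + nb_dispersion * mu^2; 0 -> Poisson
    neg_probe_rate_frac: float = 0.02  # fraction of mean real-probe rate
    region_tree: dict = field(default_factory=lambda: dict(DEFAULT_REGION_TREE))
    n_fovs: int = 8
    region_affinity: float = 0.5  # share of a type's cells in its home region
    planted_deg: list[PlantedDEG] | None = None
    planted_modules: list[PlantedModule] | None = None
    n_planted_modules: int = 4
    module_genes_each: int = 30
    rewired_pairs: list[RewiredPair] | None = None
    area_mean: float = 100.0
    area_sd: float = 10.0
    seed: int = 0

    def leaf_regions(self) -> list[str]:
        leaves = []
        for d5 in self.region_tree.values():
            for ll in d5.values():
                leaves.extend(ll)
        return leaves

    def region_parents(self) -> dict[str, tuple[str, str]]:
        """leaf -> (depth-3, depth-5) labels."""
        out = {}
        for d3, d5map in self.region_tree.items():
            for d5, leaves in d5map.items():
                for leaf in leaves:
                    out[leaf] = (d3, d5)
        return out


@dataclass
class GroundTruth:
    cell_type_of_cell: np.ndarray  # int per cell
    type_identity: dict[int, str]  # planted type -> rule identity
    marker_genes: dict[int, list[str]]
    deg_truth: list[PlantedDEG]
    module_truth: dict[str, int]  # gene -> module index
    rewired_edges: list[tuple[str, str, int]]
    hub_truth: list[str] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "cell_type_of_cell": self.cell_type_of_cell.tolist(),
            "type_identity": {str(k): v for k, v in self.type_identity.items()},
            "marker_genes": {str(k): v for k, v in self.marker_genes.items()},
            "deg_truth": [
                {
                    "genotype": d.genotype,
                    "cell_type": d.cell_type,
                    "genes": d.genes,
                    "log2fc": d.log2fc,
                    "focus_type": d.focus_type,
                    "baseline_log2fc_in_type": d.baseline_log2fc_in_type,
                }
                for d in self.deg_truth
            ],
            "module_truth": self.module_truth,
            "rewired_edges": [list(e) for e in self.rewired_edges],
            "hub_truth": self.hub_truth,
        }


class Dataset:
    """In-memory dataset: sparse counts, per-cell table, gene table, truth."""

    def __init__(self, counts, genes: pd.DataFrame, cells: pd.DataFrame,
                 truth: GroundTruth, config: SimConfig):
        self.counts = sp.csr_matrix(counts)
        self.genes = genes
        self.cells = cells
        self.truth = truth
        self.config = config


def _validate(cfg: SimConfig) -> None:
    for name in ("n_cells_per_group", "n_genes", "n_negative_probes",
                 "n_cell_types", "markers_per_type", "n_fovs"):
        if getattr(cfg, name) <= 0:
            raise ValueError(f"{name} must be > 0")
    if not cfg.leaf_regions():
        raise ValueError("region tree is empty")
    if cfg.n_cell_types * cfg.markers_per_type > cfg.n_genes // 2:
        raise ValueError("marker sets exceed half the panel")


def _default_planted(cfg: SimConfig, gene_names: list[str],
                     rng: np.random.Generator):
    """Fill in default planted DEG sets, modules and rewiring."""
    leaves = cfg.leaf_regions()
    # genes not used as markers are eligible for DEG / module planting
    n_marker = cfg.n_cell_types * cfg.markers_per_type
    free = gene_names[n_marker:]
    deg = cfg.planted_deg
    if deg is None:
        deg = [PlantedDEG(genotype="AA", cell_type=None, genes=list(free[:12]),
                          log2fc=1.5, focus_type=0, baseline_log2fc_in_type=2.0)]
    mods = cfg.planted_modules
    if mods is None:
        mods = []
        off = 12
        # orthogonal region-score patterns so planted modules are distinct;
        # constant-magnitude ±1 (Hadamard) patterns when the region count
        # allows, so that even-order distortions of the measurement scale
        # are constant across regions and cannot couple modules
        k = min(cfg.n_planted_modules, len(leaves) - 1)
        n_leaves = len(leaves)
        had = 1 << (n_leaves - 1).bit_length()
        if had == n_leaves and k < n_leaves:
            from scipy.linalg import hadamard
            patterns = hadamard(n_leaves)[1:k + 1].astype(float)
        else:
            raw = rng.normal(size=(n_leaves, k))
            q, _ = np.linalg.qr(raw)
            patterns = (q * np.sqrt(n_leaves)).T
        for m in range(cfg.n_planted_modules):
            genes = list(free[off:off + cfg.module_genes_each])
            off += cfg.module_genes_each
            pat = patterns[m % k]
            scores = {r: float(pat[i]) for i, r in enumerate(leaves)}
            mods.append(PlantedModule(genes=genes, region_scores=scores))
    seen: set[str] = set()
    for m in mods:
        if seen & set(m.genes):
            raise ValueError("planted module gene sets overlap")
        seen |= set(m.genes)
    rew = cfg.rewired_pairs
    if rew is None and mods:
        rew = [RewiredPair(region_a=leaves[0], region_b=leaves[1], module=0)]
    return deg, mods, rew or []


def generate_dataset(config: SimConfig) -> Dataset:
    """Draw a full four-group dataset from the configured generative model.

    Returns a :class:`Dataset` with sparse counts (cells × genes, negative
    probes appended as flagged genes), a per-cell metadata table (x, y, fov,
    sample, genotype, treatment, region at depths 3/5/7, segmentation area)
    and the ground truth needed by recovery tests.
    """
    _validate(config)
    rng = np.random.default_rng(config.seed)
    leaves = config.leaf_regions()
    parents = config.region_parents()

    # ---- gene panel ------------------------------------------------------
    marker_genes: dict[int, list[str]] = {}
    type_identity: dict[int, str] = {}
    gene_names: list[str] = []
    for t in range(config.n_cell_types):
        ident, rule_genes = DEFAULT_TYPE_IDENTITIES[t % len(DEFAULT_TYPE_IDENTITIES)]
        if t >= len(DEFAULT_TYPE_IDENTITIES):
            # cycled identities reuse the rule but need fresh gene ids
            rule_genes = []
        type_identity[t] = ident
        names = list(rule_genes)
        k = 0
        while len(names) < config.markers_per_type:
            names.append(f"Mk{t:02d}_{k:02d}")
            k += 1
        marker_genes[t] = names[: config.markers_per_type]
        gene_names.extend(marker_genes[t])
    n_filler = config.n_genes - len(gene_names)
    if n_filler < 0:
        raise ValueError("markers exceed panel size")
    gene_names.extend(f"G{i:04d}" for i in range(n_filler))
    neg_names = [f"NegPrb{i:02d}" for i in range(config.n_negative_probes)]
    if set(neg_names) & set(gene_names):
        raise ValueError("marker sets overlap negative probes")

    deg_list, mod_list, rew_list = _default_planted(config, gene_names, rng)
    gene_index = {g: i for i, g in enumerate(gene_names)}

    # ---- baseline expression profile ------------------------------------
    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)
    module_truth: dict[str, int] = {}
    loadings = np.zeros(config.n_genes)
    med = float(np.median(base))
    for mi, mod in enumerate(mod_list):
        # antithetic ± loading pairs summing to zero: the linear modulation
        # (1 + loading*score) then conserves module mass exactly, so the
        # per-cell profile normalization cannot couple distinct modules
        mags = rng.uniform(0.25, 0.45, size=(len(mod.genes) + 1) // 2)
        for k, g in enumerate(mod.genes):
            gi = gene_index[g]
            base[gi] = med  # flat baseline within a module
            loadings[gi] = mags[k // 2] * (1.0 if k % 2 == 0 else -1.0)
            if k == len(mod.genes) - 1 and len(mod.genes) % 2 == 1:
                loadings[gi] = 0.0
            module_truth[g] = mi

    # canonical rule genes: high baseline expression in-panel
    rule_gene_names = {g for t in range(config.n_cell_types)
                       for g in marker_genes[t] if not g.startswith("Mk")}
    for g in rule_gene_names:
        base[gene_index[g]] = config.rule_gene_base

    # per-type profiles: markers elevated in their type, depleted elsewhere
    mult = 2.0 ** config.marker_log2fc
    bg = 2.0 ** (-config.marker_background_log2fc)
    type_profiles = np.tile(base, (config.n_cell_types, 1))
    all_marker_idx = {t: [gene_index[g] for g in marker_genes[t]]
                      for t in range(config.n_cell_types)}
    for t in range(config.n_cell_types):
        for s, idx in all_marker_idx.items():
            type_profiles[t, idx] = (type_profiles[t, idx] * mult if s == t
                                     else type_profiles[t, idx] * bg)

    # ---- cells -----------------------------------------------------------
    n_per = config.n_cells_per_group
    n_cells = n_per * len(GROUPS)
    cell_type = np.tile(
        np.repeat(np.arange(config.n_cell_types),
                  -(-n_per // config.n_cell_types))[:n_per], len(GROUPS))
    group = np.repeat(GROUPS, n_per)
    genotype = np.array([g.split("_")[0] for g in group])
    treatment = np.array([g.split("_")[1] for g in group])

    # region: each type has a home leaf region (cycled); affinity share there
    home = np.arange(config.n_cell_types) % len(leaves)
    p_other = (1.0 - config.region_affinity) / max(len(leaves) - 1, 1)
    region_idx = np.empty(n_cells, dtype=int)
    for t in range(config.n_cell_types):
        mask = cell_type == t
        probs = np.full(len(leaves), p_other)
        if len(leaves) > 1:
            probs[home[t]] = config.region_affinity
        else:
            probs[:] = 1.0
        probs /= probs.sum()
        region_idx[mask] = rng.choice(len(leaves), size=mask.sum(), p=probs)
    region_d7 = np.array(leaves)[region_idx]

    # FOVs: round-robin map FOV -> leaf region; cell's FOV uniform among its
    # region's FOVs
    fov_region = [leaves[i % len(leaves)] for i in range(config.n_fovs)]
    fovs_of_region = {r: [i for i, fr in enumerate(fov_region) if fr == r]
                      for r in leaves}
    fov = np.array([fovs_of_region[r][rng.integers(len(fovs_of_region[r]))]
                    if fovs_of_region[r] else rng.integers(config.n_fovs)
                    for r in region_d7])

    lib = rng.lognormal(mean=np.log(config.libsize_mean),
                        sigma=config.libsize_sd, size=n_cells)

    # ---- per-cell expected rates ----------------------------------------
    profile = type_profiles[cell_type]  # (cells, genes), copy via fancy index
    # module region structure
    for mi, mod in enumerate(mod_list):
        gidx = np.array([gene_index[g] for g in mod.genes])
        scores = np.array([mod.region_scores.get(r, 0.0) for r in leaves])
        s_cell = scores[region_idx].copy()
        for rw in rew_list:
            if rw.module != mi:
                continue
            flip = (region_d7 == rw.region_b) & (treatment == "MOR")
            if rw.genotype is not None:
                flip &= genotype == rw.genotype
            s_cell[flip] = -s_cell[flip]
        modmult = 1.0 + mod.scale * np.outer(s_cell, loadings[gidx])
        np.maximum(modmult, 0.05, out=modmult)
        profile[:, gidx] *= modmult
    # planted treatment effects
    for d in deg_list:
        if not d.genes:
            continue
        gidx = np.array([gene_index[g] for g in d.genes])
        hit = (genotype == d.genotype) & (treatment == "MOR")
        if d.cell_type is not None:
            hit &= cell_type == d.cell_type
        profile[np.ix_(hit, gidx)] *= 2.0 ** d.log2fc
        if d.focus_type is not None and d.baseline_log2fc_in_type:
            fmask = cell_type == d.focus_type
            profile[np.ix_(fmask, gidx)] *= 2.0 ** d.baseline_log2fc_in_type

    profile /= profile.sum(axis=1, keepdims=True)
    mu = profile * lib[:, None]

    # ---- sampling --------------------------------------------------------
    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    neg_rate = config.neg_probe_rate_frac * lib / config.n_genes
    neg = rng.poisson(np.tile(neg_rate[:, None],
                              (1, config.n_negative_probes)))
    full = np.hstack([counts, neg])

    # ---- metadata --------------------------------------------------------
    fov_x = {i: 1000.0 * (i % 3) for i in range(config.n_fovs)}
    fov_y = {i: 1000.0 * (i // 3) for i in range(config.n_fovs)}
    x = np.array([fov_x[f] for f in fov]) + rng.uniform(0, 1000, n_cells)
    y = np.array([fov_y[f] for f in fov]) + rng.uniform(0, 1000, n_cells)
    area = np.maximum(rng.normal(config.area_mean, config.area_sd, n_cells), 1.0)

    cells = pd.DataFrame({
        "cell_id": [f"c{i:06d}" for i in range(n_cells)],
        "x": x, "y": y, "fov": fov, "sample": group, "genotype": genotype,
        "treatment": treatment,
        "region_d3": [parents[r][0] for r in region_d7],
        "region_d5": [parents[r][1] for r in region_d7],
        "region_d7": region_d7,
        "area": area,
    }).set_index("cell_id")
    genes = pd.DataFrame({
        "gene": gene_names + neg_names,
        "is_negative_probe": [False] * config.n_genes
        + [True] * config.n_negative_probes,
    }).set_index("gene")

    truth = GroundTruth(
        cell_type_of_cell=cell_type,
        type_identity=type_identity,
        marker_genes=marker_genes,
        deg_truth=deg_list,
        module_truth=module_truth,
        rewired_edges=[(r.region_a, r.region_b, r.module) for r in rew_list],
    )
    return Dataset(sp.csr_matrix(full), genes, cells, truth, config)


def write_fixture(dataset: Dataset, out_dir: str | Path) -> dict:
    """Write the dataset as MTX + TSV + JSON; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out / "counts.mtx", sp.coo_matrix(dataset.counts))
    dataset.genes.to_csv(out / "genes.tsv", sep="\t")
    dataset.cells.to_csv(out / "cells.tsv", sep="\t")
    (out / "truth.json").write_text(json.dumps(dataset.truth.to_json()))
    manifest = {
        "files": ["counts.mtx", "genes.tsv", "cells.tsv", "truth.json"],
        "seed": dataset.config.seed,
        "n_cells": int(dataset.counts.shape[0]),
        "n_genes": int(dataset.counts.shape[1]),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_fixture(in_dir: str | Path):
    """Read back (counts csr, genes, cells) written by :func:`write_fixture`."""
    p = Path(in_dir)
    counts = sp.csr_matrix(scipy.io.mmread(p / "counts.mtx"))
    genes = pd.read_csv(p / "genes.tsv", sep="\t", index_col=0)
    cells = pd.read_csv(p / "cells.tsv", sep="\t", index_col=0)
    return counts, genes, cells
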