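"""Region-level co-expression: inter-regional correlation networks and
weighted co-expression module detection.

Modules are detected on a region × gene mean-expression matrix (rows are
region or region × group samples): biweight midcorrelation -> unsigned
adjacency |bicor|^power -> topological overlap matrix (Zhang–Horvath) ->
average-linkage hierarchical clustering on 1−TOM -> height-based dynamic
cut with a minimum module size -> module eigengenes (first PC, oriented to
correlate positively with the module mean) -> iterative merging of modules
whose eigengene dissimilarity falls below the merge cut.  Soft power is
chosen by the scale-free fit criterion (signed R² of the log-log degree
distribution regression).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
]


def _dense(X):
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, float)


# ---------------------------------------------------------------------------
# region-level matrices and inter-regional networks
# ---------------------------------------------------------------------------

def region_mean_matrix(X, cells: pd.DataFrame, region_col: str = "region_d7",
                       group: str | None = None, sample_n: int = 50000,
                       min_cells: int = 100, max_missing: int | None = None,
                       seed: int = 0,
                       gene_names=None) -> tuple[pd.DataFrame, pd.Series]:
    """Mean normalized expression per region (optionally within one
    experimental group), over a random subsample of cells.

    Rows with fewer than ``min_cells`` cells are dropped; when
    ``max_missing`` is set, rows with more than that many all-zero gene
    values are dropped as under-sampled.  Returns (region × gene matrix,
    per-row cell counts).
    """
    rng = np.random.default_rng(seed)
    X = _dense(X)
    mask = np.ones(len(cells), dtype=bool)
    if group is not None:
        mask &= (cells["sample"] == group).to_numpy()
    idx = np.flatnonzero(mask)
    if idx.size > sample_n:
        idx = np.sort(rng.choice(idx, size=sample_n, replace=False))
    regions = cells[region_col].to_numpy()[idx]
    rows, counts = {}, {}
    for r in np.unique(regions):
        sub = idx[regions == r]
        if sub.size < min_cells:
            continue
        prof = X[sub].mean(axis=0)
        if max_missing is not None and int((prof == 0).sum()) > max_missing:
            continue
        rows[r] = prof
        counts[r] = int(sub.size)
    if not rows:
        raise ValueError("no region survives the filters")
    cols = (list(gene_names) if gene_names is not None
            else [f"g{i}" for i in range(X.shape[1])])
    M = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return M.sort_index(), pd.Series(counts).sort_index()


def interregion_network(M: pd.DataFrame, r_min: float = 0.95):
    """Pearson correlation network over region gene profiles.

    Edges where r > ``r_min``; degree centrality = degree/(n−1).
    Constant-profile regions have undefined correlations and are dropped
    with a warning.  Returns (edge DataFrame, centrality Series, full r
    matrix).
    """
    if M.shape[0] < 3:
        raise ValueError("need >= 3 regions")
    sd = M.std(axis=1)
    if (sd == 0).any():
        warnings.warn(f"constant regions dropped: {list(M.index[sd == 0])}")
        M = M.loc[sd > 0]
    R = np.corrcoef(M.to_numpy())
    regions = list(M.index)
    n = len(regions)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if R[i, j] > r_min:
                edges.append({"region_a": regions[i], "region_b": regions[j],
                              "r": float(R[i, j])})
    edge_df = pd.DataFrame(edges, columns=["region_a", "region_b", "r"])
    deg = pd.Series(0, index=regions, dtype=float)
    for _, e in edge_df.iterrows():
        deg[e["region_a"]] += 1
        deg[e["region_b"]] += 1
    centrality = deg / max(n - 1, 1)
    return edge_df, centrality, pd.DataFrame(R, index=regions, columns=regions)


# ---------------------------------------------------------------------------
# biweight midcorrelation, adjacency, TOM
# ---------------------------------------------------------------------------

def bicor(X: np.ndarray, c: float = 9.0) -> np.ndarray:
    """Biweight midcorrelation matrix over columns of X (samples × genes).

    Uses the standard Tukey biweight: u = (x − median)/(c·MAD), weights
    (1 − u²)² for |u| < 1.  Columns with MAD 0 fall back to mean/SD
    (Pearson-style) weights of 1.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    W = np.empty_like(X)
    Z = np.empty_like(X)
    for j in range(m):
        if mad[j] == 0:
            # degenerate MAD: plain deviation from the mean, unit weights
            Z[:, j] = X[:, j] - X[:, j].mean()
            W[:, j] = 1.0
        else:
            u = (X[:, j] - med[j]) / (c * mad[j])
            w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
            Z[:, j] = (X[:, j] - med[j]) * w
            W[:, j] = w
    norm = np.sqrt((Z ** 2).sum(axis=0))
    norm[norm == 0] = 1.0
    Zn = Z / norm
    return np.clip(Zn.T @ Zn, -1.0, 1.0)


def tom_similarity(A: np.ndarray) -> np.ndarray:
    """Topological overlap matrix (Zhang–Horvath) of an adjacency A with
    zero diagonal: TOM_ij = (L_ij + a_ij)/(min(k_i, k_j) + 1 − a_ij),
    TOM_ii = 1."""
    A = np.asarray(A, dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A
    k = A.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A
    T = (L + A) / denom
    np.fill_diagonal(T, 1.0)
    return T


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R² of the log10 p(k) vs log10 k regression over binned
    connectivity; positive when the slope is negative (power-law-like)."""
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if k.size < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        m = which == b
        if m.sum() == 0:
            continue
        xs.append(np.log10(k[m].mean()))
        ys.append(np.log10(m.mean()))
    if len(xs) < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(xs, ys)
    return float(-np.sign(slope) * r ** 2)


def pick_soft_power(M: pd.DataFrame, powers=range(1, 21),
                    r2_min: float = 0.8, default: int = 8):
    """Lowest power whose unsigned |bicor|^power network satisfies the
    scale-free criterion (signed R² > ``r2_min``); falls back to
    ``default`` with a warning when none qualifies.  Returns (power,
    per-power fit table)."""
    X = M.to_numpy()
    if X.shape[0] < 8:
        warnings.warn("fewer than 8 samples: soft-power fit is unstable")
    C = np.abs(bicor(X))
    np.fill_diagonal(C, 0.0)
    rows = []
    chosen = None
    for p in powers:
        A = C ** p
        k = A.sum(axis=1)
        r2 = scale_free_fit(k)
        rows.append({"power": p, "signed_r2": r2, "mean_k": float(k.mean())})
        if chosen is None and r2 > r2_min:
            chosen = p
    if chosen is None:
        warnings.warn(f"no power reached signed R² > {r2_min}; using {default}")
        chosen = default
    return chosen, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

@dataclass
class ModuleSet:
    assignment: pd.Series  # gene -> color label ('grey' = unassigned)
    eigengenes: pd.DataFrame  # samples × modules, unit-norm columns
    soft_power: int = 8
    linkage_: np.ndarray = None
    merge_history: list = field(default_factory=list)

    def genes_of(self, module: str) -> list[str]:
        return list(self.assignment.index[self.assignment == module])

    @property
    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.columns]


def _eigengene(X: np.ndarray) -> np.ndarray:
    """First PC of standardized gene profiles (unit-norm sample scores),
    sign-oriented to correlate positively with the module mean."""
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    e = U[:, 0]
    mean_prof = Z.mean(axis=1)
    if np.corrcoef(e, mean_prof)[0, 1] < 0:
        e = -e
    return e


def detect_modules(M: pd.DataFrame, power: int = 8, min_size: int = 20,
                   deep_split: int = 3, merge_cut: float = 0.10) -> ModuleSet:
    """WGCNA-style module detection on a samples × genes matrix.

    Adjacency |bicor|^power -> TOM -> average-linkage clustering on 1−TOM
    -> height cut (the cut quantile tightens with ``deep_split``: deeper
    splits produce more, smaller branches) -> branches below ``min_size``
    to 'grey' -> eigengene computation -> iterative merge of modules with
    eigengene dissimilarity < ``merge_cut``.
    """
    genes = list(M.columns)
    X = M.to_numpy(dtype=float)
    good = X.std(axis=0) > 0
    if (~good).any():
        warnings.warn(f"{int((~good).sum())} constant genes set to grey")
    Xg = X[:, good]
    gnames = [g for g, ok in zip(genes, good) if ok]
    if len(gnames) < min_size:
        warnings.warn("too few clusterable genes: single grey module")
        assign = pd.Series("grey", index=genes)
        return ModuleSet(assignment=assign,
                         eigengenes=pd.DataFrame(index=M.index),
                         soft_power=power)
    A = np.abs(bicor(Xg)) ** power
    T = tom_similarity(A)
    D = 1.0 - T
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    # deep_split in 0..4 maps to a cut at a tightening height quantile
    q = {0: 0.99, 1: 0.98, 2: 0.97, 3: 0.96, 4: 0.95}.get(int(deep_split), 0.96)
    cut = q * Z[:, 2].max()
    raw = fcluster(Z, t=cut, criterion="distance")
    labels = np.full(len(gnames), "grey", dtype=object)
    next_color = 0
    # stable module naming: largest branch first
    order = sorted(np.unique(raw),
                   key=lambda c: (-(raw == c).sum(), c))
    for c in order:
        m = raw == c
        if m.sum() >= min_size:
            color = (MODULE_COLORS[next_color]
                     if next_color < len(MODULE_COLORS)
                     else f"module{next_color}")
            labels[m] = color
            next_color += 1
    assign = pd.Series("grey", index=genes, dtype=object)
    assign.loc[gnames] = labels
    # eigengenes + merging
    history = []
    while True:
        mods = sorted(set(assign) - {"grey"})
        if not mods:
            break
        E = {m: _eigengene(M[assign.index[assign == m]].to_numpy())
             for m in mods}
        if len(mods) < 2:
            break
        best = None
        for i in range(len(mods)):
            for j in range(i + 1, len(mods)):
                d = 1.0 - np.corrcoef(E[mods[i]], E[mods[j]])[0, 1]
                if d < merge_cut and (best is None or d < best[0]):
                    best = (d, mods[i], mods[j])
        if best is None:
            break
        _, a, b = best
        assign[assign == b] = a
        history.append((b, a))
    mods = sorted(set(assign) - {"grey"})
    eig = pd.DataFrame(
        {m: _eigengene(M[assign.index[assign == m]].to_numpy()) for m in mods},
        index=M.index)
    return ModuleSet(assignment=assign, eigengenes=eig, soft_power=power,
                     linkage_=Z, merge_history=history)


# ---------------------------------------------------------------------------
# module-trait correlation, Fisher enrichment, prioritization
# ---------------------------------------------------------------------------

def module_trait(modules: ModuleSet, traits: pd.DataFrame):
    """Pearson r and two-sided p (t approximation) between module
    eigengenes and binary/continuous trait columns.  Constant traits give
    NaN."""
    E = modules.eigengenes
    r = pd.DataFrame(index=E.columns, columns=traits.columns, dtype=float)
    p = r.copy()
    n = len(E)
    for m in E.columns:
        for t in traits.columns:
            x, y = E[m].to_numpy(), traits[t].to_numpy(dtype=float)
            if y.std() == 0 or x.std() == 0:
                r.loc[m, t] = np.nan
                p.loc[m, t] = np.nan
                continue
            rv = float(np.corrcoef(x, y)[0, 1])
            r.loc[m, t] = rv
            if abs(rv) >= 1.0:
                p.loc[m, t] = 0.0
            else:
                tt = rv * np.sqrt((n - 2) / (1 - rv ** 2))
                p.loc[m, t] = 2 * stats.t.sf(abs(tt), n - 2)
    return r, p


def fisher_module_enrichment(modules: ModuleSet, effect_sets: dict,
                             universe, cap: float = 10.0) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of each effect gene set in each
    module, as min(−log10 p, cap), plus a within-effect [0, 1]
    normalization (column *_norm).  Empty sets score 0."""
    universe = set(universe)
    mods = sorted(set(modules.assignment) - {"grey"})
    out = pd.DataFrame(index=mods, columns=list(effect_sets), dtype=float)
    for eff, genes in effect_sets.items():
        s = set(genes) & universe
        for m in mods:
            mg = set(modules.genes_of(m)) & universe
            if not s:
                out.loc[m, eff] = 0.0
                continue
            a = len(mg & s)
            b = len(mg - s)
            c = len(s - mg)
            d = len(universe - mg - s)
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            out.loc[m, eff] = min(-np.log10(max(p, 1e-300)), cap)
    norm = out.copy()
    for eff in out.columns:
        mx = out[eff].max()
        norm[eff] = out[eff] / mx if mx > 0 else 0.0
    norm.columns = [f"{c}_norm" for c in norm.columns]
    return pd.concat([out, norm], axis=1)


def prioritize_modules(E: pd.DataFrame, aa_col: str = "DEG_TREAT_AA",
                       gg_col: str = "DEG_TREAT_GG", top_k: int = 3) -> dict:
    """Three rankings over the capped enrichment matrix:
    (a) |AA-treatment − GG-treatment| enrichment difference, (b) the
    per-effect maxima, (c) stable deduplicated union of the top_k of every
    metric.  Ties resolve by module label order."""
    value_cols = [c for c in E.columns if not c.endswith("_norm")]
    diff = (E[aa_col] - E[gg_col]).abs()
    rank_a = list(diff.sort_values(ascending=False,
                                   kind="stable").index)
    rank_a = sorted(rank_a, key=lambda m: (-diff[m], str(m)))
    rank_b = {eff: sorted(E.index, key=lambda m: (-E.loc[m, eff], str(m)))
              for eff in value_cols}
    union = []
    for m in rank_a[:top_k]:
        if m not in union:
            union.append(m)
    for eff in value_cols:
        for m in rank_b[eff][:top_k]:
            if m not in union:
                union.append(m)
    return {"by_genotype_difference": rank_a, "by_effect": rank_b,
            "union_top": union}
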