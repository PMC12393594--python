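"""Differential expression, disproportionality scoring and composition
dynamics.

All two-group tests are Wilcoxon rank-sum on normalized expression with
Benjamini–Hochberg adjustment; fold changes are log2 of the ratio of group
means with a pseudocount of 1/scale_factor.  The disproportionality
statistic flags transcriptionally hyper-responsive cell types: the mean
normalized expression of treatment DEGs per type, z-scored across types,
gated at the two-sided 90% normal quantile (|z| > 1.6449) together with a
mean |log2FC| > 1 requirement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: two-sided alpha = 0.10 standard-normal quantile, reported rounded to 1.64
Z_CRIT_90 = float(stats.norm.ppf(1 - 0.10 / 2))


def _dense(X):
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, float)


def de_test(Xa, Xb, gene_names, min_pct: float = 0.25,
            logfc_min: float = 0.1, upregulated_only: bool = True,
            scale_factor: float = 10000.0, comparison: str = "",
            return_all: bool = False) -> pd.DataFrame:
    """Wilcoxon rank-sum differential expression between two cell groups.

    Genes detected in >= ``min_pct`` of either group are tested; P values
    are BH-adjusted across tested genes; log2FC = log2((mean_a + eps) /
    (mean_b + eps)) with eps = 1/scale_factor.  Rows obey |log2FC| >=
    ``logfc_min`` (log2FC > 0 only when ``upregulated_only``) unless
    ``return_all``.
    """
    Xa, Xb = _dense(Xa), _dense(Xb)
    if Xa.shape[0] < 3 or Xb.shape[0] < 3:
        raise ValueError("groups must have >= 3 cells")
    gene_names = np.asarray(list(gene_names))
    pct_a = (Xa > 0).mean(axis=0)
    pct_b = (Xb > 0).mean(axis=0)
    tested = (pct_a >= min_pct) | (pct_b >= min_pct)
    if not tested.any():
        return pd.DataFrame(columns=["comparison", "gene", "log2FC", "p_value",
                                     "p_adj", "pct_in", "pct_out", "q_diff"])
    A, B = Xa[:, tested], Xb[:, tested]
    # exact null for tiny tie-free samples, tie-corrected normal otherwise
    method = "auto" if max(A.shape[0], B.shape[0]) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(A, B, alternative="two-sided", axis=0,
                             method=method)
    p = np.asarray(res.pvalue)
    # constant genes (all ties) yield nan under the normal approximation
    p = np.where(np.isnan(p), 1.0, p)
    p_adj = multipletests(p, method="fdr_bh")[1]
    # fold change on the de-logged expression scale (exp(x) - 1 undoes the
    # log1p normalization), with a pseudocount of 1/scale_factor
    eps = 1.0 / scale_factor
    ma = np.expm1(A).mean(axis=0)
    mb = np.expm1(B).mean(axis=0)
    lfc = np.log2((ma + eps) / (mb + eps))
    tab = pd.DataFrame({
        "comparison": comparison,
        "gene": gene_names[tested],
        "log2FC": lfc,
        "p_value": p,
        "p_adj": p_adj,
        "pct_in": pct_a[tested],
        "pct_out": pct_b[tested],
    })
    tab["q_diff"] = tab["pct_in"] - tab["pct_out"]
    if not return_all:
        keep = np.abs(tab["log2FC"]) >= logfc_min
        if upregulated_only:
            keep &= tab["log2FC"] > 0
        tab = tab[keep]
    return tab.reset_index(drop=True)


def interregional_deg(X, cells: pd.DataFrame, gene_names,
                      region_col: str = "region_d5", n_sub: int = 500,
                      p_adj_max: float = 0.01, lfc_min: float = 1.5,
                      seed: int = 0):
    """Per-region MOR-vs-SAL tests within each genotype on subsampled
    cells; returns (tables dict keyed (genotype, region), region-specific
    gene sets, full per-region passing sets for Venn-style output)."""
    rng = np.random.default_rng(seed)
    X = _dense(X)
    tables: dict[tuple, pd.DataFrame] = {}
    passing: dict[tuple, set] = {}
    for geno in sorted(cells["genotype"].unique()):
        for region in sorted(cells[region_col].unique()):
            sel = {}
            skip = False
            for trt in ("MOR", "SAL"):
                m = ((cells["genotype"] == geno)
                     & (cells[region_col] == region)
                     & (cells["treatment"] == trt)).to_numpy()
                idx = np.flatnonzero(m)
                if idx.size < 3:
                    warnings.warn(f"{region} lacks {trt} cells in {geno}; skipped")
                    skip = True
                    break
                if idx.size > n_sub:
                    idx = rng.choice(idx, size=n_sub, replace=False)
                sel[trt] = idx
            if skip:
                continue
            tab = de_test(X[sel["MOR"]], X[sel["SAL"]], gene_names,
                          min_pct=0.0, logfc_min=0.0, upregulated_only=False,
                          comparison=f"{geno}:{region}:MOR_vs_SAL",
                          return_all=True)
            tables[(geno, region)] = tab
            hit = tab[(tab["p_adj"] < p_adj_max)
                      & (tab["log2FC"].abs() > lfc_min)]
            passing[(geno, region)] = set(hit["gene"])
    specific: dict[tuple, set] = {}
    for (geno, region), genes in passing.items():
        others = set().union(*(g for k, g in passing.items()
                               if k[0] == geno and k != (geno, region)),
                             set())
        specific[(geno, region)] = genes - others
    return tables, specific, passing


def deg_ratio_z(counts_up: dict, counts_down: dict, counts_tested: dict) -> pd.Series:
    """z-scored DEG burden per cell type: (n_up + n_down)/n_tested,
    standardized (population sd) across types."""
    types = sorted(counts_tested)
    ratio = np.array([
        (counts_up.get(t, 0) + counts_down.get(t, 0)) / max(counts_tested[t], 1)
        for t in types], dtype=float)
    sd = ratio.std()
    z = np.zeros_like(ratio) if sd == 0 else (ratio - ratio.mean()) / sd
    return pd.Series(z, index=types, name="deg_ratio_z")


@dataclass
class DisproportionalityResult:
    cell_type: object
    composite_score: float
    z: float
    mean_abs_log2fc: float
    valid_deg_fraction: float
    flagged: bool


def disproportionality(X, labels, gene_names, deg: pd.DataFrame,
                       z_crit: float = Z_CRIT_90, min_valid_frac: float = 0.25,
                       lfc_gate: float = 1.0,
                       weighted: bool = False) -> list[DisproportionalityResult]:
    """Composite DEG-expression score per cell type, z-scored across types.

    For each type the valid DEGs are those with nonzero expression in the
    type; types whose valid fraction is below ``min_valid_frac`` are
    excluded.  The composite is the mean over valid DEGs of the gene's mean
    normalized expression (optionally weighted by |log2FC|).  A type is
    flagged iff |z| > ``z_crit`` and its mean |log2FC| over valid DEGs
    exceeds ``lfc_gate``.
    """
    X = _dense(X)
    labels = np.asarray(labels)
    gene_names = list(gene_names)
    col = {g: i for i, g in enumerate(gene_names)}
    deg = deg[deg["gene"].isin(col)]
    if deg.empty:
        raise ValueError("no DEGs present in the matrix")
    gidx = np.array([col[g] for g in deg["gene"]])
    w = np.abs(deg["log2FC"].to_numpy())
    rows = []
    for t in np.unique(labels):
        sub = X[labels == t][:, gidx]
        gene_mean = sub.mean(axis=0)
        valid = gene_mean > 0
        frac = float(valid.mean())
        if frac < min_valid_frac:
            continue
        if weighted:
            comp = float(np.average(gene_mean[valid], weights=w[valid]))
        else:
            comp = float(gene_mean[valid].mean())
        rows.append((t, comp, frac, float(w[valid].mean())))
    if len(rows) < 3:
        raise ValueError("fewer than 3 included types: z undefined")
    comps = np.array([r[1] for r in rows])
    sd = comps.std()  # population convention
    degenerate = sd <= 1e-12 * max(1.0, float(np.abs(comps).max()))
    z = np.zeros_like(comps) if degenerate else (comps - comps.mean()) / sd
    out = []
    for (t, comp, frac, mlfc), zi in zip(rows, z):
        out.append(DisproportionalityResult(
            cell_type=t, composite_score=comp, z=float(zi),
            mean_abs_log2fc=mlfc, valid_deg_fraction=frac,
            flagged=bool(abs(zi) > z_crit and mlfc > lfc_gate)))
    return out


def gini(proportions) -> float:
    """Gini coefficient of a proportion vector (0 = perfectly even)."""
    x = np.sort(np.asarray(proportions, dtype=float))
    n = x.size
    if n == 0 or x.sum() == 0:
        return 0.0
    cum = np.cumsum(x)
    return float((n + 1 - 2 * (cum / cum[-1]).sum()) / n)


def shannon(counts) -> float:
    """Shannon diversity H = -sum p ln p over a count/proportion vector."""
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        return 0.0
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


@dataclass
class CompositionDynamics:
    table: pd.DataFrame  # long format: genotype, region, cell_type, ...
    shannon_by_type: pd.DataFrame
    gini_by_region: pd.DataFrame
    clip_range: tuple = (5.0, 95.0)


def composition_dynamics(cells: pd.DataFrame, labels,
                         region_col: str = "region_d7", min_n: int = 50,
                         clip: tuple = (5.0, 95.0)) -> CompositionDynamics:
    """Morphine-induced compositional change per (region, cell type,
    genotype).

    Only (cell type, region) pairs observed in all four groups and with
    >= ``min_n`` cells per group enter; pct_change = 100·(n_MOR −
    n_SAL)/n_SAL; the display normalization is a symmetric log
    (sign(x)·log1p(|x|/100)) followed by min–max scaling to [−1, 1];
    circle_size = log1p(n_SAL) clipped to the [clip] percentile range.
    Shannon H of each type's regional distribution is computed per
    treatment state; Gini of cell-type proportions per region.
    """
    labels = np.asarray(labels)
    df = cells.copy()
    df["cell_type"] = labels
    counts = (df.groupby(["genotype", "treatment", region_col, "cell_type"],
                         observed=True).size().rename("n").reset_index())
    piv = counts.pivot_table(index=[region_col, "cell_type"],
                             columns=["genotype", "treatment"], values="n",
                             fill_value=0)
    groups = [("AA", "SAL"), ("AA", "MOR"), ("GG", "SAL"), ("GG", "MOR")]
    present = piv[(piv[[g for g in groups if g in piv.columns]] >= min_n)
                  .all(axis=1)] if all(g in piv.columns for g in groups) else piv.iloc[:0]
    rows = []
    for (region, ctype), row in present.iterrows():
        for geno in ("AA", "GG"):
            n_sal, n_mor = row[(geno, "SAL")], row[(geno, "MOR")]
            if n_sal == 0:
                warnings.warn(f"{region}/{ctype}: zero SAL count, excluded")
                continue
            pct = 100.0 * (n_mor - n_sal) / n_sal
            rows.append({"genotype": geno, "region": region,
                         "cell_type": ctype, "n_SAL": int(n_sal),
                         "n_MOR": int(n_mor), "pct_change": pct})
    tab = pd.DataFrame(rows)
    if len(tab):
        symlog = np.sign(tab["pct_change"]) * np.log1p(tab["pct_change"].abs() / 100.0)
        lo, hi = symlog.min(), symlog.max()
        if hi > lo:
            tab["normalized_change"] = 2 * (symlog - lo) / (hi - lo) - 1
        else:
            tab["normalized_change"] = 0.0
        size = np.log1p(tab["n_SAL"].astype(float))
        p_lo, p_hi = np.percentile(size, clip[0]), np.percentile(size, clip[1])
        tab["circle_size"] = size.clip(p_lo, p_hi)
    # Shannon per type: distribution over regions, per treatment state
    sh_rows = []
    for trt in sorted(df["treatment"].unique()):
        sub = df[df["treatment"] == trt]
        for t in np.unique(labels):
            dist = sub[sub["cell_type"] == t][region_col].value_counts()
            sh_rows.append({"treatment": trt, "cell_type": t,
                            "shannon_H": shannon(dist.to_numpy())})
    # Gini per region over cell-type proportions
    gi_rows = []
    for region in sorted(df[region_col].unique()):
        dist = df[df[region_col] == region]["cell_type"].value_counts()
        gi_rows.append({"region": region, "gini": gini(dist.to_numpy())})
    return CompositionDynamics(table=tab,
                               shannon_by_type=pd.DataFrame(sh_rows),
                               gini_by_region=pd.DataFrame(gi_rows),
                               clip_range=clip)
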