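"""Gene-set enrichment: per-cell weighted scores and regional
over-representation with a genotype bias metric.

The per-cell score for term T is a weighted mean difference over
gene-standardized expression: score(c, T) = sum_{g in T∩DEG} w_g z_cg /
sum w_g − mean_{g in DEG} z_cg with w_g = |log2FC_g|.  It is a
deterministic alternative to a running-sum GSEA statistic, isolated in one
function so a KS-style variant can be substituted.  Regional enrichment is
a hypergeometric over-representation test with BH adjustment; the
composite metric −log10(q)·mean(log2FC of hit genes) is differenced
between genotypes to give the AA−GG bias.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests


def _dense(X):
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X, float)


def percell_enrichment(X, gene_names, deg: pd.DataFrame, sets: dict,
                       upper_pct: float = 90.0, lower_pct: float = 10.0):
    """Per-cell weighted enrichment scores and percentile verdicts.

    Returns (scores DataFrame cells × terms, verdicts DataFrame with
    'enriched'/'depleted'/'neutral').  Terms with no DEG overlap are
    skipped with a warning.
    """
    X = _dense(X)
    gene_names = list(gene_names)
    col = {g: i for i, g in enumerate(gene_names)}
    deg = deg[deg["gene"].isin(col)]
    if deg.empty:
        raise ValueError("DEG table shares no genes with the matrix")
    didx = np.array([col[g] for g in deg["gene"]])
    w_all = pd.Series(np.abs(deg["log2FC"].to_numpy()),
                      index=deg["gene"].to_numpy())
    sub = X[:, didx]
    mu, sd = sub.mean(axis=0), sub.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (sub - mu) / sd  # cells × DEGs, gene-standardized
    baseline = Z.mean(axis=1)
    pos = {g: j for j, g in enumerate(deg["gene"].to_numpy())}
    scores = {}
    for term, genes in sets.items():
        hit = [g for g in genes if g in pos]
        if not hit:
            warnings.warn(f"term {term!r} has no DEG overlap; skipped")
            continue
        w = w_all[hit].to_numpy()
        if w.sum() == 0:
            w = np.ones_like(w)
        cols = [pos[g] for g in hit]
        scores[term] = Z[:, cols] @ (w / w.sum()) - baseline
    score_df = pd.DataFrame(scores)
    verdicts = pd.DataFrame(index=score_df.index, columns=score_df.columns,
                            data="neutral")
    for term in score_df.columns:
        v = score_df[term]
        up = np.percentile(v, upper_pct)
        lo = np.percentile(v, lower_pct)
        verdicts.loc[v > up, term] = "enriched"
        verdicts.loc[v < lo, term] = "depleted"
    return score_df, verdicts


def hypergeom_test(n_hits: int, set_size: int, deg_size: int,
                   universe: int) -> float:
    """One-sided over-representation P = P(X >= n_hits) for X ~
    Hypergeom(universe, set_size, deg_size)."""
    return float(stats.hypergeom.sf(n_hits - 1, universe, set_size, deg_size))


def region_enrichment(deg_by_region: dict, sets: dict, background: dict,
                      top_k: int = 20) -> pd.DataFrame:
    """Hypergeometric over-representation per (region, genotype, term)
    with the AA−GG composite bias.

    ``deg_by_region``: (genotype, region) -> DEG table; ``background``:
    (genotype, region) -> list of all tested genes.  The composite is
    −log10(q_adj)·mean(log2FC of hit genes); rows are ranked by composite
    within each (genotype, region) and the bias column gives
    composite_AA − composite_GG for matching (region, term).
    """
    rows = []
    for (geno, region), deg in deg_by_region.items():
        bg = set(background[(geno, region)])
        if not bg:
            raise ValueError("empty background")
        dg = set(deg["gene"]) & bg
        lfc = deg.set_index("gene")["log2FC"]
        term_rows = []
        for term, genes in sets.items():
            s = set(genes) & bg
            hits = sorted(s & dg)
            if not hits:
                continue
            p = hypergeom_test(len(hits), len(s), len(dg), len(bg))
            term_rows.append({"genotype": geno, "region": region,
                              "term": term, "n_hits": len(hits),
                              "set_size": len(s), "p": p,
                              "mean_log2fc": float(lfc[hits].mean())})
        if not term_rows:
            continue
        sub = pd.DataFrame(term_rows)
        sub["q_adj"] = multipletests(sub["p"], method="fdr_bh")[1]
        sub["composite"] = (-np.log10(np.maximum(sub["q_adj"], 1e-300))
                            * sub["mean_log2fc"])
        rows.append(sub)
    if not rows:
        return pd.DataFrame(columns=["genotype", "region", "term", "n_hits",
                                     "set_size", "p", "mean_log2fc", "q_adj",
                                     "composite", "bias", "rank"])
    tab = pd.concat(rows, ignore_index=True)
    comp = tab.pivot_table(index=["region", "term"], columns="genotype",
                           values="composite", fill_value=0.0)
    bias = (comp.get("AA", 0.0) - comp.get("GG", 0.0)).rename("bias")
    tab = tab.merge(bias.reset_index(), on=["region", "term"], how="left")
    tab["rank"] = tab.groupby(["genotype", "region"])["composite"] \
        .rank(ascending=False, method="first")
    return tab[tab["rank"] <= top_k].reset_index(drop=True)


def slim_rollup(term_table: pd.DataFrame, parent_map: pd.DataFrame,
                top_n: int = 60) -> pd.DataFrame:
    """Aggregate enriched terms to slim parent categories.

    Terms are ranked by (frequency across region/module/group
    combinations, then minimal FDR), the top ``top_n`` kept, and every
    parent category attached (multiple parents allowed; unmapped terms get
    parent 'unassigned').  ``parent_map`` columns: term, parent.
    """
    if "q_adj" not in term_table.columns:
        raise ValueError("term_table must carry a q_adj column")
    combo_cols = [c for c in ("genotype", "region", "module", "group")
                  if c in term_table.columns]
    stats_ = term_table.groupby("term").agg(
        frequency=("term", "size") if not combo_cols else (combo_cols[0], "size"),
        min_fdr=("q_adj", "min")).reset_index()
    if combo_cols:
        freq = (term_table.drop_duplicates(subset=["term"] + combo_cols)
                .groupby("term").size().rename("frequency"))
        stats_ = stats_.drop(columns="frequency").merge(freq.reset_index(),
                                                        on="term")
    stats_ = stats_.sort_values(["frequency", "min_fdr", "term"],
                                ascending=[False, True, True]).head(top_n)
    pm = parent_map.groupby(parent_map.columns[0])[parent_map.columns[1]] \
        .apply(list).to_dict()
    rows = []
    for _, r in stats_.iterrows():
        parents = pm.get(r["term"], ["unassigned"])
        for p in parents:
            rows.append({"term": r["term"], "parent": p,
                         "frequency": int(r["frequency"]),
                         "min_fdr": float(r["min_fdr"])})
    return pd.DataFrame(rows)
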