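"""Probe-, cell- and FOV-level quality control and normalization.

Implements the standard QC cascade for imaging-based spatial
transcriptomics: negative-control probes screened by iterative Grubbs'
outlier test, target probes compared against the negative-probe background
(median cut plus a one-sided Poisson exceedance test), per-cell filters
(minimum transcripts, negative-probe fraction, count-to-gene ratio,
segmentation-area outliers), two-stage FOV filters, log-normalization to a
fixed per-cell total, and a percentile-based secondary cell filter applied
before clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy import stats


@dataclass
class QCReport:
    """Bookkeeping for a QC run; counts are conserved per axis
    (input = retained + removed)."""

    n_input_cells: int = 0
    n_retained_cells: int = 0
    removed: dict = field(default_factory=dict)
    retained_genes: list = field(default_factory=list)
    retained_fovs: list = field(default_factory=list)
    fov_scale: float = 1.0
    percentile_convention: str = "linear (type 7)"

    @property
    def pass_rate(self) -> float:
        if self.n_input_cells == 0:
            return float("nan")
        return 100.0 * self.n_retained_cells / self.n_input_cells


def grubbs_outliers(values, alpha: float = 0.01) -> np.ndarray:
    """Iterative two-sided Grubbs' test; returns indices of removed values.

    At each step the single most extreme value is tested with
    G = max|x - mean| / sd against the critical value
    ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with
    t = t_{alpha/(2n), n-2}; removal repeats until no value is significant.
    Fewer than 3 values cannot be tested (empty result with a warning).
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    removed: list[int] = []
    active = list(range(values.size))
    if values.size < 3:
        warnings.warn("Grubbs test undefined for n < 3; nothing removed")
        return np.array([], dtype=int)
    while len(active) >= 3:
        x = values[active]
        sd = x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - x.mean())
        i = int(np.argmax(dev))
        g = dev[i] / sd
        n = len(active)
        t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))
        if g > g_crit:
            removed.append(active.pop(i))
        else:
            break
    return np.array(sorted(removed), dtype=int)


def filter_probes(counts, is_negative: np.ndarray, alpha: float = 0.01,
                  detection_p_max: float = 0.01,
                  background_percentile: float = 50.0,
                  report: QCReport | None = None) -> np.ndarray:
    """Probe-level QC; returns indices of retained genes (targets + clean
    negatives).

    (a) negative probes whose total counts are Grubbs outliers (P < alpha)
    are dropped from the background model; (b) targets with total counts
    below the ``background_percentile`` of the retained-negative totals are
    removed; (c) targets whose one-sided Poisson exceedance test against
    the mean retained-negative total gives P > ``detection_p_max`` are
    removed.
    """
    counts = sp.csr_matrix(counts)
    is_negative = np.asarray(is_negative, dtype=bool)
    if not is_negative.any():
        raise ValueError("no negative probes: background undefined")
    totals = np.asarray(counts.sum(axis=0)).ravel()
    neg_idx = np.flatnonzero(is_negative)
    bad_neg = neg_idx[grubbs_outliers(totals[neg_idx], alpha=alpha)]
    clean_neg = np.setdiff1d(neg_idx, bad_neg)
    if clean_neg.size == 0:
        raise ValueError("all negative probes flagged as outliers")
    bg = totals[clean_neg]
    cut = np.percentile(bg, background_percentile)
    lam = bg.mean()
    tgt_idx = np.flatnonzero(~is_negative)
    keep = []
    for j in tgt_idx:
        if totals[j] < cut:
            continue
        # P(Pois(lam) >= total); high totals -> small p -> confident detection
        p = stats.poisson.sf(totals[j] - 1, lam) if lam > 0 else 0.0
        if p > detection_p_max:
            continue
        keep.append(j)
    retained = np.array(sorted(list(clean_neg) + keep), dtype=int)
    if report is not None:
        report.removed["probes_grubbs_negative"] = int(bad_neg.size)
        report.removed["targets_background"] = int(tgt_idx.size - len(keep))
        report.retained_genes = retained.tolist()
    return retained


def filter_cells(counts, areas, min_transcripts: int = 5,
                 max_neg_frac: float = 0.10, area_alpha: float = 0.01,
                 is_negative: np.ndarray | None = None,
                 report: QCReport | None = None) -> np.ndarray:
    """Cell-level QC; returns indices of retained cells.

    Retains cells with >= ``min_transcripts`` total transcripts, <=
    ``max_neg_frac`` of counts on negative probes, a total-count to
    detected-gene ratio strictly > 1, and segmentation areas that are not
    Grubbs outliers at ``area_alpha``.
    """
    counts = sp.csr_matrix(counts)
    areas = np.asarray(areas, dtype=float)
    n = counts.shape[0]
    if areas.shape[0] != n:
        raise ValueError("areas not aligned to cells")
    totals = np.asarray(counts.sum(axis=1)).ravel()
    detected = np.asarray((counts > 0).sum(axis=1)).ravel()
    if is_negative is None:
        neg_counts = np.zeros(n)
    else:
        neg_counts = np.asarray(
            counts[:, np.asarray(is_negative, dtype=bool)].sum(axis=1)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        neg_frac = np.where(totals > 0, neg_counts / np.maximum(totals, 1), 0.0)
        ratio = np.where(detected > 0, totals / np.maximum(detected, 1), 0.0)
    area_out = np.zeros(n, dtype=bool)
    area_out[grubbs_outliers(areas, alpha=area_alpha)] = True
    ok = ((totals >= min_transcripts) & (neg_frac <= max_neg_frac)
          & (ratio > 1) & ~area_out)
    if report is not None:
        report.n_input_cells = n
        report.n_retained_cells = int(ok.sum())
        report.removed["cells_min_transcripts"] = int((totals < min_transcripts).sum())
        report.removed["cells_neg_frac"] = int((neg_frac > max_neg_frac).sum())
        report.removed["cells_ratio"] = int((ratio <= 1).sum())
        report.removed["cells_area_outlier"] = int(area_out.sum())
    return np.flatnonzero(ok)


def filter_fovs(counts, fov_of_cell, is_negative: np.ndarray | None = None,
                min_mean_counts_run: float = 100.0,
                max_mean_neg: float = 1.0, min_cells: int = 500,
                min_mean_counts_pipeline: float = 10.0,
                cell_scale: float = 1.0,
                report: QCReport | None = None) -> np.ndarray:
    """Two-stage FOV filter; returns retained FOV ids (sorted).

    Run-level: mean counts/cell >= ``min_mean_counts_run``, mean
    negative-probe counts/cell <= ``max_mean_neg``, and at least
    ``min_cells * cell_scale`` cells.  Pipeline-level: mean
    transcripts/cell >= ``min_mean_counts_pipeline``.  ``cell_scale``
    rescales the cell minimum for small fixtures.
    """
    counts = sp.csr_matrix(counts)
    fov_of_cell = np.asarray(fov_of_cell)
    if fov_of_cell.shape[0] != counts.shape[0]:
        raise ValueError("unknown FOV assignment: length mismatch")
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if is_negative is None:
        neg = np.zeros(counts.shape[0])
    else:
        neg = np.asarray(
            counts[:, np.asarray(is_negative, dtype=bool)].sum(axis=1)).ravel()
    kept = []
    for f in np.unique(fov_of_cell):
        m = fov_of_cell == f
        n = int(m.sum())
        mean_counts = totals[m].mean()
        mean_neg = neg[m].mean()
        run_ok = (mean_counts >= min_mean_counts_run
                  and mean_neg <= max_mean_neg
                  and n >= min_cells * cell_scale)
        pipe_ok = mean_counts >= min_mean_counts_pipeline
        if run_ok and pipe_ok:
            kept.append(f)
    if report is not None:
        report.retained_fovs = [x.item() if hasattr(x, "item") else x
                                for x in kept]
        report.fov_scale = cell_scale
    return np.array(kept)


def lognormalize(counts, scale_factor: float = 10000.0) -> sp.csr_matrix:
    """ln(1 + scale_factor * count / cell_total) per entry (LogNormalize).

    Zero counts map to zero; cells with zero total are rejected by name
    (index) because the normalization is undefined for them.
    """
    counts = sp.csr_matrix(counts, dtype=float)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    bad = np.flatnonzero(totals == 0)
    if bad.size:
        raise ValueError(f"zero-total cells cannot be normalized: {bad[:10].tolist()}")
    out = counts.multiply(scale_factor / totals[:, None]).tocsr()
    out.data = np.log1p(out.data)
    return out


def secondary_filter(counts, pct: float = 5.0) -> tuple[np.ndarray, dict]:
    """Pre-clustering cell filter: drop cells whose total counts OR
    detected gene counts fall below the ``pct``-th percentile of the
    respective distribution (linear-interpolation percentile).  Returns
    (retained indices, realized thresholds)."""
    counts = sp.csr_matrix(counts)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    detected = np.asarray((counts > 0).sum(axis=1)).ravel()
    if pct <= 0:
        return np.arange(counts.shape[0]), {"counts": -np.inf, "genes": -np.inf}
    t_cut = np.percentile(totals, pct)
    g_cut = np.percentile(detected, pct)
    ok = (totals >= t_cut) & (detected >= g_cut)
    return np.flatnonzero(ok), {"counts": float(t_cut), "genes": float(g_cut)}


def run_qc(counts, genes, cells, fov_scale: float = 1.0,
           scale_factor: float = 10000.0):
    """Convenience cascade: probe -> cell -> FOV filters, then
    log-normalization.  Returns (normalized csr, gene index, cell index,
    QCReport)."""
    report = QCReport()
    is_neg = genes["is_negative_probe"].to_numpy()
    gkeep = filter_probes(counts, is_neg, report=report)
    ckeep = filter_cells(counts[:, gkeep], cells["area"].to_numpy(),
                         is_negative=is_neg[gkeep], report=report)
    fkeep = filter_fovs(counts[ckeep][:, gkeep],
                        cells["fov"].to_numpy()[ckeep],
                        is_negative=is_neg[gkeep], cell_scale=fov_scale,
                        report=report)
    fov_ok = np.isin(cells["fov"].to_numpy()[ckeep], fkeep)
    ckeep = ckeep[fov_ok]
    report.n_retained_cells = int(ckeep.size)
    # normalization excludes negative probes
    target = gkeep[~is_neg[gkeep]]
    X = lognormalize(counts[ckeep][:, target], scale_factor=scale_factor)
    return X, target, ckeep, report
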