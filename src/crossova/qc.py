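"""Cell and gene quality filtering, depth normalization, variable-gene
selection and marker-score cell-type annotation.

Filtering keeps cells detecting at least ``min_genes`` genes with a
mitochondrial count fraction of at most ``max_mito`` ("fewer than 200 genes"
and "more than 10% mitochondrial" are read literally as strict removal
bounds), then keeps genes detected in at least ``min_cells_per_gene`` of the
surviving cells.  Normalization is the standard depth-scaled log transform
``ln(1 + count / total * scale_factor)``; variable genes follow the vst
recipe (variance standardized against a smooth log-log mean-variance trend,
clipped at sqrt(n)).
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess

from .exceptions import ConfigurationError, EmptyResultError

__all__ = [
    "filter_cells_genes",
    "normalize_log",
    "select_hvg",
    "annotate_by_markers",
    "mito_mask",
]


def mito_mask(adata: ad.AnnData, prefix: str = "MT-") -> np.ndarray:
    """Boolean mask of mitochondrial genes by symbol prefix (case-insensitive).

    Uses ``var["symbol"]`` when present (10x features carry id + symbol),
    otherwise the var names themselves.
    """
    names = (
        adata.var["symbol"].astype(str) if "symbol" in adata.var else adata.var_names.to_series()
    )
    return names.str.upper().str.startswith(prefix.upper()).to_numpy()


def _counts(adata: ad.AnnData) -> sp.csr_matrix:
    x = adata.layers.get("counts", adata.X)
    return sp.csr_matrix(x)


def filter_cells_genes(
    adata: ad.AnnData,
    min_genes: int = 200,
    max_mito: float = 0.10,
    min_cells_per_gene: int = 3,
    mito_prefix: str = "MT-",
) -> ad.AnnData:
    """Apply the cell filter, then the gene filter, preserving order.

    Retained cells satisfy ``n_genes_detected >= min_genes`` and
    ``mito_fraction <= max_mito``; retained genes have nonzero counts in at
    least ``min_cells_per_gene`` of the *retained* cells.  Per-cell QC
    metrics land in ``obs``; removal tallies in ``uns["qc_report"]``.
    """
    if min_genes < 0 or max_mito < 0 or min_cells_per_gene < 0:
        raise ConfigurationError("QC thresholds must be nonnegative")
    x = _counts(adata)
    n_detected = np.asarray((x > 0).sum(axis=1)).ravel()
    totals = np.asarray(x.sum(axis=1)).ravel().astype(float)
    mito = mito_mask(adata, mito_prefix)
    mito_counts = np.asarray(x[:, mito].sum(axis=1)).ravel() if mito.any() else np.zeros(x.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_counts / np.maximum(totals, 1e-300), 0.0)

    keep_cells = (n_detected >= min_genes) & (mito_frac <= max_mito)
    if not keep_cells.any():
        raise EmptyResultError(
            f"all {adata.n_obs} cells removed by QC (min_genes={min_genes}, max_mito={max_mito})"
        )
    out = adata[keep_cells].copy()
    out.obs["n_genes_detected"] = n_detected[keep_cells]
    out.obs["mito_fraction"] = mito_frac[keep_cells]

    x2 = _counts(out)
    cells_per_gene = np.asarray((x2 > 0).sum(axis=0)).ravel()
    keep_genes = cells_per_gene >= min_cells_per_gene
    n_genes_removed = int((~keep_genes).sum())
    out = out[:, keep_genes].copy()
    out.uns["qc_report"] = {
        "cells_in": int(adata.n_obs),
        "cells_removed": int((~keep_cells).sum()),
        "cells_removed_min_genes": int((n_detected < min_genes).sum()),
        "cells_removed_max_mito": int(((mito_frac > max_mito) & (n_detected >= min_genes)).sum()),
        "genes_in": int(adata.n_vars),
        "genes_removed": n_genes_removed,
        "min_genes": min_genes,
        "max_mito": max_mito,
        "min_cells_per_gene": min_cells_per_gene,
    }
    return out


def normalize_log(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Depth-normalize and log-transform: ``X := ln(1 + c / total * scale)``.

    Raw counts are preserved in ``layers["counts"]``.  A cell with zero
    total counts cannot be normalized and raises, naming the cell.
    """
    x = _counts(adata)
    totals = np.asarray(x.sum(axis=1)).ravel().astype(float)
    if (totals <= 0).any():
        bad = adata.obs_names[np.where(totals <= 0)[0][0]]
        raise EmptyResultError(f"cell {bad!r} has zero total counts; cannot normalize")
    out = adata.copy()
    out.layers["counts"] = x.copy()
    norm = x.astype(np.float64).multiply(scale_factor / totals[:, None]).tocsr()
    norm.data = np.log1p(norm.data)
    out.X = norm
    out.uns["scale_factor"] = float(scale_factor)
    return out


def _vst_standardized_variance(x: sp.csr_matrix, span: float) -> tuple[np.ndarray, ...]:
    """Per-gene (mean, variance, trend variance, standardized variance).

    The trend is a lowess fit of log10 variance on log10 mean over genes with
    positive mean and variance; standardized values are clipped above at
    sqrt(n_cells) and their uncentred variance is the ranking statistic.
    """
    n, g = x.shape
    xc = x.tocsc().astype(np.float64)
    mean = np.asarray(xc.mean(axis=0)).ravel()
    sq = np.asarray(xc.multiply(xc).mean(axis=0)).ravel()
    var = (sq - mean**2) * n / max(n - 1, 1)
    # clamp float residue of the E[x^2] - mean^2 form so constant genes get 0
    var[var <= 1e-10 * np.maximum(mean**2, 1.0)] = 0.0

    fit_mask = (mean > 0) & (var > 0)
    expected = np.zeros(g)
    if fit_mask.sum() >= 2:
        lx = np.log10(mean[fit_mask])
        ly = np.log10(var[fit_mask])
        fitted = lowess(ly, lx, frac=span, return_sorted=False)
        expected[fit_mask] = 10.0 ** fitted
    std_var = np.zeros(g)
    clip = np.sqrt(n)
    esd = np.sqrt(expected)
    for j in np.where(fit_mask)[0]:
        col = xc.getcol(j)
        vals = col.data
        n0 = n - len(vals)
        z_nz = np.minimum((vals - mean[j]) / esd[j], clip)
        z0 = min((0.0 - mean[j]) / esd[j], clip)
        total_sq = (z_nz**2).sum() + n0 * z0**2
        std_var[j] = total_sq / max(n - 1, 1)
    return mean, var, expected, std_var


def select_hvg(
    adata: ad.AnnData,
    n_top: int = 2000,
    span: float = 0.3,
    batch_key: str | None = None,
) -> pd.DataFrame:
    """Rank genes by vst standardized variance computed on raw counts.

    Returns a table with ``gene_id, mean, variance, expected_variance,
    standardized_variance, rank, highly_variable``.  With ``batch_key`` the
    statistic is computed per batch and genes are selected by how many
    batches rank them in their top ``n_top``, breaking ties by median
    within-batch rank (the per-replicate-then-union convention); without it
    cells are pooled.
    """
    if adata.n_obs < 2:
        raise ConfigurationError("select_hvg needs at least 2 cells")
    x = _counts(adata)
    if n_top > adata.n_vars:
        warnings.warn(
            f"n_top={n_top} exceeds {adata.n_vars} genes; returning all genes ranked"
        )
        n_top = adata.n_vars

    mean, var, expected, std_var = _vst_standardized_variance(x, span)
    table = pd.DataFrame(
        {
            "gene_id": adata.var_names,
            "mean": mean,
            "variance": var,
            "expected_variance": expected,
            "standardized_variance": std_var,
        }
    )
    if batch_key is None:
        order = table.sort_values(
            ["standardized_variance", "gene_id"], ascending=[False, True]
        ).index
        rank = pd.Series(np.arange(1, len(table) + 1), index=order)
        table["rank"] = rank.sort_index()
        table["highly_variable"] = table["rank"] <= n_top
        return table

    batches = adata.obs[batch_key].astype(str)
    per_batch_rank = {}
    for b in batches.unique():
        xb = x[(batches == b).to_numpy()]
        if xb.shape[0] < 2:
            warnings.warn(f"batch {b!r} has < 2 cells; skipped for HVG selection")
            continue
        _, _, _, sv = _vst_standardized_variance(sp.csr_matrix(xb), span)
        sub = pd.DataFrame({"gene_id": adata.var_names, "sv": sv})
        order = sub.sort_values(["sv", "gene_id"], ascending=[False, True]).index
        r = pd.Series(np.arange(1, len(sub) + 1), index=order).sort_index()
        per_batch_rank[b] = r.to_numpy()
    ranks = np.column_stack(list(per_batch_rank.values()))
    n_selected = (ranks <= n_top).sum(axis=1)
    median_rank = np.median(ranks, axis=1)
    table["n_batches_selected"] = n_selected
    table["median_rank"] = median_rank
    order = table.sort_values(
        ["n_batches_selected", "median_rank", "gene_id"], ascending=[False, True, True]
    ).index
    rank = pd.Series(np.arange(1, len(table) + 1), index=order)
    table["rank"] = rank.sort_index()
    table["highly_variable"] = table["rank"] <= n_top
    return table


def annotate_by_markers(
    adata: ad.AnnData,
    cluster_labels,
    marker_map: dict[str, list[str]],
) -> pd.DataFrame:
    """Assign each cluster the cell type whose markers it expresses most.

    The score of a type in a cluster is the mean normalized expression of
    that type's marker genes over the cluster's cells; assignment is the
    argmax, ties broken lexicographically and flagged.  Markers absent from
    the matrix are dropped with a warning.
    """
    if not marker_map:
        raise ConfigurationError("marker_map is empty")
    labels = pd.Series(np.asarray(cluster_labels), index=adata.obs_names)
    x = sp.csr_matrix(adata.X)
    present: dict[str, list[int]] = {}
    var_index = {g: i for i, g in enumerate(adata.var_names)}
    for ctype, genes in marker_map.items():
        idx = [var_index[g] for g in genes if g in var_index]
        missing = [g for g in genes if g not in var_index]
        if missing:
            warnings.warn(f"{ctype}: {len(missing)} marker genes absent and dropped: {missing}")
        if not idx:
            warnings.warn(f"{ctype}: no marker genes present; type excluded")
            continue
        present[ctype] = idx
    if not present:
        raise ConfigurationError("no marker genes present in the matrix")

    rows = []
    for cluster in pd.unique(labels):
        mask = (labels == cluster).to_numpy()
        scores = {
            t: float(x[mask][:, idx].mean()) for t, idx in present.items()
        }
        best = max(scores.values())
        winners = sorted(t for t, s in scores.items() if s == best)
        rows.append(
            {
                "cluster": cluster,
                "cell_type": winners[0],
                "tie": len(winners) > 1,
                **{f"score_{t}": s for t, s in scores.items()},
            }
        )
    return pd.DataFrame(rows).set_index("cluster")
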