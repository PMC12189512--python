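"""Per-cell-type metabolic pathway activity with a permutation null.

Following the pathway-activity convention for single-cell metabolic
comparisons: the mean expression of each gene in a cell type is divided by
its average mean across cell types (relative expression, 1 = average), the
pathway activity is the weighted average of member genes' relative
expression with weights 1 / (number of pathways containing the gene), and
robustness comes from trimming relative values above 3x the pathway's 75th
percentile or below a third of its 25th percentile.  Significance of a
(pathway, cell type) activity is assessed by shuffling cell-type labels
and recomputing the whole score; the default test is two-sided on the
deviation |activity - 1| with an add-one correction.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError

__all__ = [
    "relative_expression",
    "pathway_activity_scores",
    "permutation_test",
    "cohens_d",
]


def relative_expression(
    adata: ad.AnnData, labels, genes: list[str] | None = None
) -> pd.DataFrame:
    """Gene x cell-type matrix of mean expression relative to the type-average.

    r(g, t) = mean_expr(g, t) / mean over types of mean_expr(g, .).  Genes
    with zero mean in every type are excluded and listed in
    ``.attrs["excluded"]``.
    """
    labels = pd.Series(np.asarray(labels), index=adata.obs_names)
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ConfigurationError("relative expression needs at least 2 cell types")
    if genes is None:
        genes = list(adata.var_names)
    present = [g for g in genes if g in set(adata.var_names)]
    sub = adata[:, present]
    x = sub.X
    x = np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)
    means = np.vstack(
        [x[(labels == t).to_numpy()].mean(axis=0) for t in types]
    ).T  # genes x types
    rel, keep = _relative_from_means(means)
    out = pd.DataFrame(rel, index=np.asarray(present)[keep], columns=types)
    out.attrs["excluded"] = [g for g, k in zip(present, keep) if not k]
    return out


def _relative_from_means(means: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    avg = means.mean(axis=1)
    keep = avg > 0
    rel = means[keep] / avg[keep, None]
    return rel, keep


def pathway_weights(pathways: dict[str, list[str]]) -> pd.Series:
    """w_g = 1 / number of supplied pathways containing gene g."""
    counts: dict[str, int] = {}
    for genes in pathways.values():
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    return pd.Series({g: 1.0 / c for g, c in counts.items()})


def _score_pathways(
    rel: pd.DataFrame,
    pathways: dict[str, list[str]],
    weights: pd.Series,
    trim: str | None = "pooled",
) -> pd.DataFrame:
    """Activity per (pathway, cell type) with outlier trimming.

    ``trim='pooled'`` pools each pathway's relative values over cell types
    before computing the trimming quartiles (the default reading of
    "within each pathway"); ``'per_type'`` trims within each cell type;
    ``None`` disables trimming.
    """
    types = list(rel.columns)
    gene_index = set(rel.index)
    rows = []
    for name, genes in pathways.items():
        members = [g for g in dict.fromkeys(genes) if g in gene_index]
        if not members:
            for t in types:
                rows.append({"pathway": name, "cell_type": t, "activity": np.nan,
                             "n_genes_used": 0, "n_outliers_removed": 0, "undefined": True})
            continue
        r = rel.loc[members].to_numpy()  # members x types
        w = weights.loc[members].to_numpy()
        if trim == "pooled":
            q25, q75 = np.percentile(r, [25, 75])
            ok = (r <= 3.0 * q75) & (r >= q25 / 3.0)
        elif trim == "per_type":
            q25 = np.percentile(r, 25, axis=0)
            q75 = np.percentile(r, 75, axis=0)
            ok = (r <= 3.0 * q75[None, :]) & (r >= q25[None, :] / 3.0)
        elif trim is None:
            ok = np.ones_like(r, dtype=bool)
        else:
            raise ConfigurationError(f"unknown trim mode {trim!r}")
        wsum = (w[:, None] * ok).sum(axis=0)
        act = np.where(wsum > 0, (w[:, None] * r * ok).sum(axis=0) / np.where(wsum > 0, wsum, 1.0), np.nan)
        for j, t in enumerate(types):
            rows.append(
                {
                    "pathway": name,
                    "cell_type": t,
                    "activity": float(act[j]),
                    "n_genes_used": int(ok[:, j].sum()),
                    "n_outliers_removed": int((~ok[:, j]).sum()),
                    "undefined": not np.isfinite(act[j]),
                }
            )
    return pd.DataFrame(rows)


def pathway_activity_scores(
    rel: pd.DataFrame,
    pathways: dict[str, list[str]],
    trim: str | None = "pooled",
) -> pd.DataFrame:
    """Weighted, outlier-trimmed pathway activity per cell type.

    Weights are 1 / pathway-membership count over the supplied sets, so a
    gene shared by two pathways contributes half the weight of a private
    gene.  Pathways with zero surviving genes in a type are flagged
    ``undefined`` rather than silently dropped.
    """
    if not pathways:
        raise ConfigurationError("no pathways supplied")
    missing = [p for p, genes in pathways.items() if not set(genes) & set(rel.index)]
    if len(missing) == len(pathways):
        raise ConfigurationError("no pathway intersects the available genes")
    return _score_pathways(rel, pathways, pathway_weights(pathways), trim)


def permutation_test(
    adata: ad.AnnData,
    labels,
    pathways: dict[str, list[str]],
    n_perm: int = 5000,
    seed: int = 0,
    alternative: str = "two-sided",
    trim: str | None = "pooled",
) -> pd.DataFrame:
    """Permutation p-values for per-type pathway activity.

    Cell-type labels are shuffled uniformly ``n_perm`` times and the whole
    activity computation (relative expression, trimming, weighting) is
    rerun on each shuffle.  With ``alternative='two-sided'`` the statistic
    is the deviation |activity - 1|; ``'greater'`` tests elevated activity
    only.  p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    if alternative not in ("two-sided", "greater"):
        raise ConfigurationError(f"unknown alternative {alternative!r}")
    labels = pd.Series(np.asarray(labels), index=adata.obs_names)
    types = sorted(labels.unique())
    union = sorted({g for genes in pathways.values() for g in genes} & set(adata.var_names))
    if not union:
        raise ConfigurationError("no pathway gene present in the matrix")
    sub = adata[:, union]
    x = sub.X
    x = np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)
    weights = pathway_weights(pathways)

    lab_codes = pd.Categorical(labels, categories=types).codes
    onehot = np.zeros((len(types), len(lab_codes)))
    onehot[lab_codes, np.arange(len(lab_codes))] = 1.0
    group_n = onehot.sum(axis=1)

    # genes with zero counts overall are excluded under every relabeling, so
    # membership indices and weights can be fixed once
    expressed = np.asarray(x.sum(axis=0)).ravel() > 0
    x = x[:, expressed]
    kept_genes = [g for g, e in zip(union, expressed) if e]
    pos = {g: i for i, g in enumerate(kept_genes)}
    members = {
        name: np.array([pos[g] for g in dict.fromkeys(genes) if g in pos], dtype=int)
        for name, genes in pathways.items()
    }
    wvecs = {name: weights.loc[[kept_genes[i] for i in idx]].to_numpy()
             for name, idx in members.items()}

    def activities(codes_perm: np.ndarray) -> np.ndarray:
        """(pathway, type) activity array, pathway-major, matching the table."""
        means = (onehot[:, codes_perm] @ x).T / group_n  # genes x types
        rel = means / means.mean(axis=1, keepdims=True)
        out = np.full((len(pathways), len(types)), np.nan)
        for k, name in enumerate(pathways):
            idx = members[name]
            if len(idx) == 0:
                continue
            r = rel[idx]
            w = wvecs[name]
            if trim == "pooled":
                q25, q75 = np.percentile(r, [25, 75])
                ok = (r <= 3.0 * q75) & (r >= q25 / 3.0)
            elif trim == "per_type":
                q25 = np.percentile(r, 25, axis=0)
                q75 = np.percentile(r, 75, axis=0)
                ok = (r <= 3.0 * q75[None, :]) & (r >= q25[None, :] / 3.0)
            else:
                ok = np.ones_like(r, dtype=bool)
            wsum = (w[:, None] * ok).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                out[k] = np.where(
                    wsum > 0, (w[:, None] * r * ok).sum(axis=0) / np.where(wsum > 0, wsum, 1.0), np.nan
                )
        return out.ravel()

    rel_obs = relative_expression(sub, labels)
    obs = _score_pathways(rel_obs, pathways, weights, trim)

    def deviation(act: np.ndarray) -> np.ndarray:
        return np.abs(act - 1.0) if alternative == "two-sided" else act - 1.0

    obs_dev = deviation(activities(np.arange(len(lab_codes))))
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(obs_dev))
    for _ in range(n_perm):
        perm = rng.permutation(len(lab_codes))
        dev = deviation(activities(perm))
        with np.errstate(invalid="ignore"):
            exceed += (dev >= obs_dev).astype(float)
    p = (1.0 + exceed) / (1.0 + n_perm)
    out = obs.copy()
    out["p_value"] = np.where(np.isfinite(obs_dev), p, np.nan)
    out.attrs["n_perm"] = n_perm
    out.attrs["alternative"] = alternative
    return out


def cohens_d(x, y) -> float:
    """Standardized mean difference with the pooled standard deviation.

    d = (mean x - mean y) / s_p,  s_p^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("cohens_d needs at least 2 observations per sample")
    s1, s2 = x.var(ddof=1), y.var(ddof=1)
    pooled = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    if pooled <= 0:
        raise ConfigurationError("pooled variance is zero; Cohen's d undefined")
    return float((x.mean() - y.mean()) / np.sqrt(pooled))
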