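"""Regulon activity, specificity and module structure.

A regulon is a transcription factor with its target genes, treated as one
gene set.  Activity per cell is the AUCell statistic: genes are ranked by
expression within each cell and the score is the normalized area under the
gene set's recovery curve within the top ``top_frac`` of the ranking, so it
lies in [0, 1] and is invariant to monotone transforms of expression.

Specificity uses the Jensen-Shannon divergence between a regulon's
activity distribution over cells and a cell-type indicator distribution
(RSS = 1 - sqrt(JSD), base-2 logs so both are bounded by 1), z-scored
across regulons within each cell type (RSSZ).  A regulon counts as
significant for a type when its mean AUCell there exceeds ``aucell_min``
and its RSSZ exceeds ``rssz_min``.

The connection specificity index (CSI) of regulons A and B is the fraction
of other regulons whose Pearson correlation with both A and B is lower
than the A-B correlation; Ward clustering of 1 - CSI over regulons with at
least one CSI above ``csi_min`` yields transcription-factor modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import jensenshannon, squareform
from scipy.stats import rankdata

from .exceptions import ConfigurationError

__all__ = [
    "aucell_score",
    "compute_rss",
    "compute_csi",
    "csi_from_pcc",
    "detect_modules",
    "suggest_k",
    "infer_importance",
    "extract_targets",
    "ModuleAssignment",
]


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)


def aucell_score(
    adata: ad.AnnData,
    regulons: dict[str, list[str]],
    top_frac: float = 0.05,
) -> pd.DataFrame:
    """AUCell activity of each regulon in each cell (regulons x cells).

    Expression ties are broken by ascending gene id — a deterministic
    choice, where the reference tool shuffles — so identical inputs always
    give identical scores.  Regulons with no genes in the matrix get a NaN
    row and are listed in ``.attrs["undefined"]``; partial losses are
    warned about.
    """
    if not (0 < top_frac <= 1):
        raise ConfigurationError("top_frac must be in (0, 1]")
    # sort genes by id so that stable argsort on -x breaks ties by gene id
    gene_order = np.argsort(adata.var_names.to_numpy())
    x = _dense(adata.X)[:, gene_order]
    genes = adata.var_names.to_numpy()[gene_order]
    n_cells, n_genes = x.shape
    order = np.argsort(-x, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(n_cells)[:, None]
    ranks[rows, order] = np.arange(1, n_genes + 1)

    k = int(np.ceil(top_frac * n_genes))
    gene_pos = {g: i for i, g in enumerate(genes)}
    scores = np.full((len(regulons), n_cells), np.nan)
    undefined = []
    for i, (name, members) in enumerate(regulons.items()):
        uniq = list(dict.fromkeys(members))
        if len(uniq) != len(members):
            raise ConfigurationError(f"regulon {name!r} contains duplicate targets")
        idx = [gene_pos[g] for g in uniq if g in gene_pos]
        lost = len(uniq) - len(idx)
        if lost:
            warnings.warn(f"regulon {name!r}: {lost} gene(s) absent from the matrix")
        if not idx:
            undefined.append(name)
            continue
        m = min(len(idx), k)
        max_auc = m * (m + 1) / 2 + (k - m) * m
        r = ranks[:, idx]
        scores[i] = np.clip(k - r + 1, 0, None).sum(axis=1) / max_auc
    out = pd.DataFrame(scores, index=list(regulons), columns=adata.obs_names)
    out.attrs["undefined"] = undefined
    out.attrs["top_frac"] = top_frac
    return out


def compute_rss(
    activity: pd.DataFrame,
    labels,
    aucell_min: float = 0.1,
    rssz_min: float = 1.0,
    z_axis: str = "within_type",
) -> pd.DataFrame:
    """Regulon specificity scores per (regulon, cell type).

    ``z_axis`` controls the RSSZ normalization: ``within_type`` (default)
    z-scores RSS across regulons within each cell type, identifying
    type-specific regulators; ``within_regulon`` z-scores across types.
    """
    labels = pd.Series(np.asarray(labels), index=activity.columns)
    act = activity.to_numpy(dtype=float)
    types = sorted(labels.unique())
    rows = []
    row_sums = np.nansum(act, axis=1)
    for i, reg in enumerate(activity.index):
        if not np.isfinite(act[i]).all() or row_sums[i] <= 0:
            for t in types:
                rows.append(
                    {"regulon": reg, "cell_type": t, "rss": np.nan,
                     "mean_aucell_in_type": np.nan, "undefined": True}
                )
            continue
        p = act[i] / row_sums[i]
        for t in types:
            q = (labels == t).to_numpy(dtype=float)
            q = q / q.sum()
            rss = 1.0 - jensenshannon(p, q, base=2)
            rows.append(
                {
                    "regulon": reg,
                    "cell_type": t,
                    "rss": float(rss),
                    "mean_aucell_in_type": float(act[i][(labels == t).to_numpy()].mean()),
                    "undefined": False,
                }
            )
    table = pd.DataFrame(rows)
    group = "cell_type" if z_axis == "within_type" else "regulon"
    z = table.groupby(group)["rss"].transform(
        lambda v: (v - v.mean()) / v.std(ddof=1) if v.std(ddof=1) > 0 else v * 0.0
    )
    table["rssz"] = z
    table["significant"] = (
        (table["mean_aucell_in_type"] > aucell_min) & (table["rssz"] > rssz_min)
    ).fillna(False)
    return table


def compute_csi(activity: pd.DataFrame) -> pd.DataFrame:
    """Connection specificity index between every pair of regulons.

    CSI(A, B) = #{C not in {A, B}: PCC(A,C) < PCC(A,B) and PCC(B,C) <
    PCC(A,B)} / (N - 2), computed on cell-level activity; symmetric with a
    unit diagonal.  Zero-variance regulons are excluded with a warning.
    """
    act = activity.to_numpy(dtype=float)
    ok = np.isfinite(act).all(axis=1) & (act.std(axis=1) > 0)
    if (~ok).any():
        warnings.warn(
            f"excluding {int((~ok).sum())} regulon(s) with zero variance or undefined activity"
        )
    names = activity.index[ok]
    act = act[ok]
    n = len(names)
    if n < 3:
        raise ConfigurationError("CSI needs at least 3 regulons with nonzero variance")
    pcc = np.corrcoef(act)
    return pd.DataFrame(csi_from_pcc(pcc), index=names, columns=names)


def csi_from_pcc(pcc: np.ndarray) -> np.ndarray:
    """CSI matrix from a regulon-regulon Pearson correlation matrix."""
    n = pcc.shape[0]
    if n < 3:
        raise ConfigurationError("CSI needs at least 3 regulons")
    csi = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            thr = pcc[i, j]
            below = (pcc[i] < thr) & (pcc[j] < thr)
            below[i] = below[j] = False
            csi[i, j] = csi[j, i] = below.sum() / (n - 2)
    np.fill_diagonal(csi, 1.0)
    return csi


@dataclass
class ModuleAssignment:
    modules: dict[str, int]
    linkage: np.ndarray | None
    k: int
    unclustered: list[str] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(self.modules, name="module", dtype=int)


def detect_modules(csi: pd.DataFrame, k: int, csi_min: float = 0.8) -> ModuleAssignment:
    """Ward-cluster regulons with strong specific connections into k modules.

    Regulons with at least one off-diagonal CSI strictly above ``csi_min``
    are clustered on distance 1 - CSI; the dendrogram is cut at ``k``
    modules.  Regulons failing the CSI screen are reported as unclustered.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    c = csi.to_numpy(dtype=float)
    off = c - np.eye(len(c))
    keep = (off > csi_min).any(axis=1)
    unclustered = list(csi.index[~keep])
    names = list(csi.index[keep])
    if not names:
        warnings.warn(f"no CSI value exceeds {csi_min}; empty module assignment")
        return ModuleAssignment({}, None, k, unclustered)
    sub = c[np.ix_(keep, keep)]
    if len(names) == 1:
        return ModuleAssignment({names[0]: 1}, None, k, unclustered)
    dist = 1.0 - sub
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    z = linkage(squareform(dist, checks=False), method="ward")
    assignment = fcluster(z, t=min(k, len(names)), criterion="maxclust")
    return ModuleAssignment(dict(zip(names, (int(a) for a in assignment))), z, k, unclustered)


def suggest_k(csi: pd.DataFrame, csi_min: float = 0.8, k_max: int = 12) -> int:
    """Silhouette-based suggestion for the module count (advisory only)."""
    from sklearn.metrics import silhouette_score

    c = csi.to_numpy(dtype=float)
    keep = ((c - np.eye(len(c))) > csi_min).any(axis=1)
    sub = 1.0 - c[np.ix_(keep, keep)]
    np.fill_diagonal(sub, 0.0)
    n = sub.shape[0]
    if n < 3:
        return 1
    z = linkage(squareform((sub + sub.T) / 2.0, checks=False), method="ward")
    best_k, best_s = 2, -np.inf
    for k in range(2, min(k_max, n - 1) + 1):
        lab = fcluster(z, t=k, criterion="maxclust")
        if len(set(lab)) < 2:
            continue
        s = silhouette_score(sub, lab, metric="precomputed")
        if s > best_s:
            best_k, best_s = k, s
    return best_k


def infer_importance(
    adata: ad.AnnData,
    regulators: list[str],
    targets: list[str],
    estimator: str = "correlation",
    scale: float = 10.0,
    seed: int = 0,
    n_estimators: int = 100,
) -> pd.DataFrame:
    """Regulator-to-target importance table (GENIE3-style IM values).

    ``correlation``: IM = |Spearman rho| x ``scale`` — deterministic, with
    ``scale`` mapping correlation onto the conventional IM axis where 1
    marks a moderate association.  ``tree_ensemble``: per-target random
    forest regression on the regulators; sklearn importances (which sum to
    1 per target) are multiplied by the number of regulators so that 1 is
    the importance of an average regulator.  Regulator == target pairs are
    skipped.
    """
    var_idx = {g: i for i, g in enumerate(adata.var_names)}
    missing = [g for g in list(regulators) + list(targets) if g not in var_idx]
    if missing:
        raise ConfigurationError(f"genes absent from matrix: {missing[:5]}")
    x = _dense(adata.X)
    reg_x = x[:, [var_idx[g] for g in regulators]]
    rows = []
    if estimator == "correlation":
        reg_r = rankdata(reg_x, axis=0)
        reg_r = (reg_r - reg_r.mean(axis=0)) / np.where(reg_r.std(axis=0) > 0, reg_r.std(axis=0), 1.0)
        for t in targets:
            ty = rankdata(x[:, var_idx[t]])
            sd = ty.std()
            ty = (ty - ty.mean()) / (sd if sd > 0 else 1.0)
            rho = reg_r.T @ ty / len(ty)
            for r, g in zip(rho, regulators):
                if g == t:
                    continue
                rows.append({"regulator": g, "target": t, "importance": abs(float(r)) * scale})
    elif estimator == "tree_ensemble":
        from sklearn.ensemble import RandomForestRegressor

        rng = np.random.default_rng(seed)
        for t in targets:
            feats = [g for g in regulators if g != t]
            if not feats:
                continue
            fx = x[:, [var_idx[g] for g in feats]]
            model = RandomForestRegressor(
                n_estimators=n_estimators,
                max_features="sqrt",
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            model.fit(fx, x[:, var_idx[t]])
            for g, imp in zip(feats, model.feature_importances_):
                rows.append({"regulator": g, "target": t, "importance": float(imp) * len(feats)})
    else:
        raise ConfigurationError(f"unknown estimator {estimator!r}")
    return pd.DataFrame(rows, columns=["regulator", "target", "importance"])


def extract_targets(im: pd.DataFrame, regulator: str, im_min: float = 1.0) -> list[str]:
    """Targets of a regulator with importance strictly above ``im_min``."""
    sub = im[im["regulator"] == regulator]
    if sub.empty:
        raise ConfigurationError(f"regulator {regulator!r} not in importance table")
    hits = sub[sub["importance"] > im_min].sort_values(
        ["importance", "target"], ascending=[False, True]
    )
    return list(hits["target"])
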