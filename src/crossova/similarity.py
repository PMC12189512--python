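"""Cross-species cell-type similarity: neighbor-voting AUROC and Spearman
correlation of mean expression profiles.

The neighbor-voting statistic follows the MetaNeighbor scheme.  A cell-cell
similarity network is built from the Spearman correlation of highly
variable gene expression and rank-normalized per cell to [0, 1].  For an
ordered pair of species (train A, test B) and a training cell type t, each
test cell accumulates a degree-normalized vote

    vote(b) = sum_{a in A, type t} S[b, a] / sum_{a in A} S[b, a]

and the AUROC of those votes with each test cell type's membership as the
positive class measures how well A's type t identifies B's types.  The two
directions are averaged.  Being rank-based end to end, the statistic is
invariant to monotone transforms of expression.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .exceptions import ConfigurationError
from .qc import select_hvg

__all__ = [
    "neighbor_voting_auroc",
    "crossspecies_spearman",
    "neighbor_species_scores",
    "auroc_from_scores",
    "voting_hvgs",
]


def auroc_from_scores(scores: np.ndarray, positives: np.ndarray) -> float:
    """AUROC of a score vector against a boolean positive mask (midranks)."""
    scores = np.asarray(scores, dtype=float)
    positives = np.asarray(positives, dtype=bool)
    n_pos = int(positives.sum())
    n_neg = int((~positives).sum())
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = rankdata(scores)
    return (ranks[positives].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def voting_hvgs(
    data, n_top: int = 2000, species_key: str = "species"
) -> list[str]:
    """Union of per-species top HVGs within the shared ortholog space."""
    adata = data.adata if hasattr(data, "adata") else data
    union: set[str] = set()
    for species in adata.obs[species_key].unique():
        sub = adata[adata.obs[species_key] == species]
        tab = select_hvg(sub, n_top=min(n_top, sub.n_vars))
        union |= set(tab.loc[tab["highly_variable"], "gene_id"])
    return sorted(union)


def neighbor_voting_auroc(
    data,
    hvgs: list[str] | None = None,
    species_key: str = "species",
    type_key: str = "cell_type",
    min_cells: int = 2,
) -> pd.DataFrame:
    """Neighbor-voting AUROC between every cross-species cell-type pair.

    Parameters
    ----------
    data
        A :class:`~crossova.orthologs.MultiSpeciesDataset` or an AnnData with
        normalized expression on a shared gene space.
    hvgs
        Genes to build the similarity network from; defaults to the union of
        per-species HVGs.

    Returns a square DataFrame indexed by (species, cell_type); the diagonal
    is 1 by convention, same-species off-diagonal entries are NaN, and the
    matrix is symmetrized by averaging the two training directions.  Group
    cell counts are attached as ``.attrs["n_cells"]``.
    """
    adata = data.adata if hasattr(data, "adata") else data
    species = list(pd.unique(adata.obs[species_key]))
    if len(species) < 2:
        raise ConfigurationError("neighbor voting needs at least 2 species")
    if hvgs is None:
        hvgs = voting_hvgs(adata, species_key=species_key)
    hvgs = [g for g in hvgs if g in set(adata.var_names)]
    if len(hvgs) < 2:
        raise ConfigurationError("fewer than 2 voting genes present")

    groups = (
        adata.obs.groupby([species_key, type_key], observed=True).size().rename("n")
    )
    small = groups[groups < min_cells]
    for (s, t), n in small.items():
        warnings.warn(f"group ({s}, {t}) has {n} < {min_cells} cells; excluded")
    keep_groups = set(groups[groups >= min_cells].index)
    mask = [
        (s, t) in keep_groups
        for s, t in zip(adata.obs[species_key], adata.obs[type_key])
    ]
    adata = adata[np.asarray(mask)]

    x = adata[:, hvgs].X
    x = np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)
    ranks = rankdata(x, axis=1)
    corr = np.corrcoef(ranks)  # Pearson of ranks == Spearman
    n_cells = corr.shape[0]
    s_net = rankdata(corr, axis=1) / n_cells  # per-cell rank normalization

    sp_arr = adata.obs[species_key].to_numpy()
    ty_arr = adata.obs[type_key].to_numpy()
    labels = sorted(keep_groups)
    index = pd.MultiIndex.from_tuples(labels, names=["species", "cell_type"])
    acc = pd.DataFrame(np.nan, index=index, columns=index)

    for a in species:
        a_mask = sp_arr == a
        for b in species:
            if a == b:
                continue
            b_mask = sp_arr == b
            s_ba = s_net[np.ix_(b_mask, a_mask)]
            degree = s_ba.sum(axis=1)
            b_types = ty_arr[b_mask]
            for t in sorted({t for s, t in labels if s == a}):
                votes = s_ba[:, ty_arr[a_mask] == t].sum(axis=1) / degree
                for u in sorted({t2 for s2, t2 in labels if s2 == b}):
                    acc.loc[(a, t), (b, u)] = auroc_from_scores(votes, b_types == u)

    sym = (acc + acc.T) / 2.0
    np.fill_diagonal(sym.values, 1.0)
    sym.attrs["n_cells"] = {f"{s}|{t}": int(n) for (s, t), n in groups[groups >= min_cells].items()}
    return sym


def crossspecies_spearman(
    data,
    n_top: int = 2000,
    species_key: str = "species",
    type_key: str = "cell_type",
    batch_key: str | None = None,
) -> pd.DataFrame:
    """Spearman rho of mean expression between species, per shared cell type.

    For each unordered species pair the gene set is the union of each side's
    top ``n_top`` vst HVGs (restricted to the shared ortholog space); rho
    compares the per-cell-type mean normalized expression vectors.
    """
    adata = data.adata if hasattr(data, "adata") else data
    species = list(pd.unique(adata.obs[species_key]))
    hvg_sets: dict[str, set[str]] = {}
    for s in species:
        sub = adata[adata.obs[species_key] == s]
        key = batch_key if batch_key and batch_key in sub.obs else None
        tab = select_hvg(sub, n_top=min(n_top, sub.n_vars), batch_key=key)
        hvg_sets[s] = set(tab.loc[tab["highly_variable"], "gene_id"])

    rows = []
    for i, s1 in enumerate(species):
        for s2 in species[i + 1 :]:
            genes = sorted(hvg_sets[s1] | hvg_sets[s2])
            gi = [i for i, g in enumerate(adata.var_names) if g in set(genes)]
            t1 = set(adata.obs.loc[adata.obs[species_key] == s1, type_key])
            t2 = set(adata.obs.loc[adata.obs[species_key] == s2, type_key])
            shared_types = sorted(t1 & t2)
            if not shared_types:
                warnings.warn(f"no shared cell types between {s1} and {s2}")
                continue
            for t in shared_types:
                m1 = _group_mean(adata, species_key, s1, type_key, t, gi)
                m2 = _group_mean(adata, species_key, s2, type_key, t, gi)
                rho = spearmanr(m1, m2).statistic
                rows.append(
                    {
                        "species_a": s1,
                        "species_b": s2,
                        "cell_type": t,
                        "spearman_rho": float(rho),
                        "n_genes": len(gi),
                    }
                )
    return pd.DataFrame(rows, columns=["species_a", "species_b", "cell_type", "spearman_rho", "n_genes"])


def _group_mean(adata, species_key, species, type_key, ctype, gene_idx) -> np.ndarray:
    mask = (
        (adata.obs[species_key] == species) & (adata.obs[type_key] == ctype)
    ).to_numpy()
    x = adata.X[mask][:, gene_idx]
    return np.asarray(x.mean(axis=0)).ravel()


def neighbor_species_scores(
    auroc: pd.DataFrame, species_order: list[str]
) -> pd.DataFrame:
    """Matched-cell-type AUROC for consecutive species in a supplied order.

    The order is the user's evolutionary arrangement (e.g. zebrafish, mouse,
    donkey, macaque, human); for each adjacent pair the matched-type entries
    of the AUROC matrix are extracted.
    """
    known = set(auroc.index.get_level_values("species"))
    unknown = [s for s in species_order if s not in known]
    if unknown:
        raise ConfigurationError(f"species not in AUROC matrix: {unknown}")
    rows = []
    for a, b in zip(species_order, species_order[1:]):
        types_a = {t for s, t in auroc.index if s == a}
        types_b = {t for s, t in auroc.index if s == b}
        for t in sorted(types_a & types_b):
            rows.append(
                {
                    "species_a": a,
                    "species_b": b,
                    "cell_type": t,
                    "auroc": float(auroc.loc[(a, t), (b, t)]),
                }
            )
    return pd.DataFrame(rows, columns=["species_a", "species_b", "cell_type", "auroc"])
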