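"""Wilcoxon rank-sum marker detection and cross-species marker partitioning.

Differential expression between two cell groups uses the two-sided
Wilcoxon rank-sum (Mann-Whitney) test with midranks, tie correction and
continuity correction, Bonferroni adjustment over the genes tested, and a
log2 fold change computed on de-logged normalized means.  Genes pass when
adjusted p < 0.05 and |log2FC| > 0.25 (both thresholds configurable);
"markers" are the positive side only.

`partition_markers` maps per-species marker lists into the reference gene
space through the one-to-one ortholog table and splits them into markers
conserved in every species, markers private to exactly one species, and an
intermediate bucket for genes shared by some but not all species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .exceptions import ConfigurationError
from .orthologs import ONE2ONE

__all__ = ["wilcoxon_de", "find_all_markers", "partition_markers", "MarkerPartition"]

LOG2FC_EPS = 1e-9


def _dense(x) -> np.ndarray:
    return np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)


def wilcoxon_de(
    adata: ad.AnnData,
    group1,
    group2,
    alpha: float = 0.05,
    min_lfc: float = 0.25,
    group1_name: str = "group1",
    group2_name: str = "group2",
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DE of group1 vs group2, per gene.

    ``group1`` / ``group2`` are boolean masks or obs-name collections; they
    must be nonempty and disjoint.  log2fc = log2((m1+eps)/(m2+eps)) with
    m = mean of expm1(normalized expression).  Bonferroni uses the number
    of genes tested here.
    """
    m1 = _as_mask(adata, group1)
    m2 = _as_mask(adata, group2)
    if not m1.any() or not m2.any():
        raise ConfigurationError("both groups must be nonempty")
    if (m1 & m2).any():
        raise ConfigurationError("groups overlap")
    x1 = _dense(adata[m1].X)
    x2 = _dense(adata[m2].X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = mannwhitneyu(
            x1, x2, axis=0, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = np.asarray(res.pvalue, dtype=float)
    # genes constant across both groups: no evidence either way
    allsame = (x1.min(axis=0) == x1.max(axis=0)) & (x2.min(axis=0) == x2.max(axis=0)) & (
        x1.min(axis=0) == x2.min(axis=0)
    )
    p = np.where(allsame | ~np.isfinite(p), 1.0, p)
    mean1 = np.expm1(x1).mean(axis=0)
    mean2 = np.expm1(x2).mean(axis=0)
    log2fc = np.log2((mean1 + LOG2FC_EPS) / (mean2 + LOG2FC_EPS))
    n_tests = adata.n_vars
    p_adj = np.minimum(1.0, p * n_tests)
    table = pd.DataFrame(
        {
            "gene": adata.var_names,
            "group1": group1_name,
            "group2": group2_name,
            "log2fc": log2fc,
            "p_value": p,
            "p_adjusted": p_adj,
            "pct1": (x1 > 0).mean(axis=0),
            "pct2": (x2 > 0).mean(axis=0),
        }
    )
    table["significant"] = (table["p_adjusted"] < alpha) & (table["log2fc"].abs() > min_lfc)
    return table


def _as_mask(adata: ad.AnnData, group) -> np.ndarray:
    arr = np.asarray(group)
    if arr.dtype == bool and arr.shape == (adata.n_obs,):
        return arr
    names = set(map(str, arr.tolist()))
    return adata.obs_names.isin(names)


def find_all_markers(
    adata: ad.AnnData,
    labels,
    alpha: float = 0.05,
    min_lfc: float = 0.25,
    min_cells: int = 3,
) -> dict[str, pd.DataFrame]:
    """One-vs-rest Wilcoxon DE for every cell type.

    Returns a DE table per type; its ``is_marker`` column flags genes
    passing both thresholds with positive fold change.  Types with fewer
    than ``min_cells`` cells are skipped with a warning.
    """
    labels = pd.Series(np.asarray(labels), index=adata.obs_names)
    types = sorted(labels.unique())
    if len(types) < 2:
        raise ConfigurationError("find_all_markers needs at least 2 cell types")
    out: dict[str, pd.DataFrame] = {}
    for t in types:
        mask = (labels == t).to_numpy()
        if mask.sum() < min_cells:
            warnings.warn(f"cell type {t!r} has {int(mask.sum())} < {min_cells} cells; skipped")
            continue
        table = wilcoxon_de(
            adata, mask, ~mask, alpha=alpha, min_lfc=min_lfc,
            group1_name=t, group2_name="rest",
        )
        table["is_marker"] = table["significant"] & (table["log2fc"] > min_lfc)
        out[t] = table
    return out


def marker_lists(de_tables: dict[str, pd.DataFrame]) -> dict[str, list[str]]:
    """Extract the positive marker gene lists from `find_all_markers` output."""
    return {
        t: sorted(tab.loc[tab["is_marker"], "gene"]) for t, tab in de_tables.items()
    }


@dataclass
class MarkerPartition:
    """Cross-species split of cell-type markers (reference gene symbols)."""

    conserved: dict[str, list[str]] = field(default_factory=dict)
    species_specific: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    intermediate: dict[str, list[str]] = field(default_factory=dict)
    n_unmapped: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "conserved": self.conserved,
            "species_specific": self.species_specific,
            "intermediate": self.intermediate,
            "n_unmapped": self.n_unmapped,
        }


def partition_markers(
    markers: dict[str, dict[str, list[str]]],
    table: pd.DataFrame,
    species_list: list[str],
) -> MarkerPartition:
    """Split per-species markers into conserved / species-specific / intermediate.

    ``markers`` maps species -> cell type -> species gene ids.  Ids are
    translated to reference symbols through the one-to-one rows of
    ``table``; unmapped ids are excluded and counted.  Per cell type:
    conserved genes are markers in every listed species; species-specific
    genes are markers in exactly one; the rest are intermediate.  The three
    buckets are disjoint and cover the mapped union.
    """
    missing = [s for s in species_list if s not in markers]
    if missing:
        raise ConfigurationError(f"marker lists missing for species: {missing}")
    one = table[table["homology_type"] == ONE2ONE]
    lut = {
        s: one[one["species"] == s].set_index("species_gene")["ref_gene"].to_dict()
        for s in species_list
    }
    part = MarkerPartition()
    all_types = sorted({t for s in species_list for t in markers[s]})
    for ctype in all_types:
        ref_sets: dict[str, set[str]] = {}
        for s in species_list:
            genes = markers[s].get(ctype, [])
            mapped = {lut[s][g] for g in genes if g in lut[s]}
            part.n_unmapped[s] = part.n_unmapped.get(s, 0) + sum(
                1 for g in genes if g not in lut[s]
            )
            ref_sets[s] = mapped
        union = set().union(*ref_sets.values())
        counts = {g: sum(g in ref_sets[s] for s in species_list) for g in union}
        conserved = {g for g, c in counts.items() if c == len(species_list)}
        part.conserved[ctype] = sorted(conserved)
        part.species_specific[ctype] = {
            s: sorted(g for g in ref_sets[s] if counts[g] == 1 and len(species_list) > 1)
            for s in species_list
        }
        specific_union = {
            g for s in species_list for g in part.species_specific[ctype][s]
        }
        part.intermediate[ctype] = sorted(union - conserved - specific_union)
    return part
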