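"""One-to-one ortholog filtering and multi-species harmonization.

Cross-species comparison requires a common gene space.  Following the
standard practice for vertebrate atlas comparisons, only genes annotated as
``one2one_ortholog`` in *every* analysed species are retained, and each
species matrix is re-indexed to the reference-species symbols in a single
shared order.  Expression values are never altered — genes are only
selected and renamed; genes mapped in the table but absent from any
species' matrix are dropped globally (zero-filling would fabricate absence
signal) and reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyResultError

__all__ = ["filter_one2one", "harmonize_datasets", "MultiSpeciesDataset"]

ONE2ONE = "one2one_ortholog"


def filter_one2one(table: pd.DataFrame, species_list: list[str]) -> pd.DataFrame:
    """Keep reference genes that are one-to-one orthologs in every species.

    Returns the surviving (ref_gene, species) rows for the listed species,
    sorted by ``ref_gene``.
    """
    if not species_list:
        raise ConfigurationError("species_list is empty")
    have = set(table["species"].unique())
    missing = [s for s in species_list if s not in have]
    if missing:
        raise ConfigurationError(f"species absent from ortholog table: {missing}")
    sub = table[table["species"].isin(species_list) & (table["homology_type"] == ONE2ONE)]
    counts = sub.groupby("ref_gene")["species"].nunique()
    keep = counts[counts == len(species_list)].index
    out = sub[sub["ref_gene"].isin(keep)].sort_values(["ref_gene", "species"])
    dup = out.duplicated(subset=["ref_gene", "species"])
    if dup.any():
        bad = out.loc[dup, "ref_gene"].unique()[:5]
        raise ConfigurationError(
            f"ortholog table not one-to-one after filtering: duplicated (ref_gene, species) e.g. {list(bad)}"
        )
    return out.reset_index(drop=True)


@dataclass
class MultiSpeciesDataset:
    """Species matrices re-indexed to one shared ortholog gene order."""

    adata: ad.AnnData  # concatenated cells x shared ref genes
    species: list[str]
    genes: list[str]
    dropped_genes: list[str] = field(default_factory=list)

    def per_species(self, species: str) -> ad.AnnData:
        return self.adata[self.adata.obs["species"] == species]


def harmonize_datasets(
    matrices: dict[str, ad.AnnData], table: pd.DataFrame
) -> MultiSpeciesDataset:
    """Assemble per-species matrices into one shared-ortholog dataset.

    ``table`` must already be one-to-one filtered.  Each species matrix is
    restricted to its mapped genes, columns renamed to reference symbols and
    ordered identically across species; the result is a concatenated AnnData
    with ``obs["species"]``, ``obs["cell_type"]`` and a composite
    ``obs["group"]`` label.
    """
    if not matrices:
        raise ConfigurationError("no matrices supplied")
    mapped: dict[str, pd.Series] = {}
    for species, adata in matrices.items():
        sub = table[(table["species"] == species) & (table["homology_type"] == ONE2ONE)]
        if sub["ref_gene"].duplicated().any() or sub["species_gene"].duplicated().any():
            raise ConfigurationError(f"{species}: duplicated ref_gene or species_gene in table")
        lookup = sub.set_index("species_gene")["ref_gene"]
        present = lookup[lookup.index.isin(adata.var_names)]
        mapped[species] = present

    shared: set[str] | None = None
    for species, present in mapped.items():
        refs = set(present.values)
        shared = refs if shared is None else shared & refs
    all_mapped = set(table.loc[table["homology_type"] == ONE2ONE, "ref_gene"])
    if not shared:
        raise EmptyResultError("no shared ortholog genes across the supplied matrices")
    dropped = sorted(all_mapped - shared)
    if dropped:
        warnings.warn(
            f"{len(dropped)} mapped genes absent from at least one matrix; dropped globally"
        )

    gene_order = sorted(shared)
    pieces = []
    for species, adata in matrices.items():
        inverse = pd.Series(mapped[species].index.values, index=mapped[species].values)
        cols = inverse.loc[gene_order].values
        sub = adata[:, cols].copy()
        sub.var_names = gene_order
        sub.obs["species"] = species
        pieces.append(sub)
    merged = ad.concat(pieces, join="inner", merge="same", index_unique=None)
    merged.var_names = gene_order  # concat preserves order; make it explicit
    if "cell_type" in merged.obs:
        merged.obs["group"] = (
            merged.obs["species"].astype(str) + "|" + merged.obs["cell_type"].astype(str)
        )
    merged.uns["dropped_genes"] = dropped
    return MultiSpeciesDataset(
        adata=merged, species=list(matrices), genes=gene_order, dropped_genes=dropped
    )
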