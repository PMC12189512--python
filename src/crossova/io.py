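"""Readers and writers for the plain-text formats the pipeline exchanges.

All matrices follow the 10x Genomics convention on disk (genes as MTX rows,
cells as columns); in memory every matrix is cells x genes inside an
:class:`anndata.AnnData`.  These converters are the only place orientation
changes.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .exceptions import ParseError

__all__ = [
    "read_tenx",
    "write_tenx",
    "read_gmt",
    "write_gmt",
    "read_ortholog_tsv",
    "write_ortholog_tsv",
    "read_cell_meta",
    "write_cell_meta",
]

ORTHOLOG_COLUMNS = ["ref_gene", "species", "species_gene", "homology_type"]


def read_tenx(directory: str | Path) -> ad.AnnData:
    """Read a 10x-style MTX triplet (matrix.mtx, features.tsv, barcodes.tsv).

    Returns an AnnData of cells x genes with integer CSR counts; the second
    features column, when present, lands in ``var["symbol"]``.
    """
    directory = Path(directory)
    mtx_path = directory / "matrix.mtx"
    try:
        m = scipy.io.mmread(mtx_path)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ParseError(f"malformed MTX file {mtx_path}: {exc}") from exc
    m = sp.csr_matrix(m.T)  # disk is genes x cells

    features = pd.read_csv(directory / "features.tsv", sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None, dtype=str)
    if len(barcodes) != m.shape[0]:
        raise ParseError(
            f"{directory}: barcodes.tsv has {len(barcodes)} entries but "
            f"matrix.mtx has {m.shape[0]} columns"
        )
    if len(features) != m.shape[1]:
        raise ParseError(
            f"{directory}: features.tsv has {len(features)} entries but "
            f"matrix.mtx has {m.shape[1]} rows"
        )
    var = pd.DataFrame(index=pd.Index(features[0].values, name="gene_id"))
    if features.shape[1] > 1:
        var["symbol"] = features[1].values
    adata = ad.AnnData(
        X=m.astype(np.int64),
        obs=pd.DataFrame(index=pd.Index(barcodes[0].values, name="barcode")),
        var=var,
    )
    return adata


def write_tenx(adata: ad.AnnData, directory: str | Path) -> None:
    """Write the raw matrix of ``adata`` as an uncompressed 10x MTX triplet."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    x = adata.layers.get("counts", adata.X)
    x = sp.coo_matrix(sp.csr_matrix(x).T)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), x, field="integer")
    feats = pd.DataFrame({"id": adata.var_names})
    feats["symbol"] = (
        adata.var["symbol"].values if "symbol" in adata.var else adata.var_names
    )
    feats.to_csv(directory / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into ``{set_name: [genes]}`` (description column ignored)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene (got {len(parts)} fields)"
                )
            name, _desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = ".") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_ortholog_tsv(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ORTHOLOG_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: ortholog table missing columns {missing}")
    return table[ORTHOLOG_COLUMNS]


def write_ortholog_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table[ORTHOLOG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_cell_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("barcode", "species", "replicate", "cell_type"):
        if col not in meta.columns:
            raise ParseError(f"{path}: cell metadata missing column {col!r}")
    return meta.set_index("barcode")


def write_cell_meta(meta: pd.DataFrame, path: str | Path) -> None:
    out = meta.reset_index().rename(columns={"index": "barcode"})
    if "barcode" not in out.columns:
        out.insert(0, "barcode", meta.index)
    out.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_jsonify)


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
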