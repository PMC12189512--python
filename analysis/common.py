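"""Shared setup for the numbered analysis drivers.

The demo study: three synthetic species sharing conserved ovary cell-type
programs (endothelial, granulosa, immune, theca), one species ("spC")
carrying a private granulosa program, planted TF regulons and planted
pathway shifts.  Stage drivers read the simulated data from
``<out>/data`` and write their tables next to it.
"""

from __future__ import annotations

import argparse
import warnings
from pathlib import Path

from crossova import io as cio
from crossova.qc import filter_cells_genes, normalize_log
from crossova.synthetic import SpeciesConfig, generate_dataset

warnings.filterwarnings("ignore")

SEED = 20260101 % (2**31 - 1)
SPECIES = ["spA", "spB", "spC"]
CELL_TYPES = {"endothelial": 0.25, "granulosa": 0.25, "immune": 0.25, "theca": 0.25}
N_CELLS = 600
N_GENES = 500
N_REGULONS = 12
N_PATHWAYS = 10
MIN_GENES = 100  # QC floor scaled to the 500-gene demo panel


def parse_out(description: str) -> Path:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--out", type=Path, default=Path("results"))
    return ap.parse_args().out


def simulate():
    configs = [
        SpeciesConfig(s, N_CELLS, dict(CELL_TYPES), species_effect_sd=0.0)
        for s in SPECIES
    ]
    return generate_dataset(
        configs,
        n_genes=N_GENES,
        n_regulons=N_REGULONS,
        n_pathways=N_PATHWAYS,
        seed=SEED,
        species_specific_programs={"spC": ["granulosa"]},
    )


def load_raw(out: Path) -> dict:
    adatas = {}
    for s in SPECIES:
        adata = cio.read_tenx(out / "data" / s)
        meta = cio.read_cell_meta(out / "data" / s / "cell_meta.tsv")
        adata.obs = adata.obs.join(meta)
        adatas[s] = adata
    return adatas


def load_normalized(out: Path) -> dict:
    return {
        s: normalize_log(filter_cells_genes(a, min_genes=MIN_GENES))
        for s, a in load_raw(out).items()
    }


def load_harmonized(out: Path):
    from crossova.orthologs import filter_one2one, harmonize_datasets

    norm = load_normalized(out)
    table = filter_one2one(cio.read_ortholog_tsv(out / "data" / "orthologs.tsv"), SPECIES)
    return norm, table, harmonize_datasets(norm, table)
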