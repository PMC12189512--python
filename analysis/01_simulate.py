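"""Simulate the three-species demo dataset and write it to <out>/data.

Writes per-species 10x MTX triplets with cell metadata, the ortholog table,
pathway and regulon gene sets, and the planted ground truth.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common
from crossova import io as cio


def main() -> None:
    out = common.parse_out(__doc__)
    data = out / "data"
    ds = common.simulate()
    for s, adata in ds.adatas.items():
        cio.write_tenx(adata, data / s)
        cio.write_cell_meta(
            adata.obs[["species", "replicate", "cell_type"]], data / s / "cell_meta.tsv"
        )
    cio.write_ortholog_tsv(ds.ortholog_table, data / "orthologs.tsv")
    cio.write_gmt(ds.pathways, data / "pathways.gmt")
    cio.write_gmt(ds.ground_truth.regulon_sets(), data / "regulons.gmt")
    truth = ds.ground_truth
    cio.write_json(
        {
            "conserved_markers": truth.conserved_markers,
            "species_specific_markers": {
                f"{s}|{t}": v for (s, t), v in truth.species_specific_markers.items()
            },
            "regulons": truth.regulons,
            "pathway_effects": {
                f"{p}|{t}|{s}": e for (p, t, s), e in truth.pathway_effects.items()
            },
        },
        data / "ground_truth.json",
    )
    n = sum(a.n_obs for a in ds.adatas.values())
    print(f"simulated {n} cells in {len(ds.adatas)} species, "
          f"{common.N_GENES} genes, {common.N_REGULONS} regulons, "
          f"{common.N_PATHWAYS} pathways -> {data}")


if __name__ == "__main__":
    main()
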