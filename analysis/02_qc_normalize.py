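"""QC-filter each species, report what was removed, and rank variable genes.

Cells need >= 100 detected genes (of the 500-gene demo panel) and <= 10%
mitochondrial counts; genes must be detected in >= 3 surviving cells.
Writes the per-species QC report and vst HVG tables.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common
from crossova.qc import filter_cells_genes, normalize_log, select_hvg


def main() -> None:
    out = common.parse_out(__doc__)
    reports, hvg_frames = [], []
    for s, adata in common.load_raw(out).items():
        filtered = filter_cells_genes(adata, min_genes=common.MIN_GENES)
        rep = {"species": s, **filtered.uns["qc_report"]}
        reports.append(rep)
        norm = normalize_log(filtered)
        hvg = select_hvg(norm, n_top=200, batch_key="replicate")
        hvg.insert(0, "species", s)
        hvg_frames.append(hvg)
        print(
            f"{s}: removed {rep['cells_removed']}/{rep['cells_in']} cells "
            f"({rep['cells_removed_max_mito']} over the mito bound), "
            f"{rep['genes_removed']} genes"
        )
    pd.DataFrame(reports).to_csv(out / "qc_report.csv", index=False)
    pd.concat(hvg_frames).to_csv(out / "hvg_tables.csv", index=False)
    print(f"wrote {out / 'qc_report.csv'} and {out / 'hvg_tables.csv'}")


if __name__ == "__main__":
    main()
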