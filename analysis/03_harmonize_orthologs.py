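"""Restrict all species to the shared one-to-one ortholog space.

Mirrors the standard cross-species protocol: keep genes annotated
one2one_ortholog in every species, re-index each matrix to reference
symbols in one shared order.  Writes the shared gene list.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import common


def main() -> None:
    out = common.parse_out(__doc__)
    _, table, multi = common.load_harmonized(out)
    pd.Series(multi.genes, name="ref_gene").to_csv(out / "shared_genes.csv", index=False)
    print(
        f"{table['ref_gene'].nunique()} one-to-one orthologs across {len(common.SPECIES)} "
        f"species; {len(multi.genes)} present in every matrix "
        f"({len(multi.dropped_genes)} dropped), {multi.adata.n_obs} cells total"
    )


if __name__ == "__main__":
    main()
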