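"""Wilcoxon markers per species and the conserved / species-specific split.

One-vs-rest Wilcoxon (Bonferroni p < 0.05, |log2FC| > 0.25, positive side)
per species, mapped through the one-to-one ortholog table.  The planted
design predicts: every conserved program gene lands in the conserved
bucket, and spC's private granulosa program is returned as spC-specific.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import common
from crossova import io as cio
from crossova.markers import find_all_markers, marker_lists, partition_markers


def main() -> None:
    out = common.parse_out(__doc__)
    norm, table, _ = common.load_harmonized(out)
    found = {}
    for s, adata in norm.items():
        tables = find_all_markers(adata, adata.obs["cell_type"])
        found[s] = marker_lists(tables)
        n = sum(len(v) for v in found[s].values())
        print(f"{s}: {n} markers across {len(found[s])} cell types")
    part = partition_markers(found, table, common.SPECIES)
    cio.write_json(part.to_dict(), out / "marker_partition.json")

    truth = json.load(open(out / "data" / "ground_truth.json"))
    planted = set(truth["species_specific_markers"].get("spC|granulosa", []))
    got = set(part.species_specific["granulosa"]["spC"])
    print(f"conserved granulosa markers: {len(part.conserved['granulosa'])}; "
          f"spC-specific recovered {len(got & planted)}/{len(planted)} planted "
          f"({'exact' if got == planted else 'with extras'})")


if __name__ == "__main__":
    main()
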