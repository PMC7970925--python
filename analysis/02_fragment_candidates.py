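#!/usr/bin/env python
"""Enumerate candidate fragment structures for the observed product-ion
masses (m/z 69, 95, 121, 143 and the 379 parent) and compare them with the
packaged annotations.

Finding: every packaged annotation appears among the combinatorially
enumerated candidates for its mass (<= 3 skeleton bond cleavages, hydrogen
rearrangement slack +/-2), and the 379 parent is uniquely the whole
28-carbon skeleton.
"""

from pathlib import Path

import pandas as pd

from ergolabel import load_atlas
from ergolabel.fragments import (
    enumerate_fragments,
    format_carbon_set,
    packaged_annotations_path,
    read_annotations,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    atlas = load_atlas()
    parent = atlas.molecule("ergosterol")
    annotations = {a.nominal_mz: a for a in read_annotations(packaged_annotations_path(), parent)}

    rows = []
    for mz in sorted(annotations):
        candidates = enumerate_fragments(parent, mz)
        ann = annotations[mz]
        hit = next((c for c in candidates if c.carbons == ann.carbons), None)
        print(
            f"m/z {mz}: {len(candidates)} candidates; packaged annotation "
            f"{format_carbon_set(ann.carbons)} "
            + (f"found at rank {hit.rank}" if hit else "NOT among candidates")
        )
        rows.extend(
            {
                "nominal_mz": c.nominal_mz,
                "rank": c.rank,
                "formula": c.formula,
                "carbons": format_carbon_set(c.carbons),
                "n_cleavages": c.n_cleavages,
                "is_packaged_annotation": c.carbons == ann.carbons,
            }
            for c in candidates
        )
    pd.DataFrame(rows).to_csv(OUT / "fragment_candidates.tsv", sep="\t", index=False)
    print(f"wrote {OUT / 'fragment_candidates.tsv'} ({len(rows)} rows)")


if __name__ == "__main__":
    main()
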