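#!/usr/bin/env python
"""Parameter-recovery validation: simulate spectrum pairs under known
hypotheses, read apparent shifts, classify, and score.

Finding (seed 1, n = 1e5 molecules, 5% detection threshold): at full tracer
enrichment (0.985), 4/5 fragments recover the generating hypothesis under
either route (the whole-skeleton parent envelope is truncated by the
detection threshold and stays unexplained); recovery degrades monotonically
as enrichment drops to 0.2.
"""

from pathlib import Path

from ergolabel import Hypothesis, load_atlas
from ergolabel.fragments import packaged_annotations_path, read_annotations
from ergolabel.simulate import recovery_experiment

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    atlas = load_atlas()
    parent = atlas.molecule("ergosterol")
    annotations = read_annotations(packaged_annotations_path(), parent)

    table = recovery_experiment(
        atlas,
        hypotheses=(Hypothesis("MVA"), Hypothesis("MEP")),
        enrichments=(0.2, 0.5, 0.985),
        fragments=annotations,
        n_molecules=100_000,
        seed=1,
    )
    table.to_csv(OUT / "recovery.tsv", sep="\t", index=False)
    print(table.to_string(index=False))
    print(f"wrote {OUT / 'recovery.tsv'}")


if __name__ == "__main__":
    main()
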