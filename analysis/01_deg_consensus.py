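#!/usr/bin/env python
"""Consensus differential-expression statistics.

Builds the five-caller DEG set family (two NOISeq thresholds, two GFold
thresholds, EdgeR) with the published per-method totals and unique counts,
and summarizes how much each caller overlaps the others.  The headline
numbers: EdgeR is the least consensual caller (~5% private genes), the
stricter NOISeq run is almost fully contained in the union of the others,
and the all-method core holds 10,627 genes.
"""

from pathlib import Path

from devgrn.fixtures import deg_set_family
from devgrn.preprocess import overlap_stats

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sets = deg_set_family()
    stats = overlap_stats(sets)
    OUT.mkdir(exist_ok=True)
    table = stats.to_frame()
    table.to_csv(OUT / "deg_overlap.csv", index=False)
    print(table.to_string(index=False))
    print(f"\ncore intersection (all methods): {stats.core_intersection_size} genes")
    print(f"wrote {OUT / 'deg_overlap.csv'}")


if __name__ == "__main__":
    main()
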