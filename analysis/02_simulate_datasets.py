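#!/usr/bin/env python
"""Generate the two synthetic developmental time courses.

Emulates the study's sampling regimes: a dense course (34 timepoints every
2 h, duplicated measurements) and a sparse 10-timepoint course over
0-72 hpf (single replicate), both drawn from random signed regulatory
networks with decaying maternal transcripts and 10% multiplicative noise.
Writes the expression tables, metadata, TF lists and true edge lists under
results/data/.
"""

from pathlib import Path

from devgrn.fixtures import dense_fixture, sparse_fixture
from devgrn.io import write_edge_list, write_expression, write_gene_set

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for tag, maker in (("dense", dense_fixture), ("sparse", sparse_fixture)):
        expr, meta, truth, net, cfg = maker(seed=SEED)
        write_expression(expr, OUT / f"{tag}_expr.tsv", meta, OUT / f"{tag}_meta.tsv")
        write_edge_list(truth, OUT / f"{tag}_truth.csv")
        write_gene_set(net.tf_ids, OUT / f"{tag}_tfs.txt")
        print(f"{tag}: {expr.shape[0]} genes x {expr.shape[1]} samples, "
              f"{len(truth)} true edges, {len(net.tf_ids)} TFs")
    print(f"wrote datasets under {OUT}")


if __name__ == "__main__":
    main()
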