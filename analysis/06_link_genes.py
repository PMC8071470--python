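"""Nominate representative genes per functional category by repetition.

Categories are the top-level ancestors of the synthetic ontology: each
groups the gene sets below it.  Within a category, genome-wide DEGs are
intersected with the member sets' genes and ranked by how many of those
sets contain them; recurrent genes are the category's representatives.
"""

import argparse
import sys
from pathlib import Path

import networkx as nx
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohort import DATA_DIR, RESULTS_DIR

from functionome.data_io import read_gmt, read_obo
from functionome.linkage import rank_repetition, repetitions_to_frame, top_k
from functionome.stats import GeneTestResult


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=DATA_DIR)
    parser.add_argument("--out-dir", type=Path, default=RESULTS_DIR)
    parser.add_argument("--top", type=int, default=10)
    args = parser.parse_args()

    collection = read_gmt(args.data_dir / "gene_sets.gmt")
    graph = read_obo(args.data_dir / "ontology.obo")
    df = pd.read_csv(args.out_dir / "gene_tests.tsv", sep="\t")
    degs = [
        GeneTestResult(gene_id=r["id"], u_statistic=r["U"], p_raw=r["p"], q=r["q"],
                       significant=bool(r["significant"]))
        for _, r in df.iterrows()
    ]

    roots = [n for n in graph.nodes if graph.out_degree(n) == 0]
    frames = []
    for root in sorted(roots):
        members = sorted(
            t for t in nx.ancestors(graph, root) if t in collection
        )  # leaves below this root (edges point child -> parent)
        if not members:
            continue
        reps = top_k(rank_repetition(members, collection, degs), args.top)
        frames.append(repetitions_to_frame(reps, category=root))
        if reps:
            lead = reps[0]
            print(f"{root:<14} {len(members):>3} sets; top gene {lead.gene_id} "
                  f"(in {lead.n_sets} sets, best q {lead.best_q:.2e})")
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(args.out_dir / "linked_genes.tsv", sep="\t", index=False)
    print(f"{len(table)} category-linked representative genes -> linked_genes.tsv")


if __name__ == "__main__":
    main()
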