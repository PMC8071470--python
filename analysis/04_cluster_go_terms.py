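"""Cluster significant terms in the ontology and rank clusters by CWI.

Per case group, groups the significant sets under their highest significant
ancestors in the synthetic is_a DAG, ranks clusters by cluster weight index
(each cluster's -log10(p) weight share), and derives the terms common to
every group's top-k list with their per-group ranks.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohort import DATA_DIR, RESULTS_DIR

from functionome.clustering import build_clusters, clusters_to_frame, common_top_terms, rank_clusters
from functionome.data_io import read_gmt, read_obo
from functionome.stats import SetTestResult


def load_results(path: Path) -> list[SetTestResult]:
    df = pd.read_csv(path, sep="\t")
    return [
        SetTestResult(set_id=r["id"], u_statistic=r["U"], p_raw=r["p"], q=r["q"],
                      significant=bool(r["significant"]), direction=int(r["direction"]))
        for _, r in df.iterrows()
    ]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=DATA_DIR)
    parser.add_argument("--out-dir", type=Path, default=RESULTS_DIR)
    parser.add_argument("--top-k", type=int, default=50)
    args = parser.parse_args()

    graph = read_obo(args.data_dir / "ontology.obo")
    collection = read_gmt(args.data_dir / "gene_sets.gmt")
    names = {gs.set_id: gs.name for gs in collection}

    heads_per_group: dict[str, list[str]] = {}
    for path in sorted(args.out_dir.glob("set_tests_*.tsv")):
        group = path.stem.removeprefix("set_tests_")
        sig = [r for r in load_results(path) if r.significant]
        if not sig:
            print(f"{group}: no significant terms, skipped")
            continue
        ranked = rank_clusters(build_clusters(sig, graph))
        frame = clusters_to_frame(ranked, names)
        frame.to_csv(args.out_dir / f"clusters_{group}.tsv", sep="\t", index=False)
        heads_per_group[group] = [c.head_term for c in ranked]
        top = ranked[0]
        print(f"{group:<14} {len(ranked)} clusters from {len(sig)} terms; "
              f"top: {top.head_term} (CWI {top.cwi:.4f}, {len(top.members)} members)")

    if len(heads_per_group) >= 2:
        common = common_top_terms(heads_per_group, k=args.top_k)
        common.to_csv(args.out_dir / "common_terms.tsv", sep="\t", index=False)
        print(f"common top-{args.top_k} terms across {len(heads_per_group)} groups: {len(common)}")


if __name__ == "__main__":
    main()
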