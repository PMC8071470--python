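"""Simulate the study cohort and write it out as plain files.

Emits the expression table, sample labels (with subtypes), the gene set
collection (GMT), a synthetic is_a ontology over the sets (OBO), and the
ground-truth record of which sets were dysregulated.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from cohort import DATA_DIR, build_cohort

from functionome.data_io import write_expression_table, write_gmt, write_labels


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--out-dir", type=Path, default=DATA_DIR)
    args = parser.parse_args()

    matrix, collection, ontology, truth = build_cohort(args.seed)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    write_expression_table(matrix, args.out_dir / "expression.tsv")
    write_labels(matrix, args.out_dir / "labels.tsv")
    write_gmt(collection, args.out_dir / "gene_sets.gmt")
    truth.to_json(args.out_dir / "truth.json")
    with open(args.out_dir / "ontology.obo", "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n\n")
        for node in ontology.nodes:
            fh.write(f"[Term]\nid: {node}\nname: {ontology.nodes[node].get('name', node)}\n")
            for parent in ontology.successors(node):
                fh.write(f"is_a: {parent}\n")
            fh.write("\n")

    n_case = len(matrix.case_ids)
    n_ctrl = len(matrix.control_ids)
    print(f"cohort: {matrix.values.shape[0]} genes x {n_case} cases + {n_ctrl} controls")
    print(f"gene sets: {len(collection)}; planted dysregulated: {len(truth.planted_set_ids)}")
    print(f"wrote expression/labels/GMT/OBO/truth to {args.out_dir}")


if __name__ == "__main__":
    main()
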