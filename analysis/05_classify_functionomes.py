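"""Classify functionome patterns case-vs-control with a repeated-CV SVM.

Per case group against the shared controls: stratified 5-fold RBF-SVM
cross-validation repeated 10 times over the GSR columns, reporting the
mean (SD) of sensitivity, specificity and accuracy and the mean AUC.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohort import DATA_DIR, RESULTS_DIR, case_groups

from functionome.classify import cv_classify
from functionome.data_io import read_expression_table, read_labels
from functionome.gsr import Functionome


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=DATA_DIR)
    parser.add_argument("--out-dir", type=Path, default=RESULTS_DIR)
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--folds", type=int, default=5)
    parser.add_argument("--repeats", type=int, default=10)
    args = parser.parse_args()

    groups, subtypes, platforms = read_labels(args.data_dir / "labels.tsv")
    matrix = read_expression_table(args.data_dir / "expression.tsv", groups, subtypes, platforms)
    gsr = pd.read_csv(args.out_dir / "functionome.tsv", sep="\t", index_col=0)
    functionome = Functionome(gsr=gsr, skipped=pd.DataFrame())

    frames = []
    for name, ids in case_groups(matrix).items():
        keep = ids + matrix.control_ids
        sub = Functionome(gsr=functionome.gsr.loc[keep], skipped=functionome.skipped)
        report = cv_classify(
            sub, matrix.groups.reindex(keep), n_folds=args.folds,
            n_repeats=args.repeats, seed=args.seed, group=name,
        )
        frames.append(report.to_frame())
        print(f"{name:<14} sens {report.sensitivity_mean:.4f} ({report.sensitivity_sd:.4f})  "
              f"spec {report.specificity_mean:.4f} ({report.specificity_sd:.4f})  "
              f"acc {report.accuracy_mean:.4f} ({report.accuracy_sd:.4f})  "
              f"AUC {report.auc:.4f}")
    pd.concat(frames, ignore_index=True).to_csv(
        args.out_dir / "classification.tsv", sep="\t", index=False
    )


if __name__ == "__main__":
    main()
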