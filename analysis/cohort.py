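"""Shared study design for the numbered analysis scripts.

One synthetic cohort mirroring the shape of a borderline-ovarian-tumour
microarray compendium: 92 case samples (79 serous-like + 13 mucinous-like)
against a shared pool of 136 controls, 200 GO-like gene sets of 10 genes
from a 1000-gene universe, with 25% of sets dysregulated in cases at
scramble strength 0.8 over per-sample noise of 0.3 SD.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from functionome.data_io import ExpressionMatrix
from functionome.synthetic import SyntheticConfig, generate_cohort, generate_collection, generate_ontology

DATA_DIR = Path("results/data")
RESULTS_DIR = Path("results")

SUBTYPE_SIZES = {"serous_like": 79, "mucinous_like": 13}
N_CONTROL = 136


def study_config(seed: int) -> SyntheticConfig:
    return SyntheticConfig(
        n_case=sum(SUBTYPE_SIZES.values()),
        n_control=N_CONTROL,
        n_genes=1000,
        n_sets=200,
        set_size_min=10,
        set_size_max=10,
        planted_fraction=0.25,
        scramble_strength=0.8,
        noise_sd=0.3,
        seed=seed,
    )


def build_cohort(seed: int):
    """Generate the study cohort with subtype labels attached."""
    cfg = study_config(seed)
    collection = generate_collection(cfg)
    matrix, truth = generate_cohort(cfg, collection)
    subtype_values = []
    for name, size in SUBTYPE_SIZES.items():
        subtype_values += [name] * size
    subtypes = pd.Series(
        subtype_values + [pd.NA] * cfg.n_control, index=matrix.sample_ids
    )
    matrix = ExpressionMatrix(values=matrix.values, groups=matrix.groups, subtypes=subtypes)
    ontology = generate_ontology(collection, depth=2, seed=seed)
    return matrix, collection, ontology, truth


def case_groups(matrix: ExpressionMatrix) -> dict[str, list[str]]:
    """The three nested case groups: all cases plus each subtype."""
    groups = {"all_cases": matrix.case_ids}
    for name in SUBTYPE_SIZES:
        groups[name] = list(matrix.subtypes.index[matrix.subtypes == name])
    return groups
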