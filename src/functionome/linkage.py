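"""Representative-gene selection by repetition across a GO term category.

For a category of GO terms, the genes annotated to those terms (via the
gene set definitions) are intersected with the genome-wide DEGs; each
significant DEG is ranked by how many of the category's sets contain it
("repetition"), the idea being that a gene recurring across a category's
terms is a stronger candidate driver of that category's dysregulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .data_io import GeneSetCollection
from .stats import GeneTestResult

__all__ = ["GeneRepetition", "rank_repetition", "top_k", "repetitions_to_frame"]


@dataclass(frozen=True)
class GeneRepetition:
    gene_id: str
    n_sets: int
    best_q: float


def rank_repetition(
    category_terms,
    collection: GeneSetCollection,
    degs: list[GeneTestResult],
) -> list[GeneRepetition]:
    """Rank significant DEGs by membership count over the category's sets.

    Sort order: repetition count descending, then smallest q, then gene id.
    Only genes appearing in at least one category set are listed.
    """
    category_terms = list(category_terms)
    if not category_terms:
        raise ValueError("category_terms must be nonempty")
    missing = [t for t in category_terms if t not in collection]
    if missing:
        raise KeyError(f"category terms absent from collection: {missing}")
    sig = {r.gene_id: r for r in degs if r.significant}
    counts: dict[str, int] = {}
    for term in set(category_terms):
        for gene in collection[term].genes:
            if gene in sig:
                counts[gene] = counts.get(gene, 0) + 1
    reps = [
        GeneRepetition(gene_id=g, n_sets=n, best_q=float(sig[g].q))
        for g, n in counts.items()
    ]
    return sorted(reps, key=lambda r: (-r.n_sets, r.best_q, r.gene_id))


def top_k(reps: list[GeneRepetition], k: int) -> list[GeneRepetition]:
    """First k entries of a ranked repetition list (fewer if shorter)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return reps[:k]


def repetitions_to_frame(reps: list[GeneRepetition], category: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": range(1, len(reps) + 1),
            "gene": [r.gene_id for r in reps],
            "n_sets": [r.n_sets for r in reps],
            "best_q": [r.best_q for r in reps],
            "category": category,
        }
    )
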