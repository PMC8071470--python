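"""Gene set regularity (GSR) indices — a modified DIRAC statistic.

Each gene set with m measured genes is encoded, per sample, as the binary
vector of its m(m-1)/2 pairwise expression-order comparisons.  A rank
template is the per-pair majority bit over the control samples ("the most
common gene expression ordering" of the set in the normal state).  The GSR
index of a sample for a set is the fraction of its pair bits that match the
template: 1 means the set's internal ordering is exactly the normal
consensus, 0 means it is exactly opposite.  The functionome of a cohort is
the samples x sets matrix of GSR indices.

The statistic is purely ordinal: any strictly increasing transform of one
sample's expression values leaves its pair bits, and hence every GSR index,
unchanged.  Ties within a sample are broken by ascending gene-symbol order,
so the encoding is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, GeneSet, GeneSetCollection

__all__ = [
    "PairOrderVector",
    "RankTemplate",
    "Functionome",
    "measured_genes",
    "pair_orders",
    "pair_order_bits",
    "build_template",
    "gsr_index",
    "build_functionome",
    "corrected_group_mean",
]

MIN_MEASURED_GENES = 2  # a 1-gene set has no pairs and is not retained


@dataclass(frozen=True)
class PairOrderVector:
    """Pairwise-order encoding of one sample over one gene set."""

    set_id: str
    genes: tuple[str, ...]            # measured genes, collection order
    bits: np.ndarray                  # uint8, length m(m-1)/2

    @property
    def pairs(self) -> list[tuple[int, int]]:
        m = len(self.genes)
        return [(i, j) for i in range(m) for j in range(i + 1, m)]


@dataclass(frozen=True)
class RankTemplate:
    """Majority pair-order pattern of the control group for one gene set."""

    set_id: str
    genes: tuple[str, ...]
    template_bits: np.ndarray         # uint8
    support: np.ndarray               # fraction of controls voting 1, per pair

    @property
    def pairs(self) -> list[tuple[int, int]]:
        m = len(self.genes)
        return [(i, j) for i in range(m) for j in range(i + 1, m)]


@dataclass
class Functionome:
    """Samples x gene sets matrix of GSR indices in [0, 1]."""

    gsr: pd.DataFrame                 # rows = samples, columns = set ids
    skipped: pd.DataFrame             # set_id, n_measured_genes, reason

    @property
    def sample_ids(self) -> list[str]:
        return list(self.gsr.index)

    @property
    def set_ids(self) -> list[str]:
        return list(self.gsr.columns)

    def to_tsv(self, path) -> None:
        out = self.gsr.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


def measured_genes(gene_set: GeneSet, matrix_genes) -> tuple[str, ...]:
    """The set's genes present in the expression matrix, collection order."""
    universe = set(matrix_genes)
    return tuple(g for g in gene_set.genes if g in universe)


def pair_order_bits(values: np.ndarray, genes: tuple[str, ...]) -> np.ndarray:
    """Pairwise order bits for m genes over n samples.

    ``values`` has shape (m,) or (m, n).  Bit for pair (i, j), i < j, is 1
    when expression of gene i is below gene j; an exact tie falls back to
    ascending gene-symbol order so that the comparison is a strict total
    order within every sample.
    """
    vals = np.asarray(values, dtype=float)
    squeeze = vals.ndim == 1
    if squeeze:
        vals = vals[:, None]
    m = vals.shape[0]
    iu, ju = np.triu_indices(m, k=1)
    tie_break = np.array([genes[i] < genes[j] for i, j in zip(iu, ju)], dtype=bool)
    vi, vj = vals[iu], vals[ju]
    bits = (vi < vj) | ((vi == vj) & tie_break[:, None])
    bits = bits.astype(np.uint8)
    return bits[:, 0] if squeeze else bits


def pair_orders(
    sample_values: pd.Series | dict,
    gene_set: GeneSet,
    matrix_genes,
) -> PairOrderVector | None:
    """Encode one sample's expression over one gene set.

    Genes absent from the matrix are dropped from the set (consistently for
    all samples).  Returns None when fewer than two genes are measured: such
    a set is not retained and is recorded in the skip log by the caller.
    """
    genes = measured_genes(gene_set, matrix_genes)
    if len(genes) < MIN_MEASURED_GENES:
        return None
    sample_values = pd.Series(sample_values)
    vals = sample_values.reindex(list(genes)).to_numpy(dtype=float)
    return PairOrderVector(
        set_id=gene_set.set_id, genes=genes, bits=pair_order_bits(vals, genes)
    )


def build_template(controls: ExpressionMatrix | pd.DataFrame, gene_set: GeneSet) -> RankTemplate:
    """Majority pairwise ordering of a gene set over control samples.

    ``support`` is the fraction of controls with bit 1 per pair; the template
    bit is 1 whenever support >= 0.5 (ties at exactly 0.5 vote 1, a fixed
    convention).
    """
    if isinstance(controls, ExpressionMatrix):
        values = controls.values[controls.control_ids]
    else:
        values = controls
    if values.shape[1] == 0:
        raise ValueError(f"no control samples to build template for {gene_set.set_id!r}")
    genes = measured_genes(gene_set, values.index)
    if len(genes) < MIN_MEASURED_GENES:
        raise ValueError(f"gene set {gene_set.set_id!r} has <2 measured genes")
    bits = pair_order_bits(values.loc[list(genes)].to_numpy(dtype=float), genes)
    support = bits.mean(axis=1)
    return RankTemplate(
        set_id=gene_set.set_id,
        genes=genes,
        template_bits=(support >= 0.5).astype(np.uint8),
        support=support,
    )


def gsr_index(sample: PairOrderVector, template: RankTemplate) -> float:
    """Fraction of a sample's pair orderings matching the control template."""
    if sample.set_id != template.set_id or sample.genes != template.genes:
        raise ValueError(
            f"pair-list mismatch: sample {sample.set_id!r}/{sample.genes} vs "
            f"template {template.set_id!r}/{template.genes}"
        )
    return float((sample.bits == template.template_bits).mean())


def build_functionome(
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    leave_one_out: bool = False,
) -> Functionome:
    """Score every sample against control-derived templates for every set.

    Templates are built from the control group only; cases and controls are
    both scored against them.  With ``leave_one_out`` each control is scored
    against the template rebuilt from the other controls, removing the small
    upward bias of scoring a sample against a consensus it voted in.  Sets
    with fewer than two measured genes are excluded and logged.
    """
    control_ids = matrix.control_ids
    if not control_ids:
        raise ValueError("functionome requires at least one control sample")
    values = matrix.values
    ctrl_pos = np.array([values.columns.get_loc(s) for s in control_ids])
    all_vals = values.to_numpy(dtype=float)
    gene_pos = {g: k for k, g in enumerate(values.index)}

    n_controls = len(ctrl_pos)
    columns: dict[str, np.ndarray] = {}
    skipped: list[tuple[str, int, str]] = []
    for gs in collection:
        genes = measured_genes(gs, values.index)
        m = len(genes)
        if m < MIN_MEASURED_GENES:
            skipped.append((gs.set_id, m, "fewer than 2 measured genes"))
            continue
        rows = np.array([gene_pos[g] for g in genes])
        bits = pair_order_bits(all_vals[rows], genes)        # (n_pairs, n_samples)
        ctrl_bits = bits[:, ctrl_pos]
        votes = ctrl_bits.sum(axis=1)                        # controls voting 1
        template = (votes >= n_controls / 2.0).astype(np.uint8)
        gsr = (bits == template[:, None]).mean(axis=0)
        if leave_one_out and n_controls > 1:
            loo_votes = votes[:, None] - ctrl_bits           # (n_pairs, n_controls)
            loo_template = loo_votes >= (n_controls - 1) / 2.0
            gsr[ctrl_pos] = (ctrl_bits == loo_template).mean(axis=0)
        columns[gs.set_id] = gsr
    if not columns:
        raise ValueError("no gene set retained (all have <2 measured genes)")
    gsr_df = pd.DataFrame(columns, index=values.columns)
    skip_df = pd.DataFrame(skipped, columns=["set_id", "n_measured_genes", "reason"])
    return Functionome(gsr=gsr_df, skipped=skip_df)


def corrected_group_mean(f: Functionome, samples) -> tuple[float, float]:
    """Mean and SD of all GSR entries over a sample subset.

    Reported for a case group alongside the same quantity for the control
    group, mirroring a cohort summary table.  SD uses the n-1 denominator.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample group")
    entries = f.gsr.loc[samples].to_numpy(dtype=float).ravel()
    sd = float(entries.std(ddof=1)) if entries.size > 1 else 0.0
    return float(entries.mean()), sd
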