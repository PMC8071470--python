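"""Readers/writers for the standard formats the pipeline touches.

Expression tables are plain TSV (genes x samples), gene set collections are
GMT, and the ontology is an OBO 1.2 flat file.  Multi-platform inputs are
harmonized by gene-symbol intersection only: the downstream gene set
regularity statistic is ordinal within each sample, so cross-platform scale
differences are irrelevant and no normalization or batch correction is
applied.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx
import obonet
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "read_expression_table",
    "write_expression_table",
    "read_labels",
    "write_labels",
    "read_obo",
    "ancestors",
    "harmonize",
]


class FormatError(ValueError):
    """A file did not conform to its declared format."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample group labels.

    ``values`` is a DataFrame indexed by unique gene symbols with sample ids
    as columns.  ``groups`` maps every sample to ``"case"`` or ``"control"``;
    ``subtypes`` and ``platforms`` are optional free-text annotations.
    """

    values: pd.DataFrame
    groups: pd.Series
    subtypes: pd.Series | None = None
    platforms: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise FormatError("expression matrix contains missing values")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene symbols: {list(dups)[:5]}")
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = self.groups.index[self.groups.isna()]
            raise FormatError(f"samples without group label: {list(missing)[:5]}")
        bad = set(self.groups.unique()) - {"case", "control"}
        if bad:
            raise FormatError(f"group labels must be case/control, got {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def sample_ids_of(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    @property
    def control_ids(self) -> list[str]:
        return self.sample_ids_of("control")

    @property
    def case_ids(self) -> list[str]:
        return self.sample_ids_of("case")


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) < 1:
            raise ValueError(f"gene set {self.set_id!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.set_id!r} has duplicate genes")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet]
    source_tag: str = "GO"
    _index: dict[str, GeneSet] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for gs in self.sets:
            if gs.set_id in self._index:
                raise ValueError(f"duplicate set id {gs.set_id!r} in collection")
            self._index[gs.set_id] = gs

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self._index

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._index[set_id]

    @property
    def set_ids(self) -> list[str]:
        return [gs.set_id for gs in self.sets]


def read_gmt(path, source_tag: str = "GO") -> GeneSetCollection:
    """Read a GMT gene set collection (one set per line: id, description, genes...).

    Duplicate gene symbols within a line are dropped, keeping the first
    occurrence.  A line with fewer than three tab-separated fields is a
    format error reported with its line number.
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            set_id, name = fields[0], fields[1]
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets.append(GeneSet(set_id=set_id, name=name, genes=tuple(genes)))
    return GeneSetCollection(sets=sets, source_tag=source_tag)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.set_id, gs.name, *gs.genes]) + "\n")


def read_labels(path) -> tuple[pd.Series, pd.Series | None, pd.Series | None]:
    """Read a sample label TSV: sample_id, group[, subtype[, platform]]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: labels file needs >=2 columns")
    df = df.set_index(df.columns[0])
    groups = df.iloc[:, 0]
    subtypes = df.iloc[:, 1] if df.shape[1] >= 2 else None
    platforms = df.iloc[:, 2] if df.shape[1] >= 3 else None
    return groups, subtypes, platforms


def write_labels(matrix: ExpressionMatrix, path) -> None:
    cols = {"group": matrix.groups}
    if matrix.subtypes is not None:
        cols["subtype"] = matrix.subtypes
    if matrix.platforms is not None:
        cols["platform"] = matrix.platforms
    df = pd.DataFrame(cols)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_expression_table(
    path,
    labels: dict[str, str] | pd.Series,
    subtypes: dict[str, str] | pd.Series | None = None,
    platforms: dict[str, str] | pd.Series | None = None,
    collapse: str = "max",
) -> ExpressionMatrix:
    """Read a genes x samples TSV with a header of sample ids.

    ``labels`` maps every sample id in the table to ``case``/``control``.
    Rows sharing a gene symbol (multiple probes) are collapsed to the
    per-sample maximum by default.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty data section")
    non_numeric = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        row = bad.index[0] if len(bad) else "?"
        raise FormatError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values in data section")
    labels = pd.Series(dict(labels)) if not isinstance(labels, pd.Series) else labels
    unlabeled = [s for s in df.columns if s not in labels.index]
    if unlabeled:
        raise FormatError(f"{path}: samples missing from labels: {unlabeled[:5]}")
    if df.index.duplicated().any():
        if collapse != "max":
            raise ValueError(f"unknown collapse rule {collapse!r}")
        df = df.groupby(level=0, sort=False).max()
    df.index = df.index.astype(str)
    return ExpressionMatrix(
        values=df,
        groups=labels.reindex(df.columns),
        subtypes=pd.Series(dict(subtypes)).reindex(df.columns) if subtypes is not None else None,
        platforms=pd.Series(dict(platforms)).reindex(df.columns) if platforms is not None else None,
    )


def write_expression_table(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_obo(path) -> nx.DiGraph:
    """Read an OBO ontology, keeping only is_a edges (child -> parent).

    Obsolete terms are dropped.  A cyclic is_a relation is an error: the
    clustering stage requires a DAG.
    """
    multi = obonet.read_obo(path, ignore_obsolete=True)
    graph = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        graph.add_node(node, name=data.get("name", node))
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(graph):
        raise FormatError(f"{path}: cyclic is_a relations")
    return graph


def ancestors(graph: nx.DiGraph, term: str) -> set[str]:
    """All is_a ancestors of a term (edges point child -> parent)."""
    return nx.descendants(graph, term)


def harmonize(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate cohorts restricted to their common gene symbols.

    No value normalization is performed; rank-within-sample statistics
    downstream make per-platform scales irrelevant.
    """
    if not matrices:
        raise ValueError("harmonize requires at least one matrix")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("no genes shared by all input matrices")
    genes = sorted(common)
    values = pd.concat([m.values.loc[genes] for m in matrices], axis=1)
    if values.columns.duplicated().any():
        raise ValueError("duplicate sample ids across input matrices")
    groups = pd.concat([m.groups for m in matrices])

    def _cat(attr):
        parts = [
            getattr(m, attr) if getattr(m, attr) is not None
            else pd.Series(pd.NA, index=m.sample_ids)
            for m in matrices
        ]
        if all(getattr(m, attr) is None for m in matrices):
            return None
        return pd.concat(parts)

    return ExpressionMatrix(
        values=values,
        groups=groups,
        subtypes=_cat("subtypes"),
        platforms=_cat("platforms"),
    )
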