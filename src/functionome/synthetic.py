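"""Seeded synthetic cohorts with planted gene set dysregulation.

The generator emulates the statistical structure the GSR analysis assumes:
controls share a latent baseline ordering of gene scores plus per-sample
noise; case samples are identical except that a chosen fraction of gene
sets has its within-set ordering scrambled at a tunable strength.  Because
the GSR statistic is purely ordinal, dysregulation is planted by permuting
the latent scores of a set's genes — a mean shift that preserves ordering
would be invisible — and the permutation is constructed to invert an exact
target fraction of the set's gene pairs (1.0 = full reversal).  An optional
per-sample strictly increasing transform emulates arbitrary platform
intensity scales; it changes no downstream rank statistic.

All randomness flows from a single seed through named substreams, so
collections, cohorts and ontology fixtures are independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, GeneSet, GeneSetCollection

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_collection",
    "generate_cohort",
    "generate_ontology",
    "permutation_with_inversions",
]

_STREAMS = ("collection", "planting", "baseline", "control_noise", "case_noise",
            "scales", "ontology")


def _rng(seed: int, stream: str) -> np.random.Generator:
    idx = _STREAMS.index(stream)
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(len(_STREAMS))[idx])


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror a mid-sized two-group design: 30 cases vs 30 controls,
    200 gene sets of ~10 genes drawn from a 1000-gene universe, a quarter of
    the sets dysregulated in cases with 80% of their pair orderings
    inverted, and per-sample Gaussian jitter of 0.3 SD on latent gene scores
    whose between-gene spread is 1.
    """

    n_case: int = 30
    n_control: int = 30
    n_genes: int = 1000
    n_sets: int = 200
    set_size_min: int = 10
    set_size_max: int = 10
    planted_fraction: float = 0.25
    scramble_strength: float = 0.8
    noise_sd: float = 0.3
    platform_scales: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_case, self.n_control, self.n_genes, self.n_sets) <= 0:
            raise ValueError("counts must be positive")
        if not (2 <= self.set_size_min <= self.set_size_max):
            raise ValueError("need 2 <= set_size_min <= set_size_max")
        if self.set_size_max > self.n_genes:
            raise ValueError("set size exceeds gene universe")
        for name in ("planted_fraction", "scramble_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort."""

    planted_set_ids: list[str]
    groups: pd.Series
    realized_strength: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "planted_set_ids": self.planted_set_ids,
            "groups": self.groups.to_dict(),
            "realized_strength": self.realized_strength,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def permutation_with_inversions(m: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """A random permutation of range(m) with exactly k pair inversions.

    Sampled through its inversion table (digit i may hold 0..m-1-i
    inversions); k = 0 gives the identity and k = m(m-1)/2 the full
    reversal.  The draw is uniform over inversion tables summing to k
    subject to the per-digit caps, which is sufficient here: only the
    inversion count matters to the planted signal.
    """
    kmax = m * (m - 1) // 2
    if not 0 <= k <= kmax:
        raise ValueError(f"need 0 <= k <= {kmax}, got {k}")
    caps = np.arange(m - 1, -1, -1)  # digit i (value i) in [0, m-1-i]
    code = np.zeros(m, dtype=int)
    remaining = k
    for i in range(m):
        tail = int(caps[i + 1:].sum())
        lo = max(0, remaining - tail)
        hi = min(caps[i], remaining)
        code[i] = rng.integers(lo, hi + 1)
        remaining -= code[i]
    # decode: insert values m-1..0, value i at position code[i]; every
    # earlier-inserted value is larger, so value i gains code[i] inversions
    seq: list[int] = []
    for i in range(m - 1, -1, -1):
        seq.insert(code[i], i)
    return np.array(seq, dtype=int)


def count_inversions(perm: np.ndarray) -> int:
    perm = np.asarray(perm)
    return int(sum((perm[i] > perm[i + 1:]).sum() for i in range(len(perm) - 1)))


def generate_collection(config: SyntheticConfig) -> GeneSetCollection:
    """Seeded random gene sets sampled without replacement per set."""
    rng = _rng(config.seed, "collection")
    genes = np.array([f"G{i:05d}" for i in range(config.n_genes)])
    width = len(str(config.n_sets))
    sets = []
    for s in range(config.n_sets):
        size = int(rng.integers(config.set_size_min, config.set_size_max + 1))
        members = rng.choice(genes, size=size, replace=False)
        sid = f"SET{s:0{width}d}"
        sets.append(GeneSet(set_id=sid, name=f"synthetic set {s}", genes=tuple(members)))
    return GeneSetCollection(sets=sets, source_tag="GO")


def _apply_planting(
    baseline: np.ndarray,
    collection: GeneSetCollection,
    gene_pos: dict[str, int],
    planted: list[str],
    strength: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Scramble the latent scores of each planted set's genes.

    Set genes are ranked by latent score and re-dealt those scores through a
    permutation carrying round(strength * n_pairs) inversions, so the
    realized inverted-pair fraction equals the requested strength exactly
    (before noise).  Overlapping planted sets are scrambled sequentially in
    set-id order; realized strengths are recomputed afterwards against the
    original baseline.
    """
    latent = baseline.copy()
    for sid in planted:
        gs = collection[sid]
        idx = np.array([gene_pos[g] for g in gs.genes])
        m = len(idx)
        n_pairs = m * (m - 1) // 2
        k = int(round(strength * n_pairs))
        perm = permutation_with_inversions(m, k, rng)
        order = idx[np.argsort(latent[idx], kind="stable")]   # genes by ascending score
        sorted_vals = np.sort(latent[idx])
        latent[order] = sorted_vals[perm]
    return latent


def _realized_strength(
    baseline: np.ndarray, latent: np.ndarray, idx: np.ndarray
) -> float:
    """Fraction of within-set gene pairs whose order the planting inverted."""
    b, l = baseline[idx], latent[idx]
    m = len(idx)
    iu, ju = np.triu_indices(m, k=1)
    before = b[iu] < b[ju]
    after = l[iu] < l[ju]
    return float((before != after).mean())


def generate_cohort(
    config: SyntheticConfig, collection: GeneSetCollection
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw a two-group cohort with planted ordinal dysregulation.

    Controls are latent baseline gene scores plus per-sample noise; cases
    use the scrambled latent vector plus the same kind of noise.  Noise is
    applied after planting, so the requested scramble strength is the
    pre-noise inversion fraction; the realized (pre-noise) fraction per
    planted set is recorded in the truth object.
    """
    n_planted = int(round(config.planted_fraction * len(collection)))
    if n_planted > 0 and len(collection) == 0:
        raise ValueError("cannot plant dysregulation into an empty collection")
    rng_base = _rng(config.seed, "baseline")
    rng_plant = _rng(config.seed, "planting")
    baseline = rng_base.normal(0.0, 1.0, size=config.n_genes)
    gene_names = [f"G{i:05d}" for i in range(config.n_genes)]
    gene_pos = {g: i for i, g in enumerate(gene_names)}
    for gs in collection:
        missing = [g for g in gs.genes if g not in gene_pos]
        if missing:
            raise ValueError(f"set {gs.set_id!r} has genes outside the universe: {missing[:3]}")

    all_ids = sorted(collection.set_ids)
    planted = sorted(rng_plant.choice(all_ids, size=n_planted, replace=False).tolist())
    case_latent = _apply_planting(
        baseline, collection, gene_pos, planted, config.scramble_strength, rng_plant
    )
    realized = {
        sid: _realized_strength(
            baseline, case_latent, np.array([gene_pos[g] for g in collection[sid].genes])
        )
        for sid in planted
    }

    ctrl = baseline[:, None] + config.noise_sd * _rng(config.seed, "control_noise").normal(
        size=(config.n_genes, config.n_control)
    )
    case = case_latent[:, None] + config.noise_sd * _rng(config.seed, "case_noise").normal(
        size=(config.n_genes, config.n_case)
    )
    values = np.concatenate([case, ctrl], axis=1)
    sample_ids = [f"case_{i:03d}" for i in range(config.n_case)] + [
        f"ctrl_{i:03d}" for i in range(config.n_control)
    ]
    if config.platform_scales:
        # per-sample strictly increasing transform: x -> exp(a x + b), a > 0
        rng_sc = _rng(config.seed, "scales")
        a = rng_sc.uniform(0.5, 2.0, size=values.shape[1])
        b = rng_sc.normal(0.0, 1.0, size=values.shape[1])
        values = np.exp(a[None, :] * values + b[None, :])
    groups = pd.Series(
        ["case"] * config.n_case + ["control"] * config.n_control, index=sample_ids
    )
    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=gene_names, columns=sample_ids),
        groups=groups,
    )
    return matrix, SyntheticTruth(
        planted_set_ids=planted, groups=groups, realized_strength=realized
    )


def generate_ontology(
    collection: GeneSetCollection,
    depth: int = 2,
    seed: int = 0,
    branching: int = 4,
) -> nx.DiGraph:
    """Random is_a DAG whose leaves are the collection's set ids.

    Leaves are shuffled and grouped under ceil(n/branching) synthetic
    parents per level, repeated ``depth`` times; each node gets exactly one
    parent, so the graph is a forest and acyclic by construction.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = _rng(seed, "ontology")
    graph = nx.DiGraph()
    current = list(collection.set_ids)
    for sid in current:
        graph.add_node(sid, name=collection[sid].name)
    for level in range(1, depth + 1):
        shuffled = list(current)
        rng.shuffle(shuffled)
        n_parents = max(1, -(-len(shuffled) // branching))
        parents = [f"SYN:L{level}:{p:03d}" for p in range(n_parents)]
        for p in parents:
            graph.add_node(p, name=f"synthetic ancestor {p}")
        for i, child in enumerate(shuffled):
            graph.add_edge(child, parents[i % n_parents])
        current = parents
    return graph
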