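"""Dysregulation calling: Mann-Whitney tests, BH-FDR, summaries, IHC score.

A gene set is called dysregulated when its GSR indices differ between case
and control samples by a two-sided Mann-Whitney U test, with
Benjamini-Hochberg control of the false discovery rate across sets at
alpha = 0.05 by default.  The same machinery applied to expression rows
yields differentially expressed genes (DEGs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .data_io import ExpressionMatrix
from .gsr import Functionome

__all__ = [
    "SetTestResult",
    "GeneTestResult",
    "HistogramSummary",
    "mann_whitney_set",
    "bh_adjust",
    "call_dysregulated",
    "call_degs",
    "summarize_histogram",
    "ihc_score",
    "results_to_frame",
]

EXACT_MAX_N = 8  # exact null distribution when both groups are this small (and no ties)


@dataclass
class SetTestResult:
    set_id: str
    u_statistic: float
    p_raw: float
    q: float | None = None
    significant: bool | None = None
    direction: int = 0  # sign of (case median - control median)


@dataclass
class GeneTestResult:
    gene_id: str
    u_statistic: float
    p_raw: float
    q: float | None = None
    significant: bool | None = None
    direction: int = 0


@dataclass
class HistogramSummary:
    bin_edges: np.ndarray
    case_counts: np.ndarray
    control_counts: np.ndarray
    case_mean: float
    case_sd: float
    control_mean: float
    control_sd: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "case_count": self.case_counts,
                "control_count": self.control_counts,
            }
        )


def _mw(case: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size < 1 or control.size < 1:
        raise ValueError("both groups need at least one observation")
    pooled = np.concatenate([case, control])
    no_ties = np.unique(pooled).size == pooled.size
    if case.size <= EXACT_MAX_N and control.size <= EXACT_MAX_N and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(case, control, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_set(case_gsr, control_gsr, set_id: str = "") -> SetTestResult:
    """Two-sided Mann-Whitney U test of GSR indices, case vs control.

    The exact null distribution is used when both groups have at most
    8 observations and there are no ties; otherwise the tie-corrected
    normal approximation with continuity correction.
    """
    u, p = _mw(case_gsr, control_gsr)
    direction = int(np.sign(np.median(case_gsr) - np.median(control_gsr)))
    return SetTestResult(set_id=set_id, u_statistic=u, p_raw=p, direction=direction)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _finalize(results: list, alpha: float) -> list:
    qs = bh_adjust([r.p_raw for r in results])
    for r, q in zip(results, qs):
        r.q = float(q)
        r.significant = bool(q < alpha)
    return results


def call_dysregulated(
    f: Functionome,
    labels: pd.Series | dict,
    alpha: float = 0.05,
    use_raw_p: bool = False,
) -> list[SetTestResult]:
    """Test every retained gene set's GSR column, case vs control.

    Significance applies the alpha threshold to BH-adjusted values; with
    ``use_raw_p`` it is applied to raw p-values instead.
    """
    labels = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    labels = labels.reindex(f.sample_ids)
    case_ids = list(labels.index[labels == "case"])
    ctrl_ids = list(labels.index[labels == "control"])
    if not case_ids or not ctrl_ids:
        raise ValueError("functionome must contain both case and control samples")
    case = f.gsr.loc[case_ids].to_numpy(dtype=float)
    ctrl = f.gsr.loc[ctrl_ids].to_numpy(dtype=float)
    results = []
    for j, sid in enumerate(f.set_ids):
        r = mann_whitney_set(case[:, j], ctrl[:, j], set_id=sid)
        results.append(r)
    results = _finalize(results, alpha)
    if use_raw_p:
        for r in results:
            r.significant = bool(r.p_raw < alpha)
    return results


def call_degs(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    use_raw_p: bool = False,
) -> list[GeneTestResult]:
    """Per-gene Mann-Whitney tests of expression, case vs control (DEGs)."""
    case_ids, ctrl_ids = matrix.case_ids, matrix.control_ids
    if not case_ids or not ctrl_ids:
        raise ValueError("matrix must contain both case and control samples")
    case = matrix.values[case_ids].to_numpy(dtype=float)
    ctrl = matrix.values[ctrl_ids].to_numpy(dtype=float)
    results = []
    for i, gene in enumerate(matrix.gene_ids):
        u, p = _mw(case[i], ctrl[i])
        direction = int(np.sign(np.median(case[i]) - np.median(ctrl[i])))
        results.append(GeneTestResult(gene_id=gene, u_statistic=u, p_raw=p, direction=direction))
    results = _finalize(results, alpha)
    if use_raw_p:
        for r in results:
            r.significant = bool(r.p_raw < alpha)
    return results


def summarize_histogram(
    f: Functionome, labels: pd.Series | dict, n_bins: int = 50
) -> HistogramSummary:
    """Per-group histograms of all GSR entries over equal-width bins of [0, 1]."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    labels = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    labels = labels.reindex(f.sample_ids)
    case_ids = list(labels.index[labels == "case"])
    ctrl_ids = list(labels.index[labels == "control"])
    if not case_ids or not ctrl_ids:
        raise ValueError("both groups must be nonempty")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    case = f.gsr.loc[case_ids].to_numpy(dtype=float).ravel()
    ctrl = f.gsr.loc[ctrl_ids].to_numpy(dtype=float).ravel()
    case_counts, _ = np.histogram(case, bins=edges)
    ctrl_counts, _ = np.histogram(ctrl, bins=edges)
    return HistogramSummary(
        bin_edges=edges,
        case_counts=case_counts,
        control_counts=ctrl_counts,
        case_mean=float(case.mean()),
        case_sd=float(case.std(ddof=1)) if case.size > 1 else 0.0,
        control_mean=float(ctrl.mean()),
        control_sd=float(ctrl.std(ddof=1)) if ctrl.size > 1 else 0.0,
    )


def ihc_score(intensity: int, percent_positive: float) -> float:
    """Immunohistochemistry quantification Q = I x P (maximum 300).

    ``intensity`` is the staining intensity grade 0-3 and
    ``percent_positive`` the percentage of positive cells in [0, 100].
    """
    if intensity not in (0, 1, 2, 3):
        raise ValueError("intensity must be an integer in {0, 1, 2, 3}")
    if not 0.0 <= percent_positive <= 100.0:
        raise ValueError("percent_positive must lie in [0, 100]")
    return float(intensity * percent_positive)


def results_to_frame(results) -> pd.DataFrame:
    """Tabulate set or gene test results for TSV export."""
    rows = []
    for r in results:
        ident = getattr(r, "set_id", None) or getattr(r, "gene_id", None)
        rows.append(
            {
                "id": ident,
                "U": r.u_statistic,
                "p": r.p_raw,
                "q": r.q,
                "significant": r.significant,
                "direction": r.direction,
            }
        )
    return pd.DataFrame(rows)
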