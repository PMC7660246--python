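"""Statistical comparison of the similarity matrices.

Splits each matrix into inter- and intra-group value sets given a group
labeling, correlates metric pairs (Pearson over shared upper-triangle
entries), and runs Welch two-sample t-tests between the inter and intra
distributions.  P-values below the double-precision floor are printed as
"<2.2e-16" in text output while the numeric value is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .similarity_metrics import SimilarityMatrix

P_FLOOR = 2.2e-16


@dataclass
class GroupLabeling:
    labels: dict[str, str]  # genome_id -> group label
    source: str = "config"

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for gid in sorted(self.labels):
            out.setdefault(self.labels[gid], []).append(gid)
        return out


@dataclass
class CorrelationReport:
    entries: list[tuple[str, str, float, int]]  # metric_x, metric_y, r, n pairs

    def r(self, metric_x: str, metric_y: str) -> float:
        for mx, my, r, _n in self.entries:
            if {mx, my} == {metric_x, metric_y}:
                return r
        raise KeyError((metric_x, metric_y))


def split_inter_intra(
    matrix: SimilarityMatrix, labeling: GroupLabeling
) -> tuple[list[float], list[float]]:
    """Partition upper-triangle entries into (intra, inter) by group label.

    Missing (NaN) values are dropped; a single-member group simply
    contributes no intra values.
    """
    missing = [g for g in matrix.genome_ids if g not in labeling.labels]
    if missing:
        raise ValueError(f"genomes without a group label: {missing}")
    intra, inter = [], []
    for a, b, v in matrix.upper_triangle():
        if math.isnan(v):
            continue
        (intra if labeling.labels[a] == labeling.labels[b] else inter).append(v)
    return intra, inter


def _shared_upper(mx: SimilarityMatrix, my: SimilarityMatrix) -> tuple[np.ndarray, np.ndarray]:
    if set(mx.genome_ids) != set(my.genome_ids):
        raise ValueError("matrices cover different genome sets")
    order = sorted(mx.genome_ids)
    a = mx.submatrix(order).values
    b = my.submatrix(order).values
    iu = np.triu_indices(len(order), k=1)
    xa, xb = a[iu], b[iu]
    keep = ~(np.isnan(xa) | np.isnan(xb))
    return xa[keep], xb[keep]


def metric_correlation(
    matrix_x: SimilarityMatrix, matrix_y: SimilarityMatrix, method: str = "pearson"
) -> tuple[float, int]:
    """Correlation coefficient between two matrices over shared non-missing
    upper-triangle entries; returns (r, n pairs used)."""
    x, y = _shared_upper(matrix_x, matrix_y)
    if len(x) < 3:
        raise ValueError("need at least 3 shared non-missing pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), int(len(x))


def correlation_report(
    matrices: list[SimilarityMatrix], method: str = "pearson"
) -> CorrelationReport:
    entries = []
    for i, mx in enumerate(matrices):
        for my in matrices[i + 1 :]:
            r, n = metric_correlation(mx, my, method)
            entries.append((mx.metric, my.metric, r, n))
    return CorrelationReport(entries)


def inter_intra_ttest(intra: list[float], inter: list[float]) -> tuple[float, float]:
    """Welch two-sample two-sided t-test between intra- and inter-group values.

    Degenerate zero-variance samples with different means give infinite t
    and p = 0 (reported as below the 2.2e-16 floor)."""
    if len(intra) < 2 or len(inter) < 2:
        raise ValueError("both samples need n >= 2")
    a, b = np.asarray(intra, float), np.asarray(inter, float)
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return math.inf if np.mean(a) > np.mean(b) else -math.inf, 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def format_pvalue(p: float) -> str:
    """Text form of a p-value, using the conventional '<2.2e-16' floor."""
    if p < P_FLOOR:
        return "<2.2e-16"
    return f"{p:.4g}"


def write_inter_intra(
    rows: list[tuple[str, str, float]], path
) -> None:
    """Long-format TSV of (metric, pair_type, value)."""
    with open(path, "w") as fh:
        fh.write("metric\tpair_type\tvalue\n")
        for metric, pair_type, value in rows:
            fh.write(f"{metric}\t{pair_type}\t{value:.6f}\n")


def write_correlations(report: CorrelationReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("metric_x\tmetric_y\tr\tn_pairs\n")
        for mx, my, r, n in report.entries:
            fh.write(f"{mx}\t{my}\t{r:.4f}\t{n}\n")
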