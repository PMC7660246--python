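"""Independent reference implementations used only to check the package.

These are deliberately plain: full dynamic-programming tables, no
prefilters, no vectorization, no shared code with the implementation
under test.
"""

from __future__ import annotations

import math

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score_reference(
    a: str,
    b: str,
    submat=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Plain affine-gap Smith–Waterman score; gap of length L costs
    gap_open + L * gap_extend."""
    if submat is None:
        submat = _BLOSUM62
    la, lb = len(a), len(b)
    neg = -math.inf
    open_cost = gap_open + gap_extend
    h = [[0.0] * (lb + 1) for _ in range(la + 1)]
    e = [[neg] * (lb + 1) for _ in range(la + 1)]
    f = [[neg] * (lb + 1) for _ in range(la + 1)]
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            e[i][j] = max(h[i - 1][j] - open_cost, e[i - 1][j] - gap_extend)
            f[i][j] = max(h[i][j - 1] - open_cost, f[i][j - 1] - gap_extend)
            s = float(submat[a[i - 1]][b[j - 1]])
            h[i][j] = max(0.0, h[i - 1][j - 1] + s, e[i][j], f[i][j])
            best = max(best, h[i][j])
    return best


def sw_score_nucleotide_reference(
    a: str, b: str, match: float = 1.0, mismatch: float = 2.0,
    gap_open: float = 5.0, gap_extend: float = 2.0,
) -> float:
    class _Mat:
        def __getitem__(self, x):
            return {y: (match if (x == y and x != "N") else -mismatch) for y in "ACGTN"}

    return sw_score_reference(a, b, _Mat(), gap_open, gap_extend)


def pearson_reference(x, y) -> float:
    """Closed-form Pearson product-moment correlation."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    sxx = sum((xi - mx) ** 2 for xi in x)
    syy = sum((yi - my) ** 2 for yi in y)
    return sxy / math.sqrt(sxx * syy)


def welch_reference(a, b) -> tuple[float, float]:
    """Welch two-sample t statistic and Welch–Satterthwaite df (no p)."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return t, df


def adjusted_rand_index(labels_a: dict, labels_b: dict) -> float:
    """Chance-corrected agreement of two partitions over the same keys."""
    keys = sorted(labels_a)
    assert sorted(labels_b) == keys
    from collections import Counter

    n = len(keys)
    contingency: Counter = Counter((labels_a[k], labels_b[k]) for k in keys)
    a_counts = Counter(labels_a[k] for k in keys)
    b_counts = Counter(labels_b[k] for k in keys)

    def comb2(x):
        return x * (x - 1) // 2

    sum_ij = sum(comb2(v) for v in contingency.values())
    sum_a = sum(comb2(v) for v in a_counts.values())
    sum_b = sum(comb2(v) for v in b_counts.values())
    expected = sum_a * sum_b / comb2(n)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def random_additive_distance_matrix(rng, n_taxa: int):
    """Random binary tree with positive branch lengths, returned as its
    exact additive leaf-to-leaf distance matrix (labels, numpy array).

    Built by random joins; leaf-to-root distances are tracked per subtree
    and cross-subtree leaf pairs get their path length fixed at the join,
    so no tree-library code is involved.
    """
    import numpy as np

    labels = [f"t{i}" for i in range(n_taxa)]
    index = {lab: i for i, lab in enumerate(labels)}
    matrix = np.zeros((n_taxa, n_taxa))
    subtrees = [{lab: 0.0} for lab in labels]  # leaf -> distance to subtree root
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        di, dj = subtrees[i], subtrees[j]
        bi = float(rng.uniform(0.05, 1.0))
        bj = float(rng.uniform(0.05, 1.0))
        for x, dx in di.items():
            for y, dy in dj.items():
                d = dx + bi + dy + bj
                matrix[index[x], index[y]] = matrix[index[y], index[x]] = d
        merged = {x: d + bi for x, d in di.items()}
        merged.update({y: d + bj for y, d in dj.items()})
        subtrees = [subtrees[k] for k in range(len(subtrees)) if k not in (i, j)]
        subtrees.append(merged)
    return labels, matrix
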