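"""Genome-similarity matrices: AAI, OrthoANI-style ANI, and POCP.

AAI is the unweighted mean percent identity over the reciprocal-best-hit
ortholog pairs of two proteomes (E <= 1e-5, both coverages >= 50 %, no
identity floor so values below 50 % remain computable).  ANI follows the
fragment-based orthologous ANI scheme: each assembly is cut into
consecutive non-overlapping 1020 bp windows, fragments are aligned
all-vs-all on both strands, reciprocal best fragment pairs covering at
least 70 % of the fragment are kept, and ANI is their mean identity.
POCP is (C1 + C2) / (T1 + T2) x 100 with C_i the number of genome i's
proteins having at least one one-way hit in the other genome at E <=
1e-5, identity >= 40 % and both coverages >= 50 %, and T_i the proteome
size.

Pairs sharing no orthologs yield a missing value (NaN), never 0: an
absent signal is not maximal dissimilarity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import GenomeRecord
from .orthology import BestHitTable, best_hits, one_way_hit_count
from .pairwise_align import KmerIndex, NucleotideAligner, ProteinAligner

ANI_FRAGMENT_LEN = 1020
ANI_FRAGMENT_COV_MIN = 70.0


@dataclass
class SimilarityMatrix:
    """Symmetric genome-by-genome matrix for one metric.

    Percentage metrics (AAI/ANI/POCP) carry 100 on the diagonal; the
    patristic-distance matrix (EVODIST) carries 0.  Missing values are
    NaN.
    """

    metric: str
    genome_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.genome_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match genome_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-9, equal_nan=True):
            raise ValueError(f"{self.metric} matrix is not symmetric")

    def value(self, a: str, b: str) -> float:
        i, j = self.genome_ids.index(a), self.genome_ids.index(b)
        return float(self.values[i, j])

    def submatrix(self, ids: list[str]) -> "SimilarityMatrix":
        idx = [self.genome_ids.index(g) for g in ids]
        return SimilarityMatrix(self.metric, list(ids), self.values[np.ix_(idx, idx)])

    def upper_triangle(self) -> list[tuple[str, str, float]]:
        out = []
        for i in range(len(self.genome_ids)):
            for j in range(i + 1, len(self.genome_ids)):
                out.append((self.genome_ids[i], self.genome_ids[j], float(self.values[i, j])))
        return out


def compute_aai(
    a: GenomeRecord,
    b: GenomeRecord,
    cov_min: float = 50.0,
    evalue_max: float = 1e-5,
    aligner: ProteinAligner | None = None,
    tables: tuple[BestHitTable, BestHitTable] | None = None,
) -> float:
    """Average amino-acid identity of two genomes over their RBH pairs.

    Returns NaN (with a warning) when the genomes share no reciprocal
    best hits.  Precomputed best-hit tables (a->b, b->a at identity floor
    0) may be passed to avoid realigning.
    """
    if a.genome_id == b.genome_id:
        return 100.0
    if tables is None:
        aligner = aligner or ProteinAligner()
        ab = best_hits(a, b, 0.0, cov_min, evalue_max, aligner=aligner)
        ba = best_hits(b, a, 0.0, cov_min, evalue_max, aligner=aligner)
    else:
        ab, ba = tables
    identities = []
    for p, hit in ab.hits.items():
        back = ba.hits.get(hit.subject_id)
        if back is not None and back.subject_id == p:
            identities.append(hit.identity_pct)
    if not identities:
        warnings.warn(
            f"no reciprocal best hits between {a.genome_id} and {b.genome_id}; AAI undefined",
            stacklevel=2,
        )
        return math.nan
    return float(np.mean(identities))


def compute_pocp(
    a: GenomeRecord,
    b: GenomeRecord,
    identity_min: float = 40.0,
    cov_min: float = 50.0,
    evalue_max: float = 1e-5,
    aligner: ProteinAligner | None = None,
    min_shared: int = 1,
) -> float:
    """Percentage of conserved proteins: 100 * (C1 + C2) / (T1 + T2)."""
    if a.genome_id == b.genome_id:
        return 100.0
    aligner = aligner or ProteinAligner()
    index_a = KmerIndex(a.proteome, k=4)
    index_b = KmerIndex(b.proteome, k=4)
    c1 = one_way_hit_count(a, b, identity_min, cov_min, evalue_max, aligner, index_b, min_shared)
    c2 = one_way_hit_count(b, a, identity_min, cov_min, evalue_max, aligner, index_a, min_shared)
    return 100.0 * (c1 + c2) / (a.n_proteins + b.n_proteins)


def _fragments(contigs: list[tuple[str, str]], fragment_len: int) -> list[str]:
    frags = []
    for _cid, seq in contigs:
        for start in range(0, len(seq) - fragment_len + 1, fragment_len):
            frags.append(seq[start : start + fragment_len])
    return frags


def compute_ani(
    a_contigs: list[tuple[str, str]],
    b_contigs: list[tuple[str, str]],
    fragment_len: int = ANI_FRAGMENT_LEN,
    fragment_cov_min: float = ANI_FRAGMENT_COV_MIN,
    aligner: NucleotideAligner | None = None,
) -> float:
    """Fragment-based orthologous ANI between two assemblies.

    Both assemblies are cut into non-overlapping *fragment_len* windows
    (trailing remainders discarded); fragments are aligned both strands,
    reciprocal best fragment pairs with >= *fragment_cov_min* % coverage
    on both fragments are retained, and ANI is their mean identity.
    """
    total_a = sum(len(s) for _i, s in a_contigs)
    total_b = sum(len(s) for _i, s in b_contigs)
    if total_a < 2 * fragment_len or total_b < 2 * fragment_len:
        raise ValueError("each assembly must total at least two fragment lengths")
    frags_a = _fragments(a_contigs, fragment_len)
    frags_b = _fragments(b_contigs, fragment_len)
    aligner = aligner or NucleotideAligner()

    named_b = [(f"b{j}", s) for j, s in enumerate(frags_b)]
    named_a = [(f"a{i}", s) for i, s in enumerate(frags_a)]
    index_b = KmerIndex(named_b, k=12, both_strands=True)
    index_a = KmerIndex(named_a, k=12, both_strands=True)

    def best_map(queries, subjects_seqs, index, min_shared=1):
        best: dict[int, int] = {}
        for qi, (qid, qseq) in enumerate(queries):
            cands = index.candidates(qseq, min_shared)
            top_s, top_j = 0.0, -1
            for sid in cands:
                j = int(sid[1:])
                s = aligner.score(qseq, subjects_seqs[j])
                if s > top_s or (s == top_s and top_j >= 0 and j < top_j):
                    top_s, top_j = s, j
            if top_j >= 0:
                best[qi] = top_j
        return best

    best_ab = best_map(named_a, frags_b, index_b)
    best_ba = best_map(named_b, frags_a, index_a)

    identities = []
    for i, j in best_ab.items():
        if best_ba.get(j) != i:
            continue
        hit = aligner.hit(frags_a[i], frags_b[j], f"a{i}", f"b{j}")
        if (
            hit is not None
            and hit.query_cov_pct >= fragment_cov_min
            and hit.subject_cov_pct >= fragment_cov_min
        ):
            identities.append(hit.identity_pct)
    if not identities:
        warnings.warn("no reciprocal fragment pairs; ANI undefined", stacklevel=2)
        return math.nan
    return float(np.mean(identities))


def metric_matrix(
    genomes: list[GenomeRecord],
    metric: str,
    tables: dict[tuple[str, str], BestHitTable] | None = None,
    **params,
) -> SimilarityMatrix:
    """Assemble the symmetric matrix for AAI, ANI or POCP over >= 2 genomes.

    For AAI, precomputed all-vs-all best-hit tables (identity floor 0)
    may be supplied so alignments are shared with the clustering stage.
    """
    if len(genomes) < 2:
        raise ValueError("metric_matrix requires at least 2 genomes")
    ids = [g.genome_id for g in genomes]
    n = len(ids)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = genomes[i], genomes[j]
            if metric == "AAI":
                pair = None
                if tables is not None:
                    pair = (tables[(a.genome_id, b.genome_id)], tables[(b.genome_id, a.genome_id)])
                v = compute_aai(a, b, tables=pair, **params)
            elif metric == "POCP":
                v = compute_pocp(a, b, **params)
            elif metric == "ANI":
                if not a.contigs or not b.contigs:
                    raise ValueError(f"ANI requires contigs for {a.genome_id} and {b.genome_id}")
                v = compute_ani(a.contigs, b.contigs, **params)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            values[i, j] = values[j, i] = v
    return SimilarityMatrix(metric, ids, values)


def write_long_format(matrices: list[SimilarityMatrix], path) -> None:
    """Long-format TSV (genome_a, genome_b, metric, value) for plotting."""
    with open(path, "w") as fh:
        fh.write("genome_a\tgenome_b\tmetric\tvalue\n")
        for m in matrices:
            for a, b, v in m.upper_triangle():
                fh.write(f"{a}\t{b}\t{m.metric}\t{'NA' if math.isnan(v) else f'{v:.6f}'}\n")
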