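"""Local pairwise alignment with identity, coverage and E-value reporting.

This is the computational substrate for orthologous clustering, AAI, ANI
and POCP.  Alignments are optimal Smith–Waterman under affine gap costs
(a gap of length L costs ``gap_open + L * gap_extend``, the BLAST
convention) with a deterministic traceback that prefers diagonal over up
over left moves.  E-values follow the ungapped Karlin–Altschul form with
fixed published constants per scoring scheme:

    bits = (lambda * S - ln K) / ln 2
    E    = m * n * 2 ** (-bits)

with m the query length and n the subject length times the number of
sequences searched.  BLAST's finite-length edge corrections are omitted;
the constants are an explicit, documented approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from . import _sw
from .io_formats import NUCLEOTIDE_ALPHABET, PROTEIN_ALPHABET

# gapped BLOSUM62 (open 11 / extend 1) and blastn match 1 / mismatch -2
PROTEIN_LAMBDA, PROTEIN_K = 0.267, 0.041
NUCLEOTIDE_LAMBDA, NUCLEOTIDE_K = 1.28, 0.46

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlignmentHit:
    """One local alignment between a query and a subject sequence."""

    query_id: str
    subject_id: str
    raw_score: float
    bit_score: float
    e_value: float
    identity_pct: float
    query_cov_pct: float
    subject_cov_pct: float
    aligned_columns: int
    mismatches: int = 0
    gap_opens: int = 0
    # 1-based inclusive coordinates on the forward query/subject
    qstart: int = 0
    qend: int = 0
    sstart: int = 0
    send: int = 0
    subject_strand: int = 1


def estimate_evalue(
    raw_score: float,
    query_len: int,
    subject_len: int,
    search_space_seqs: int = 1,
    lam: float = PROTEIN_LAMBDA,
    k: float = PROTEIN_K,
) -> tuple[float, float]:
    """Karlin–Altschul bit score and E-value for a raw alignment score.

    The effective database length is ``subject_len * search_space_seqs``,
    mirroring a search of the query against one proteome.
    """
    if raw_score <= 0:
        raise ValueError("raw_score must be positive")
    if query_len <= 0 or subject_len <= 0 or search_space_seqs <= 0:
        raise ValueError("lengths and search space must be positive")
    bits = (lam * raw_score - math.log(k)) / math.log(2)
    e_value = query_len * subject_len * search_space_seqs * 2.0 ** (-bits)
    return bits, e_value


class _Engine:
    """Encodes sequences and dispatches to the alignment kernels."""

    def __init__(self, alphabet: str, submat: np.ndarray, gap_open: float, gap_extend: float):
        self.alphabet = alphabet
        self.submat = np.asarray(submat, dtype=np.float32)
        self.gap_open = np.float32(gap_open)
        self.gap_extend = np.float32(gap_extend)
        table = np.full(256, -1, dtype=np.int8)
        for i, ch in enumerate(alphabet):
            table[ord(ch)] = i
        self._table = table

    def encode(self, seq: str, what: str) -> np.ndarray:
        if not seq:
            raise ValueError(f"empty {what} sequence")
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        codes = self._table[raw]
        if (codes < 0).any():
            bad = sorted({seq[i] for i in np.nonzero(codes < 0)[0]})
            raise ValueError(f"illegal {what} characters: {bad}")
        return codes

    def score(self, a: np.ndarray, b: np.ndarray) -> float:
        return float(_sw.sw_score(a, b, self.submat, self.gap_open, self.gap_extend))

    def align(self, a: np.ndarray, b: np.ndarray):
        return _sw.sw_align(a, b, self.submat, self.gap_open, self.gap_extend)


@lru_cache(maxsize=8)
def _protein_engine(scoring: str, gap_open: float, gap_extend: float) -> _Engine:
    mat = substitution_matrices.load(scoring)
    alphabet = "".join(sorted(PROTEIN_ALPHABET))
    n = len(alphabet)
    sub = np.zeros((n, n), dtype=np.float32)
    for i, x in enumerate(alphabet):
        for j, y in enumerate(alphabet):
            sub[i, j] = mat[x][y]
    return _Engine(alphabet, sub, gap_open, gap_extend)


@lru_cache(maxsize=8)
def _nucleotide_engine(match: float, mismatch: float, gap_open: float, gap_extend: float) -> _Engine:
    alphabet = "ACGTN"
    sub = np.full((5, 5), -mismatch, dtype=np.float32)
    for i in range(4):
        sub[i, i] = match  # N scores as mismatch against everything, itself included
    return _Engine(alphabet, sub, gap_open, gap_extend)


def _build_hit(
    stats,
    query_id: str,
    subject_id: str,
    query_len: int,
    subject_len: int,
    search_space_seqs: int,
    lam: float,
    k: float,
    strand: int = 1,
) -> AlignmentHit | None:
    score, qs, qe, ss0, se0, matches, mismatches, gaps, gap_opens, cols = stats
    if score <= 0:
        return None
    span_q, span_s = qe - qs, se0 - ss0
    bits, evalue = estimate_evalue(score, query_len, subject_len, search_space_seqs, lam, k)
    if strand == -1:
        # map the span back onto the forward subject strand (sstart > send)
        sstart, send = subject_len - ss0, subject_len - se0 + 1
    else:
        sstart, send = ss0 + 1, se0
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=score,
        bit_score=bits,
        e_value=evalue,
        identity_pct=100.0 * matches / cols if cols else 0.0,
        query_cov_pct=100.0 * span_q / query_len,
        subject_cov_pct=100.0 * span_s / subject_len,
        aligned_columns=cols,
        mismatches=mismatches,
        gap_opens=gap_opens,
        qstart=qs + 1,
        qend=qe,
        sstart=sstart,
        send=send,
        subject_strand=strand,
    )


class ProteinAligner:
    """Smith–Waterman protein aligner (default BLOSUM62, gap 11/1)."""

    lam, k = PROTEIN_LAMBDA, PROTEIN_K

    def __init__(self, scoring: str = "BLOSUM62", gap_open: float = 11, gap_extend: float = 1):
        self._engine = _protein_engine(scoring, gap_open, gap_extend)
        self._cache: dict[str, np.ndarray] = {}

    def _encode(self, seq: str) -> np.ndarray:
        enc = self._cache.get(seq)
        if enc is None:
            enc = self._engine.encode(seq, "protein")
            if len(self._cache) > 100_000:
                self._cache.clear()
            self._cache[seq] = enc
        return enc

    def score(self, a: str, b: str) -> float:
        """Optimal local alignment score (no traceback)."""
        return self._engine.score(self._encode(a), self._encode(b))

    def hit(
        self,
        a: str,
        b: str,
        query_id: str = "query",
        subject_id: str = "subject",
        search_space_seqs: int = 1,
    ) -> AlignmentHit | None:
        stats = self._engine.align(self._encode(a), self._encode(b))
        return _build_hit(
            stats, query_id, subject_id, len(a), len(b),
            search_space_seqs, self.lam, self.k,
        )


class NucleotideAligner:
    """Smith–Waterman nucleotide aligner trying both strands (best kept).

    Defaults follow blastn: match +1, mismatch -2, gap 5/2.  N scores as
    a mismatch against everything, including N.
    """

    lam, k = NUCLEOTIDE_LAMBDA, NUCLEOTIDE_K

    def __init__(self, match: float = 1, mismatch: float = 2, gap_open: float = 5, gap_extend: float = 2):
        self._engine = _nucleotide_engine(match, mismatch, gap_open, gap_extend)

    def score(self, a: str, b: str) -> float:
        ea = self._engine.encode(a, "nucleotide")
        return max(
            self._engine.score(ea, self._engine.encode(b, "nucleotide")),
            self._engine.score(ea, self._engine.encode(reverse_complement(b), "nucleotide")),
        )

    def hit(
        self,
        a: str,
        b: str,
        query_id: str = "query",
        subject_id: str = "subject",
        search_space_seqs: int = 1,
    ) -> AlignmentHit | None:
        ea = self._engine.encode(a, "nucleotide")
        eb = self._engine.encode(b, "nucleotide")
        eb_rc = self._engine.encode(reverse_complement(b), "nucleotide")
        fwd = self._engine.score(ea, eb)
        rev = self._engine.score(ea, eb_rc)
        strand = 1 if fwd >= rev else -1
        if max(fwd, rev) <= 0:
            return None
        stats = self._engine.align(ea, eb if strand == 1 else eb_rc)
        return _build_hit(
            stats, query_id, subject_id, len(a), len(b),
            search_space_seqs, self.lam, self.k, strand=strand,
        )


def local_align_protein(
    a: str,
    b: str,
    scoring: str = "BLOSUM62",
    gap_open: float = 11,
    gap_extend: float = 1,
) -> AlignmentHit | None:
    """Align two protein sequences locally; None if no positive-scoring alignment."""
    return ProteinAligner(scoring, gap_open, gap_extend).hit(a, b)


def local_align_nucleotide(
    a: str,
    b: str,
    match: float = 1,
    mismatch: float = 2,
    gap_open: float = 5,
    gap_extend: float = 2,
) -> AlignmentHit | None:
    """Align two nucleotide sequences locally on both strands; best retained."""
    return NucleotideAligner(match, mismatch, gap_open, gap_extend).hit(a, b)


# -- k-mer prefilter ---------------------------------------------------------

class KmerIndex:
    """Exact k-word index over a sequence collection, used to shortlist
    subjects before alignment.  Any subject passing the orthology filter at
    moderate divergence shares at least one exact k-word with its query, so
    the shortlist is a superset of the hits that matter.
    """

    def __init__(self, targets: Iterable[tuple[str, str]], k: int = 4, both_strands: bool = False):
        self.k = k
        self._index: dict[str, set[str]] = {}
        self._ids: list[str] = []
        for tid, seq in targets:
            self._ids.append(tid)
            seqs = [seq, reverse_complement(seq)] if both_strands else [seq]
            for s in seqs:
                for i in range(len(s) - k + 1):
                    self._index.setdefault(s[i : i + k], set()).add(tid)
        self._order = {tid: i for i, tid in enumerate(self._ids)}

    def candidates(self, query: str, min_shared: int = 1) -> list[str]:
        counts: dict[str, int] = {}
        k = self.k
        words = {query[i : i + k] for i in range(len(query) - k + 1)}
        index_get = self._index.get
        for word in words:
            for tid in index_get(word, ()):
                counts[tid] = counts.get(tid, 0) + 1
        return sorted((t for t, c in counts.items() if c >= min_shared), key=self._order.__getitem__)


def kmer_prefilter(
    query: str,
    targets: Sequence[tuple[str, str]],
    k: int = 4,
    min_shared: int = 1,
    both_strands: bool = False,
) -> list[str]:
    """Subject ids sharing >= *min_shared* distinct exact k-words with *query*."""
    if k < 2:
        raise ValueError("k must be >= 2")
    return KmerIndex(targets, k=k, both_strands=both_strands).candidates(query, min_shared)


def write_blast6(hits: Iterable[AlignmentHit], path) -> None:
    """Dump hits as 12-column BLAST outfmt-6 compatible TSV."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.subject_id, f"{h.identity_pct:.3f}",
                        h.aligned_columns, h.mismatches, h.gap_opens,
                        h.qstart, h.qend, h.sstart, h.send,
                        f"{h.e_value:.2e}", f"{h.bit_score:.1f}",
                    )
                )
                + "\n"
            )
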