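"""Core-genome phylogeny: progressive alignment of single-copy core
clusters, gap-fraction trimming, concatenation into a supermatrix,
Kimura-corrected protein distances, neighbor-joining, and patristic
(evolutionary) distances.

Distance-based inference stands in for likelihood tree building: the
demarcation logic downstream consumes relative distances and topology,
both of which neighbor-joining recovers exactly on additive inputs, which
makes every stage directly testable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from Bio.Align import substitution_matrices

_AA_ORDER = "ARNDCQEGHILKMFPSTWYVBZX*"
_AA_TO_IDX = {a: i for i, a in enumerate(_AA_ORDER)}
_GAP_IDX = len(_AA_ORDER)


def _blosum62_full() -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    n = len(_AA_ORDER)
    full = np.zeros((n + 1, n + 1))  # final row/col = gap, scores 0 against everything
    for i, a in enumerate(_AA_ORDER):
        for j, b in enumerate(_AA_ORDER):
            full[i, j] = mat[a][b]
    return full


_BLOSUM_FULL = _blosum62_full()


@dataclass
class MultipleAlignment:
    ids: list[str]
    rows: list[str]
    source_cluster_id: str = ""

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace("-", "")


@dataclass
class Supermatrix:
    ids: list[str]
    rows: list[str]
    partitions: dict[str, tuple[int, int]]  # cluster_id -> [start, end) columns

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def part(self, cluster_id: str) -> MultipleAlignment:
        s, e = self.partitions[cluster_id]
        return MultipleAlignment(list(self.ids), [r[s:e] for r in self.rows], cluster_id)


# -- progressive MSA ---------------------------------------------------------

def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - fraction of shared k-mer counts; crude but adequate for a guide tree."""
    def counts(s):
        c: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            c[w] = c.get(w, 0) + 1
        return c

    ca, cb = counts(a), counts(b)
    shared = sum(min(ca[w], cb.get(w, 0)) for w in ca)
    denom = min(len(a), len(b)) - k + 1
    if denom <= 0:
        return 1.0
    return 1.0 - shared / denom


def _profile(rows: list[str]) -> np.ndarray:
    """Column frequency profile over residues + gap."""
    n_cols = len(rows[0])
    prof = np.zeros((n_cols, _GAP_IDX + 1))
    for row in rows:
        for j, ch in enumerate(row):
            prof[j, _GAP_IDX if ch == "-" else _AA_TO_IDX[ch]] += 1
    return prof / len(rows)


def _align_profiles(
    rows_a: list[str], rows_b: list[str], gap_open: float = 11.0, gap_extend: float = 1.0
) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment with affine gaps (expected BLOSUM62
    column score; gap symbols inside a profile score 0)."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    la, lb = pa.shape[0], pb.shape[0]
    # expected substitution score for every column pair in one product
    score = pa @ _BLOSUM_FULL @ pb.T

    neg = -1e30
    open_cost = gap_open + gap_extend
    m = np.full((la + 1, lb + 1), neg)
    ix = np.full((la + 1, lb + 1), neg)  # gap in B (vertical, consumes A)
    iy = np.full((la + 1, lb + 1), neg)  # gap in A (horizontal, consumes B)
    m[0, 0] = 0.0
    ix[1:, 0] = -open_cost - gap_extend * np.arange(la)
    iy[0, 1:] = -open_cost - gap_extend * np.arange(lb)
    for i in range(1, la + 1):
        prev_best = np.maximum.reduce([m[i - 1], ix[i - 1], iy[i - 1]])
        m[i, 1:] = prev_best[:-1] + score[i - 1]
        ix[i, 1:] = np.maximum(m[i - 1, 1:] - open_cost, ix[i - 1, 1:] - gap_extend)
        ix[i, 0] = max(m[i - 1, 0] - open_cost, ix[i - 1, 0] - gap_extend)
        # horizontal pass: iy[i, j] = max(m[i, j-1] - open, iy[i, j-1] - ext),
        # i.e. iy[i, j] = max_{k<j} (m[i, k] - open - ext*(j-1-k)) as a running max
        cand = m[i, :-1] - open_cost + gap_extend * np.arange(lb)
        run = np.maximum.accumulate(cand)
        iy[i, 1:] = run - gap_extend * np.arange(lb)

    # traceback (prefer diagonal, then vertical, then horizontal)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = la, lb
    state = int(np.argmax([m[i, j], ix[i, j], iy[i, j]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            out_a.append("COL")
            out_b.append("COL")
            prev = np.array([m[i - 1, j - 1], ix[i - 1, j - 1], iy[i - 1, j - 1]])
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1 or j == 0:
            out_a.append("COL")
            out_b.append("GAP")
            if abs(ix[i, j] - (m[i - 1, j] - open_cost)) < 1e-9:
                state = 0
            i -= 1
        else:
            out_a.append("GAP")
            out_b.append("COL")
            if abs(iy[i, j] - (m[i, j - 1] - open_cost)) < 1e-9:
                state = 0
            j -= 1
    out_a.reverse()
    out_b.reverse()

    def expand(rows, ops):
        new_rows = []
        for row in rows:
            buf = []
            pos = 0
            for op in ops:
                if op == "COL":
                    buf.append(row[pos])
                    pos += 1
                else:
                    buf.append("-")
            new_rows.append("".join(buf))
        return new_rows

    return expand(rows_a, out_a), expand(rows_b, out_b)


def progressive_msa(
    sequences: list[tuple[str, str]],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    cluster_id: str = "",
) -> MultipleAlignment:
    """Progressive multiple alignment: 3-mer count distances -> UPGMA guide
    tree -> profile-profile merges with affine gaps.  Input order does not
    change the result (sequences are sorted by id first)."""
    if not sequences:
        raise ValueError("no sequences")
    seqs = sorted(sequences, key=lambda x: x[0])
    if len(seqs) == 1:
        return MultipleAlignment([seqs[0][0]], [seqs[0][1]], cluster_id)
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = _kmer_distance(seqs[i][1], seqs[j][1])
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    # merge up the guide tree
    nodes: dict[int, tuple[list[str], list[str]]] = {
        i: ([seqs[i][0]], [seqs[i][1]]) for i in range(n)
    }
    for k, (left, right, _h, _c) in enumerate(linkage):
        ids_l, rows_l = nodes.pop(int(left))
        ids_r, rows_r = nodes.pop(int(right))
        new_l, new_r = _align_profiles(rows_l, rows_r, gap_open, gap_extend)
        nodes[n + k] = (ids_l + ids_r, new_l + new_r)
    ids, rows = nodes.popitem()[1]
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    return MultipleAlignment([ids[i] for i in order], [rows[i] for i in order], cluster_id)


def trim_alignment(aln: MultipleAlignment, max_gap_fraction: float = 0.2) -> MultipleAlignment:
    """Keep exactly the columns whose gap fraction is <= *max_gap_fraction*."""
    n = len(aln.rows)
    keep = []
    for j in range(aln.n_columns):
        gaps = sum(1 for row in aln.rows if row[j] == "-")
        if gaps / n <= max_gap_fraction:
            keep.append(j)
    if not keep:
        raise ValueError(
            "trimming removed every column; loosen max_gap_fraction"
        )
    rows = ["".join(row[j] for j in keep) for row in aln.rows]
    return MultipleAlignment(list(aln.ids), rows, aln.source_cluster_id)


def concatenate(alignments: list[MultipleAlignment], ids: list[str]) -> Supermatrix:
    """Concatenate per-cluster alignments into a partitioned supermatrix.

    Every alignment must contain every id exactly once (guaranteed for
    single-copy core clusters)."""
    partitions: dict[str, tuple[int, int]] = {}
    pieces: dict[str, list[str]] = {g: [] for g in ids}
    offset = 0
    for aln in alignments:
        for g in ids:
            if g not in aln.ids:
                raise ValueError(
                    f"cluster {aln.source_cluster_id!r} is missing genome {g!r}"
                )
        width = aln.n_columns
        partitions[aln.source_cluster_id] = (offset, offset + width)
        offset += width
        for g in ids:
            pieces[g].append(aln.row(g))
    return Supermatrix(list(ids), ["".join(pieces[g]) for g in ids], partitions)


# -- distances ---------------------------------------------------------------

DISTANCE_CAP = 5.0
P_CAP = 0.85


def protein_distance(row_a: str, row_b: str) -> float:
    """Kimura-corrected protein distance d = -ln(1 - p - 0.2 p^2) from the
    proportion p of differing residues over columns where neither row is
    gapped.  Saturated pairs (p >= 0.85) are capped at d = 5."""
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal length")
    comparable = mismatches = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-" or cb == "-":
            continue
        comparable += 1
        if ca != cb:
            mismatches += 1
    if comparable == 0:
        raise ValueError("no comparable (gap-free) columns")
    p = mismatches / comparable
    if p >= P_CAP:
        warnings.warn(f"saturated distance (p={p:.3f}); capped at {DISTANCE_CAP}", stacklevel=2)
        return DISTANCE_CAP
    return -math.log(1.0 - p - 0.2 * p * p)


def supermatrix_distances(sm: Supermatrix) -> np.ndarray:
    n = len(sm.ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = protein_distance(sm.rows[i], sm.rows[j])
    return out


# -- neighbor joining --------------------------------------------------------

def nj_tree(
    distances: np.ndarray,
    ids: list[str],
    outgroup_id: str | None = None,
) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with negative branch estimates clamped
    to zero.  The tree is rooted at the midpoint of the outgroup's edge if
    an outgroup is named, else at the midpoint of the longest leaf-to-leaf
    path."""
    distances = np.asarray(distances, dtype=float)
    n = len(ids)
    if distances.shape != (n, n):
        raise ValueError("distance matrix shape does not match ids")
    if not np.allclose(distances, distances.T, atol=1e-9):
        raise ValueError("distance matrix is not symmetric")
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    taxa = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    active = list(range(n))
    dm = distances.copy()
    node_of = {i: nodes[i] for i in range(n)}

    while len(active) > 2:
        r = len(active)
        sums = {i: sum(dm[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (r - 2) * dm[i, j] - sums[i] - sums[j]
                key = (q, dm[i, j], min(i, j), max(i, j))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * dm[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = dm[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        child_i, child_j = node_of[i], node_of[j]
        parent.add_child(child_i)
        parent.add_child(child_j)
        child_i.edge.length = li
        child_j.edge.length = lj
        # distances from the new node
        new_index = dm.shape[0]
        dm = np.pad(dm, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            dm[new_index, k] = dm[k, new_index] = 0.5 * (dm[i, k] + dm[j, k] - dm[i, j])
        active = [k for k in active if k not in (i, j)] + [new_index]
        node_of[new_index] = parent

    i, j = active
    root = dendropy.Node()
    ci, cj = node_of[i], node_of[j]
    root.add_child(ci)
    root.add_child(cj)
    half = max(dm[i, j], 0.0) / 2.0
    ci.edge.length = half
    cj.edge.length = max(dm[i, j], 0.0) - half
    tree.seed_node = root
    tree.is_rooted = True
    tree.update_taxon_namespace()
    tree.encode_bipartitions()

    if outgroup_id is not None:
        _root_on_outgroup(tree, outgroup_id)
    else:
        _midpoint_root(tree)
    return tree


def _leaf_path_edges(tree: dendropy.Tree, leaf_u, leaf_v):
    """Edges along the path leaf_u -> leaf_v, ordered from u's side."""
    ancestors_u = []
    node = leaf_u
    while node is not None:
        ancestors_u.append(node)
        node = node.parent_node
    seen = set(id(n) for n in ancestors_u)
    path_v = []
    node = leaf_v
    while id(node) not in seen:
        path_v.append(node)
        node = node.parent_node
    mrca = node
    path_u = []
    node = leaf_u
    while node is not mrca:
        path_u.append(node)
        node = node.parent_node
    # edges: from u up to mrca, then down to v
    return [n.edge for n in path_u] + [n.edge for n in reversed(path_v)]


def _midpoint_root(tree: dendropy.Tree) -> None:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    pdm = tree.phylogenetic_distance_matrix()
    leaves = list(tree.leaf_node_iter())
    best = (-1.0, None, None)
    for i, u in enumerate(leaves):
        for v in leaves[i + 1 :]:
            d = pdm.patristic_distance(u.taxon, v.taxon)
            if d > best[0]:
                best = (d, u, v)
    total, u, v = best
    half = total / 2.0
    cum = 0.0
    for edge in _leaf_path_edges(tree, u, v):
        length = edge.length or 0.0
        if cum + length >= half - 1e-12:
            offset = half - cum  # distance from the u-side end of this edge
            # orient: does the path traverse this edge child->parent (towards
            # the mrca) or parent->child?  u's ancestors go child->parent.
            node = u
            going_up = False
            while node is not None:
                if node.edge is edge:
                    going_up = True
                    break
                node = node.parent_node
            if going_up:
                head_len, tail_len = offset, length - offset
            else:
                head_len, tail_len = length - offset, offset
            tree.reroot_at_edge(edge, length1=tail_len, length2=head_len)
            tree.is_rooted = True
            tree.update_bipartitions(suppress_unifurcations=True)
            return
        cum += length
    raise RuntimeError("midpoint not found on path")  # pragma: no cover


def _root_on_outgroup(tree: dendropy.Tree, outgroup_id: str) -> None:
    node = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == outgroup_id:
            node = leaf
            break
    if node is None:
        raise ValueError(f"outgroup {outgroup_id!r} not in tree")
    length = node.edge.length or 0.0
    tree.reroot_at_edge(node.edge, length1=length / 2.0, length2=length / 2.0,
                        update_bipartitions=True)


def drop_leaf(tree: dendropy.Tree, leaf_label: str) -> dendropy.Tree:
    """Return a copy of *tree* with one leaf pruned (used to strip the
    outgroup before demarcation)."""
    pruned = tree.clone(depth=1)
    taxon = pruned.taxon_namespace.get_taxon(leaf_label)
    if taxon is None:
        raise ValueError(f"leaf {leaf_label!r} not in tree")
    pruned.prune_taxa([taxon])
    pruned.purge_taxon_namespace()
    return pruned


def patristic_distances(tree: dendropy.Tree) -> "SimilarityMatrix":
    """Leaf-to-leaf path-length (patristic / evolutionary distance) matrix."""
    from .similarity_metrics import SimilarityMatrix

    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    values = np.zeros((n, n))
    taxa = {t.label: t for t in tree.taxon_namespace if t.label in set(labels)}
    for i, a in enumerate(labels):
        for j in range(i + 1, n):
            b = labels[j]
            d = pdm.patristic_distance(taxa[a], taxa[b])
            values[i, j] = values[j, i] = d
    return SimilarityMatrix("EVODIST", labels, values)


def write_supermatrix(sm: Supermatrix, fasta_path, partition_path) -> None:
    from .io_formats import write_fasta

    write_fasta(zip(sm.ids, sm.rows), fasta_path)
    with open(partition_path, "w") as fh:
        fh.write("cluster_id\tstart\tend\n")
        for cid, (s, e) in sm.partitions.items():
            fh.write(f"{cid}\t{s}\t{e}\n")
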