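"""Orthologous clustering across genomes from reciprocal best hits (RBH).

Protein p in genome A and q in genome B are reciprocal best hits when q is
p's highest-scoring qualifying hit in B and vice versa.  Hits qualify when
they clear the identity / coverage / E-value triple (defaults 50 % / 50 % /
1e-5, with coverage enforced on both sequences).  Orthologous clusters
(OCs) are the connected components of the union RBH graph over all genome
pairs; proteins with no reciprocal hit anywhere form singleton clusters so
that every gene of every genome is accounted to exactly one cluster.

A cluster is *core* if every analysis genome contributes at least one
member, *unique* if exactly one genome does, *accessory* otherwise.
Single-copy core clusters (exactly one member per genome) feed the
core-genome phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .io_formats import GenomeRecord
from .pairwise_align import AlignmentHit, KmerIndex, ProteinAligner


@dataclass
class OrthologousCluster:
    cluster_id: str
    members: frozenset  # of (genome_id, protein_id)

    @property
    def genome_multiplicity(self) -> dict[str, int]:
        mult: dict[str, int] = {}
        for gid, _pid in self.members:
            mult[gid] = mult.get(gid, 0) + 1
        return mult

    def genomes(self) -> set[str]:
        return {gid for gid, _ in self.members}

    def is_single_copy_for(self, genome_ids) -> bool:
        """True iff every listed genome contributes exactly one member."""
        mult = self.genome_multiplicity
        return all(mult.get(g, 0) == 1 for g in genome_ids)


@dataclass
class PanGenomeSummary:
    per_genome: dict[str, dict[str, int]]  # genome_id -> {core, accessory, unique}
    total_oc_count: int
    core_oc_count: int
    single_copy_core_count: int
    core_cluster_ids: list[str] = field(default_factory=list)
    single_copy_core_ids: list[str] = field(default_factory=list)


@dataclass
class BestHitTable:
    """Directed best hits query-proteome -> subject-proteome."""

    query_genome: str
    subject_genome: str
    hits: dict[str, AlignmentHit]  # query protein id -> its single best passing hit


@dataclass(frozen=True)
class HitFilter:
    identity_min: float = 50.0
    cov_min: float = 50.0
    evalue_max: float = 1e-5

    def passes(self, hit: AlignmentHit) -> bool:
        return (
            hit.identity_pct >= self.identity_min
            and hit.query_cov_pct >= self.cov_min
            and hit.subject_cov_pct >= self.cov_min
            and hit.e_value <= self.evalue_max
        )


def _min_score_for_evalue(evalue_max: float, query_len: int, db_len: int, lam: float, k: float) -> float:
    """Smallest raw score whose Karlin–Altschul E-value can reach *evalue_max*.

    Lets obviously non-significant candidates be dropped on score alone,
    before any traceback."""
    import math

    return (math.log(query_len * db_len / evalue_max) + math.log(k)) / lam


def best_hits_multi(
    proteome_a: GenomeRecord,
    proteome_b: GenomeRecord,
    filters: list[HitFilter],
    aligner: ProteinAligner | None = None,
    index_b: KmerIndex | None = None,
    prefilter_k: int = 4,
    min_shared: int = 1,
) -> list[BestHitTable]:
    """Directed best hits for several filter triples in one alignment pass.

    For each query, candidate subjects (shortlisted by shared exact
    k-words) are walked in decreasing raw-score order; for every filter
    the first passing hit is the best hit (score ties break on identity,
    then aligned columns, then subject id).  Candidates whose score
    already rules out every filter's E-value cutoff are skipped without
    traceback.
    """
    if not proteome_a.proteome or not proteome_b.proteome:
        raise ValueError("best_hits requires non-empty proteomes")
    aligner = aligner or ProteinAligner()
    index_b = index_b or KmerIndex(proteome_b.proteome, k=prefilter_k)
    b_seqs = dict(proteome_b.proteome)
    n_subjects = len(proteome_b.proteome)
    db_len_factor = n_subjects
    loosest_evalue = max(f.evalue_max for f in filters)
    tables: list[dict[str, AlignmentHit]] = [{} for _ in filters]
    for qid, qseq in proteome_a.proteome:
        candidates = index_b.candidates(qseq, min_shared)
        if not candidates:
            continue
        score_floor = _min_score_for_evalue(
            loosest_evalue, len(qseq),
            max(len(b_seqs[s]) for s in candidates) * db_len_factor,
            aligner.lam, aligner.k,
        )
        if len(candidates) == 1:
            # no ranking needed; the traceback itself carries the score
            sid = candidates[0]
            hit = aligner.hit(qseq, b_seqs[sid], qid, sid, search_space_seqs=n_subjects)
            if hit is not None and hit.raw_score >= score_floor:
                for fi, filt in enumerate(filters):
                    if filt.passes(hit):
                        tables[fi][qid] = hit
            continue
        scored = []
        for sid in candidates:
            s = aligner.score(qseq, b_seqs[sid])
            if s > 0 and s >= score_floor:
                scored.append((-s, sid))
        scored.sort()
        found: list[AlignmentHit | None] = [None] * len(filters)
        i = 0
        while i < len(scored) and any(f is None for f in found):
            # resolve the whole score-tie block at once for deterministic ties
            block_score = scored[i][0]
            block = []
            while i < len(scored) and scored[i][0] == block_score:
                sid = scored[i][1]
                hit = aligner.hit(qseq, b_seqs[sid], qid, sid, search_space_seqs=n_subjects)
                if hit is not None:
                    block.append(hit)
                i += 1
            block.sort(key=lambda h: (-h.identity_pct, -h.aligned_columns, h.subject_id))
            for fi, filt in enumerate(filters):
                if found[fi] is None:
                    for hit in block:
                        if filt.passes(hit):
                            found[fi] = hit
                            break
        for fi, hit in enumerate(found):
            if hit is not None:
                tables[fi][qid] = hit
    return [
        BestHitTable(proteome_a.genome_id, proteome_b.genome_id, t) for t in tables
    ]


def best_hits(
    proteome_a: GenomeRecord,
    proteome_b: GenomeRecord,
    identity_min: float = 50.0,
    cov_min: float = 50.0,
    evalue_max: float = 1e-5,
    aligner: ProteinAligner | None = None,
    index_b: KmerIndex | None = None,
    prefilter_k: int = 4,
    min_shared: int = 1,
) -> BestHitTable:
    """Best qualifying hit in *proteome_b* for every protein of *proteome_a*.

    The best hit is the highest-scoring subject whose alignment passes
    identity >= *identity_min*, coverage >= *cov_min* on both sequences,
    and E <= *evalue_max*; queries with no passing hit are absent.
    """
    return best_hits_multi(
        proteome_a, proteome_b,
        [HitFilter(identity_min, cov_min, evalue_max)],
        aligner=aligner, index_b=index_b,
        prefilter_k=prefilter_k, min_shared=min_shared,
    )[0]


def one_way_hit_count(
    proteome_a: GenomeRecord,
    proteome_b: GenomeRecord,
    identity_min: float,
    cov_min: float,
    evalue_max: float,
    aligner: ProteinAligner | None = None,
    index_b: KmerIndex | None = None,
    min_shared: int = 1,
) -> int:
    """Number of proteins of *proteome_a* with >= 1 qualifying hit in *proteome_b*.

    This is the C term of the POCP formula: any passing hit counts, not
    only the best or a reciprocal one.
    """
    aligner = aligner or ProteinAligner()
    index_b = index_b or KmerIndex(proteome_b.proteome, k=4)
    b_seqs = dict(proteome_b.proteome)
    n_subjects = len(proteome_b.proteome)
    filt = HitFilter(identity_min, cov_min, evalue_max)
    count = 0
    for qid, qseq in proteome_a.proteome:
        candidates = index_b.candidates(qseq, min_shared)
        if not candidates:
            continue
        floor = _min_score_for_evalue(
            evalue_max, len(qseq),
            max(len(b_seqs[s]) for s in candidates) * n_subjects,
            aligner.lam, aligner.k,
        )
        scored = sorted(
            ((-aligner.score(qseq, b_seqs[sid]), sid) for sid in candidates),
        )
        for neg_s, sid in scored:
            if -neg_s < floor or -neg_s <= 0:
                break
            hit = aligner.hit(qseq, b_seqs[sid], qid, sid, search_space_seqs=n_subjects)
            if hit is not None and filt.passes(hit):
                count += 1
                break
    return count


def rbh_edges(best_ab: BestHitTable, best_ba: BestHitTable) -> set[tuple[tuple[str, str], tuple[str, str]]]:
    """Undirected reciprocal pairs ((genome_a, p), (genome_b, q))."""
    if (best_ab.query_genome, best_ab.subject_genome) != (best_ba.subject_genome, best_ba.query_genome):
        raise ValueError("best-hit tables are not a reciprocal pair")
    edges = set()
    for p, hit in best_ab.hits.items():
        q = hit.subject_id
        back = best_ba.hits.get(q)
        if back is not None and back.subject_id == p:
            edges.add(((best_ab.query_genome, p), (best_ab.subject_genome, q)))
    return edges


def build_clusters(
    edges: set,
    genomes: list[GenomeRecord],
) -> list[OrthologousCluster]:
    """Connected components of the union RBH graph, singletons included.

    Cluster ids are assigned deterministically from the sorted smallest
    member of each component, so the partition is invariant under genome
    input order.
    """
    graph = nx.Graph()
    for genome in genomes:
        for pid, _seq in genome.proteome:
            graph.add_node((genome.genome_id, pid))
    graph.add_edges_from(edges)
    components = sorted(nx.connected_components(graph), key=lambda c: min(c))
    clusters = []
    for i, comp in enumerate(components):
        clusters.append(OrthologousCluster(cluster_id=f"OC{i + 1:06d}", members=frozenset(comp)))
    return clusters


def classify_clusters(
    clusters: list[OrthologousCluster],
    analysis_genomes: list[str],
) -> PanGenomeSummary:
    """Core / accessory / unique accounting over the analysis genome set.

    The outgroup (or any genome not listed) is ignored both in the class
    definition and in the per-genome counts.  Per-genome counts are counts
    of clusters the genome participates in, mirroring per-strain OC bars.
    """
    gset = set(analysis_genomes)
    per_genome = {g: {"core": 0, "accessory": 0, "unique": 0} for g in analysis_genomes}
    seen_genomes: set[str] = set()
    total = core = sc_core = 0
    core_ids: list[str] = []
    sc_ids: list[str] = []
    for cluster in clusters:
        present = cluster.genomes() & gset
        seen_genomes |= present
        if not present:
            continue  # outgroup-only cluster
        total += 1
        if present == gset:
            cls = "core"
            core += 1
            core_ids.append(cluster.cluster_id)
            mult = cluster.genome_multiplicity
            if all(mult.get(g, 0) == 1 for g in gset):
                sc_core += 1
                sc_ids.append(cluster.cluster_id)
        elif len(present) == 1:
            cls = "unique"
        else:
            cls = "accessory"
        for g in present:
            per_genome[g][cls] += 1
    missing = gset - seen_genomes
    if missing:
        raise ValueError(f"genomes absent from every cluster (empty proteome?): {sorted(missing)}")
    return PanGenomeSummary(
        per_genome=per_genome,
        total_oc_count=total,
        core_oc_count=core,
        single_copy_core_count=sc_core,
        core_cluster_ids=core_ids,
        single_copy_core_ids=sc_ids,
    )


def all_pairwise_best_hits(
    genomes: list[GenomeRecord],
    identity_min: float = 50.0,
    cov_min: float = 50.0,
    evalue_max: float = 1e-5,
    aligner: ProteinAligner | None = None,
) -> dict[tuple[str, str], BestHitTable]:
    """Directed best-hit tables for every ordered genome pair.

    K-mer indexes are built once per genome and shared across pairs.
    """
    aligner = aligner or ProteinAligner()
    indexes = {g.genome_id: KmerIndex(g.proteome, k=4) for g in genomes}
    by_id = {g.genome_id: g for g in genomes}
    tables: dict[tuple[str, str], BestHitTable] = {}
    ids = [g.genome_id for g in genomes]
    for a in ids:
        for b in ids:
            if a == b:
                continue
            tables[(a, b)] = best_hits(
                by_id[a], by_id[b], identity_min, cov_min, evalue_max,
                aligner=aligner, index_b=indexes[b],
            )
    return tables


def clusters_from_genomes(
    genomes: list[GenomeRecord],
    identity_min: float = 50.0,
    cov_min: float = 50.0,
    evalue_max: float = 1e-5,
    tables: dict[tuple[str, str], BestHitTable] | None = None,
) -> list[OrthologousCluster]:
    """Convenience: all-vs-all best hits -> RBH edges -> clusters."""
    if tables is None:
        tables = all_pairwise_best_hits(genomes, identity_min, cov_min, evalue_max)
    ids = [g.genome_id for g in genomes]
    edges: set = set()
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            edges |= rbh_edges(tables[(a, b)], tables[(b, a)])
    return build_clusters(edges, genomes)


def write_cluster_table(
    clusters: list[OrthologousCluster],
    summary: PanGenomeSummary,
    genome_ids: list[str],
    path,
) -> None:
    """TSV: cluster_id, class, single_copy flag, one protein-list column per genome."""
    core = set(summary.core_cluster_ids)
    sc = set(summary.single_copy_core_ids)
    gset = set(genome_ids)
    with open(path, "w") as fh:
        fh.write("cluster_id\tclass\tsingle_copy\t" + "\t".join(genome_ids) + "\n")
        for cluster in clusters:
            present = cluster.genomes() & gset
            if not present:
                continue
            if cluster.cluster_id in core:
                cls = "core"
            elif len(present) == 1:
                cls = "unique"
            else:
                cls = "accessory"
            cells = []
            for g in genome_ids:
                pids = sorted(p for gg, p in cluster.members if gg == g)
                cells.append(",".join(pids) if pids else "-")
            fh.write(
                f"{cluster.cluster_id}\t{cls}\t{1 if cluster.cluster_id in sc else 0}\t"
                + "\t".join(cells) + "\n"
            )
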