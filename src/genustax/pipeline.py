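"""End-to-end orchestration: genomes in, genus partition and all
intermediate artifacts out.

Stages share one all-vs-all alignment pass: for every ordered genome pair
a directed best-hit table is computed under two filter triples at once —
the clustering triple (identity >= 50, coverage >= 50, E <= 1e-5) and the
AAI triple (no identity floor, coverage >= 50, E <= 1e-5) — so reciprocal
best hits for orthologous clusters and for AAI come from the same
alignments.  POCP runs its own one-way search at identity >= 40.

Everything is deterministic: stages are serial by default, and when a
worker pool is used the per-pair results are collected by key, so output
never depends on worker count.
"""

from __future__ import annotations

import logging
import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .core_phylogeny import (
    Supermatrix,
    concatenate,
    drop_leaf,
    nj_tree,
    patristic_distances,
    progressive_msa,
    protein_distance,
    supermatrix_distances,
    trim_alignment,
    write_supermatrix,
)
from .genus_demarcation import (
    DemarcationConfig,
    GenusPartition,
    demarcate,
    major_clades,
    partition_report,
    write_partition,
)
from .io_formats import (
    GenomeRecord,
    Manifest,
    load_genomes,
    read_manifest,
    write_matrix_tsv,
    write_newick,
)
from .metric_comparison import (
    GroupLabeling,
    correlation_report,
    format_pvalue,
    inter_intra_ttest,
    split_inter_intra,
    write_correlations,
    write_inter_intra,
)
from .orthology import (
    BestHitTable,
    HitFilter,
    OrthologousCluster,
    PanGenomeSummary,
    best_hits_multi,
    build_clusters,
    classify_clusters,
    rbh_edges,
    write_cluster_table,
)
from .pairwise_align import KmerIndex, ProteinAligner
from .similarity_metrics import SimilarityMatrix, metric_matrix, write_long_format

logger = logging.getLogger("genustax")


@dataclass
class PipelineConfig:
    """All thresholds and switches for one pipeline run."""

    oc_identity: float = 50.0
    oc_cov: float = 50.0
    oc_evalue: float = 1e-5
    pocp_identity: float = 40.0
    pocp_cov: float = 50.0
    pocp_evalue: float = 1e-5
    aai_cov: float = 50.0
    aai_evalue: float = 1e-5
    max_gap_fraction: float = 0.2
    distance_source: str = "tree"  # or "supermatrix"
    n_top_clades: int = 3
    compute_pocp: bool = True
    compute_ani: bool = True  # skipped automatically when contigs are absent
    demarcation: DemarcationConfig = field(default_factory=DemarcationConfig)
    threads: int = 1
    # minimum shared exact 4-words before a candidate subject is aligned;
    # 3 discards unrelated-sequence noise while any hit that can clear the
    # E-value cutoff shares far more words than this
    prefilter_min_shared: int = 3

    def __post_init__(self) -> None:
        if self.distance_source not in ("tree", "supermatrix"):
            raise ValueError("distance_source must be 'tree' or 'supermatrix'")
        for v in (self.oc_identity, self.oc_cov, self.pocp_identity, self.pocp_cov, self.aai_cov):
            if not 0 <= v <= 100:
                raise ValueError("identity/coverage thresholds must be in [0, 100]")


@dataclass
class AnalysisResult:
    genomes: list[GenomeRecord]
    clusters: list[OrthologousCluster]
    summary: PanGenomeSummary
    aai: SimilarityMatrix
    pocp: SimilarityMatrix | None
    ani: SimilarityMatrix | None
    supermatrix: Supermatrix
    tree: "dendropy.Tree"  # rooted, outgroup still attached if present
    ingroup_tree: "dendropy.Tree"
    evodist: SimilarityMatrix
    partition: GenusPartition
    clades: GroupLabeling
    tree_cluster_ids: list[str]

    @property
    def ingroup_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes if not g.is_outgroup]


def _pair_job(args):
    a, b, filters, min_shared = args
    aligner = ProteinAligner()
    return (a.genome_id, b.genome_id), best_hits_multi(
        a, b, filters, aligner=aligner, min_shared=min_shared
    )


def all_pair_tables(
    genomes: list[GenomeRecord],
    filters: list[HitFilter],
    threads: int = 1,
    min_shared: int = 1,
) -> dict[tuple[str, str], list[BestHitTable]]:
    """Best-hit tables under every filter for every ordered genome pair."""
    pairs = []
    for a in genomes:
        for b in genomes:
            if a.genome_id != b.genome_id:
                pairs.append((a, b, filters, min_shared))
    results: dict[tuple[str, str], list[BestHitTable]] = {}
    if threads > 1:
        with ProcessPoolExecutor(max_workers=threads) as pool:
            for key, tables in pool.map(_pair_job, pairs, chunksize=4):
                results[key] = tables
    else:
        aligner = ProteinAligner()
        indexes = {g.genome_id: KmerIndex(g.proteome, k=4) for g in genomes}
        for a, b, filts, ms in pairs:
            results[(a.genome_id, b.genome_id)] = best_hits_multi(
                a, b, filts, aligner=aligner, index_b=indexes[b.genome_id], min_shared=ms
            )
    return results


def aai_matrix_from_tables(
    genome_ids: list[str],
    tables: dict[tuple[str, str], BestHitTable],
) -> SimilarityMatrix:
    """AAI over RBH pairs of precomputed (identity-floor-0) best-hit tables."""
    n = len(genome_ids)
    values = np.full((n, n), np.nan)
    np.fill_diagonal(values, 100.0)
    for i, a in enumerate(genome_ids):
        for j in range(i + 1, n):
            b = genome_ids[j]
            ab, ba = tables[(a, b)], tables[(b, a)]
            identities = []
            for p, hit in ab.hits.items():
                back = ba.hits.get(hit.subject_id)
                if back is not None and back.subject_id == p:
                    identities.append(hit.identity_pct)
            values[i, j] = values[j, i] = float(np.mean(identities)) if identities else np.nan
    return SimilarityMatrix("AAI", list(genome_ids), values)


def _select_tree_clusters(
    summary: PanGenomeSummary,
    clusters: list[OrthologousCluster],
    tree_genomes: list[str],
) -> list[OrthologousCluster]:
    """Single-copy core clusters usable for the tree: exactly one member in
    every ingroup genome and, when an outgroup rides along, exactly one
    member there too."""
    by_id = {c.cluster_id: c for c in clusters}
    selected = []
    for cid in summary.single_copy_core_ids:
        cluster = by_id[cid]
        if cluster.is_single_copy_for(tree_genomes):
            selected.append(cluster)
    if not selected:
        raise ValueError(
            "no single-copy core clusters span all tree genomes; "
            "the outgroup may be too distant for the clustering thresholds"
        )
    return selected


def build_core_tree(
    genomes: list[GenomeRecord],
    clusters: list[OrthologousCluster],
    config: PipelineConfig,
):
    """Single-copy core clusters -> MSA -> trim -> supermatrix -> NJ tree."""
    import dendropy  # local import keeps module load light

    ids = sorted(g.genome_id for g in genomes)
    seqs = {g.genome_id: dict(g.proteome) for g in genomes}
    alignments = []
    for cluster in clusters:
        members = sorted(cluster.members)
        cluster_seqs = [(gid, seqs[gid][pid]) for gid, pid in members]
        aln = progressive_msa(cluster_seqs, cluster_id=cluster.cluster_id)
        try:
            aln = trim_alignment(aln, config.max_gap_fraction)
        except ValueError:
            logger.warning("cluster %s fully trimmed; skipped", cluster.cluster_id)
            continue
        alignments.append(aln)
    if not alignments:
        raise ValueError("no alignment columns survive trimming in any cluster")
    sm = concatenate(alignments, ids)
    distances = supermatrix_distances(sm)
    outgroup = next((g.genome_id for g in genomes if g.is_outgroup), None)
    tree = nj_tree(distances, sm.ids, outgroup_id=outgroup)
    return sm, distances, tree


def run_analysis(genomes: list[GenomeRecord], config: PipelineConfig | None = None) -> AnalysisResult:
    """Run every stage in memory and return all results."""
    config = config or PipelineConfig()
    genomes = sorted(genomes, key=lambda g: g.genome_id)
    ingroup = [g for g in genomes if not g.is_outgroup]
    if len(ingroup) < 2:
        raise ValueError("pairwise analysis needs at least 2 non-outgroup genomes")
    ingroup_ids = [g.genome_id for g in ingroup]
    outgroup = next((g for g in genomes if g.is_outgroup), None)

    oc_filter = HitFilter(config.oc_identity, config.oc_cov, config.oc_evalue)
    aai_filter = HitFilter(0.0, config.aai_cov, config.aai_evalue)
    logger.info(
        "orthology filter: identity>=%s cov>=%s E<=%s; POCP filter: identity>=%s cov>=%s E<=%s",
        config.oc_identity, config.oc_cov, config.oc_evalue,
        config.pocp_identity, config.pocp_cov, config.pocp_evalue,
    )

    tables = all_pair_tables(
        genomes, [oc_filter, aai_filter],
        threads=config.threads, min_shared=config.prefilter_min_shared,
    )
    oc_tables = {k: v[0] for k, v in tables.items()}
    aai_tables = {k: v[1] for k, v in tables.items()}

    ids = [g.genome_id for g in genomes]
    edges: set = set()
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            edges |= rbh_edges(oc_tables[(a, b)], oc_tables[(b, a)])
    clusters = build_clusters(edges, genomes)
    summary = classify_clusters(clusters, ingroup_ids)
    logger.info(
        "clusters: %d total, %d core, %d single-copy core",
        summary.total_oc_count, summary.core_oc_count, summary.single_copy_core_count,
    )

    aai = aai_matrix_from_tables(ingroup_ids, aai_tables)

    pocp = None
    if config.compute_pocp:
        pocp = metric_matrix(
            ingroup, "POCP",
            identity_min=config.pocp_identity,
            cov_min=config.pocp_cov,
            evalue_max=config.pocp_evalue,
            min_shared=config.prefilter_min_shared,
        )

    ani = None
    if config.compute_ani and all(g.contigs for g in ingroup):
        ani = metric_matrix(ingroup, "ANI")

    tree_genome_ids = sorted(ids)
    tree_clusters = _select_tree_clusters(summary, clusters, tree_genome_ids)
    sm, sm_dist, tree = build_core_tree(genomes, tree_clusters, config)

    if outgroup is not None:
        ingroup_tree = drop_leaf(tree, outgroup.genome_id)
    else:
        ingroup_tree = tree

    if config.distance_source == "tree":
        evodist = patristic_distances(ingroup_tree)
    else:
        full = SimilarityMatrix("EVODIST", sm.ids, sm_dist)
        evodist = full.submatrix(sorted(ingroup_ids))
    partition = demarcate(ingroup_tree, aai, evodist, config.demarcation)
    n_top = min(config.n_top_clades, len(ingroup_ids))
    clades = major_clades(ingroup_tree, n_top)

    return AnalysisResult(
        genomes=genomes,
        clusters=clusters,
        summary=summary,
        aai=aai,
        pocp=pocp,
        ani=ani,
        supermatrix=sm,
        tree=tree,
        ingroup_tree=ingroup_tree,
        evodist=evodist,
        partition=partition,
        clades=clades,
        tree_cluster_ids=[c.cluster_id for c in tree_clusters],
    )


def write_outputs(result: AnalysisResult, outdir: str | Path, config: PipelineConfig) -> Path:
    """Write the deterministic artifact set for one analysis."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = [g.genome_id for g in result.genomes]

    write_cluster_table(result.clusters, result.summary, ids, outdir / "clusters.tsv")
    with open(outdir / "pangenome_summary.tsv", "w") as fh:
        fh.write("genome_id\tcore\taccessory\tunique\n")
        for gid in result.ingroup_ids:
            counts = result.summary.per_genome[gid]
            fh.write(f"{gid}\t{counts['core']}\t{counts['accessory']}\t{counts['unique']}\n")
        fh.write(
            f"#total_oc={result.summary.total_oc_count}\t"
            f"core_oc={result.summary.core_oc_count}\t"
            f"single_copy_core={result.summary.single_copy_core_count}\n"
        )

    write_matrix_tsv(result.aai, outdir / "aai.tsv")
    matrices = [result.aai, result.evodist]
    if result.pocp is not None:
        write_matrix_tsv(result.pocp, outdir / "pocp.tsv")
        matrices.append(result.pocp)
    if result.ani is not None:
        write_matrix_tsv(result.ani, outdir / "ani.tsv")
        matrices.append(result.ani)
    write_matrix_tsv(result.evodist, outdir / "evodist.tsv")
    write_long_format(matrices, outdir / "metrics_long.tsv")

    write_supermatrix(result.supermatrix, outdir / "supermatrix.faa", outdir / "partitions.tsv")
    write_newick(result.tree, outdir / "tree.nwk")

    try:
        report = correlation_report(matrices)
        write_correlations(report, outdir / "correlations.tsv")
    except ValueError as exc:
        logger.warning("correlations skipped: %s", exc)
        report = None

    rows = []
    ttest_lines = []
    for matrix in matrices:
        try:
            intra, inter = split_inter_intra(matrix, result.clades)
        except ValueError:
            continue
        rows += [(matrix.metric, "intra", v) for v in intra]
        rows += [(matrix.metric, "inter", v) for v in inter]
        if len(intra) >= 2 and len(inter) >= 2:
            try:
                t, p = inter_intra_ttest(intra, inter)
                ttest_lines.append(f"{matrix.metric}\tt={t:.4f}\tp={format_pvalue(p)}")
            except ValueError:
                pass
    write_inter_intra(rows, outdir / "inter_intra.tsv")
    (outdir / "ttests.txt").write_text("\n".join(ttest_lines) + "\n")

    write_partition(result.partition, outdir / "genera.tsv")
    report_df = partition_report(result.partition, result.aai, result.evodist, result.ani)
    report_df.to_csv(outdir / "genus_diagnostics.tsv", sep="\t", index=False, na_rep="NA")

    with open(outdir / "run.log", "w") as fh:
        fh.write(f"genustax {__version__}\n")
        fh.write(
            f"oc_filter: identity>={config.oc_identity} cov>={config.oc_cov} E<={config.oc_evalue}\n"
        )
        fh.write(
            f"pocp_filter: identity>={config.pocp_identity} cov>={config.pocp_cov} E<={config.pocp_evalue}\n"
        )
        fh.write(
            f"aai_filter: identity>=0 cov>={config.aai_cov} E<={config.aai_evalue}\n"
        )
        fh.write(
            f"demarcation: aai_min={config.demarcation.aai_min} dist_max={config.demarcation.dist_max} "
            f"aai_pass_fraction={config.demarcation.aai_pass_fraction}\n"
        )
        fh.write(f"distance_source: {config.distance_source}\n")
        fh.write(f"n_genomes: {len(result.genomes)} (ingroup {len(result.ingroup_ids)})\n")
        fh.write(f"n_tree_clusters: {len(result.tree_cluster_ids)}\n")
        fh.write(f"n_genera: {result.partition.n_groups}\n")
    return outdir


def run_all(
    manifest_path: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """Load a manifest, run every stage, and write all artifacts."""
    config = config or PipelineConfig()
    manifest = read_manifest(manifest_path)
    genomes = load_genomes(manifest, Path(manifest_path).parent)
    result = run_analysis(genomes, config)
    write_outputs(result, outdir, config)
    return result
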