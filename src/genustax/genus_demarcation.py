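"""Genus demarcation: threshold-constrained monophyletic partitioning.

Genomes are partitioned into genera by walking the rooted core-genome
tree from the root.  A clade is emitted as one genus when (i) its maximum
pairwise patristic (evolutionary) distance is at most ``dist_max`` and
(ii) at least ``aai_pass_fraction`` of its pairwise AAI values reach
``aai_min``.  Clades that fail are split into their children and tested
again; leaves pass trivially, so singleton genera are allowed.  Emitted
genera are therefore the *maximal* compliant clades — few and large — and
every genus is monophyletic by construction.

The AAI criterion is a pass fraction rather than a strict minimum: a
genus-level clade may legitimately contain one aberrant low-AAI pair
while the overwhelming majority of its pairs clear the threshold, and a
strict rule would shatter such clades.  The distance criterion stays a
strict maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .metric_comparison import GroupLabeling
from .similarity_metrics import SimilarityMatrix

AAI_MIN_DEFAULT = 70.0
DIST_MAX_DEFAULT = 0.4
AAI_PASS_FRACTION_DEFAULT = 0.95


@dataclass
class DemarcationConfig:
    aai_min: float = AAI_MIN_DEFAULT  # percent AAI a pair must reach
    dist_max: float = DIST_MAX_DEFAULT  # substitutions/site, strict max over pairs
    aai_pass_fraction: float = AAI_PASS_FRACTION_DEFAULT

    def __post_init__(self) -> None:
        if not 0 < self.aai_min < 100:
            raise ValueError("aai_min must be in (0, 100)")
        if self.dist_max < 0:
            raise ValueError("dist_max must be >= 0")
        if not 0.5 < self.aai_pass_fraction <= 1:
            raise ValueError("aai_pass_fraction must be in (0.5, 1]")


@dataclass
class GenusGroup:
    group_id: str
    members: list[str]
    min_aai: float = math.nan
    median_aai: float = math.nan
    max_dist: float = math.nan
    aai_pass_fraction: float = math.nan


@dataclass
class GenusPartition:
    groups: list[GenusGroup] = field(default_factory=list)

    def labeling(self) -> GroupLabeling:
        labels = {m: g.group_id for g in self.groups for m in g.members}
        return GroupLabeling(labels, source="demarcation")

    def group_of(self, genome_id: str) -> str:
        for g in self.groups:
            if genome_id in g.members:
                return g.group_id
        raise KeyError(genome_id)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def _pair_values(matrix: SimilarityMatrix, members: list[str]) -> list[float]:
    vals = []
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            vals.append(matrix.value(a, b))
    return vals


def _clade_passes(
    members: list[str],
    aai: SimilarityMatrix,
    evodist: SimilarityMatrix,
    config: DemarcationConfig,
) -> bool:
    if len(members) == 1:
        return True
    dists = _pair_values(evodist, members)
    if any(math.isnan(d) for d in dists):
        raise ValueError("missing evolutionary distance inside a candidate clade")
    if max(dists) > config.dist_max:
        return False
    aais = [v for v in _pair_values(aai, members) if not math.isnan(v)]
    if not aais:
        # no AAI information at all: fall back to the distance criterion alone
        return True
    frac = sum(1 for v in aais if v >= config.aai_min) / len(aais)
    return frac >= config.aai_pass_fraction


def demarcate(
    tree: dendropy.Tree,
    aai: SimilarityMatrix,
    evodist: SimilarityMatrix,
    config: DemarcationConfig | None = None,
) -> GenusPartition:
    """Partition the tree's leaves into maximal threshold-compliant clades.

    The tree must already be rooted with the outgroup removed; every leaf
    must appear in both matrices.  Missing AAI entries are excluded from
    the pass-fraction denominator.
    """
    config = config or DemarcationConfig()
    leaf_labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    for label in leaf_labels:
        for matrix in (aai, evodist):
            if label not in matrix.genome_ids:
                raise ValueError(f"genome {label!r} missing from {matrix.metric} matrix")

    emitted: list[list[str]] = []

    def visit(node) -> None:
        members = sorted(leaf.taxon.label for leaf in node.leaf_iter())
        if _clade_passes(members, aai, evodist, config):
            emitted.append(members)
            return
        for child in node.child_nodes():
            visit(child)

    visit(tree.seed_node)

    emitted.sort(key=lambda m: m[0])
    groups = []
    for i, members in enumerate(emitted):
        aais = [v for v in _pair_values(aai, members) if not math.isnan(v)]
        dists = _pair_values(evodist, members)
        groups.append(
            GenusGroup(
                group_id=f"genus_{i + 1:02d}",
                members=members,
                min_aai=min(aais) if aais else math.nan,
                median_aai=float(np.median(aais)) if aais else math.nan,
                max_dist=max(dists) if dists else math.nan,
                aai_pass_fraction=(
                    sum(1 for v in aais if v >= config.aai_min) / len(aais)
                    if aais
                    else math.nan
                ),
            )
        )
    return GenusPartition(groups)


def major_clades(tree: dendropy.Tree, n_top: int = 3) -> GroupLabeling:
    """The *n_top* deepest disjoint clades of a rooted tree.

    Starting from the whole tree, the largest remaining clade is split at
    its root until *n_top* groups exist (ties broken by smallest leaf
    label) — a reproducible stand-in for reading major clades off a
    figure."""
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if n_top < 1 or n_top > len(leaves):
        raise ValueError("n_top must be between 1 and the number of leaves")
    clades = [tree.seed_node]

    def size(node) -> int:
        return sum(1 for _ in node.leaf_iter())

    def min_leaf(node) -> str:
        return min(leaf.taxon.label for leaf in node.leaf_iter())

    while len(clades) < n_top:
        splittable = [c for c in clades if c.child_nodes()]
        if not splittable:
            raise ValueError("tree has too few internal nodes to split further")
        target = sorted(splittable, key=lambda c: (-size(c), min_leaf(c)))[0]
        clades.remove(target)
        clades.extend(target.child_nodes())

    clades.sort(key=min_leaf)
    labels = {}
    for i, clade in enumerate(clades):
        for leaf in clade.leaf_iter():
            labels[leaf.taxon.label] = f"clade_{i + 1}"
    return GroupLabeling(labels, source="major_clades")


def is_monophyletic(tree: dendropy.Tree, members: list[str]) -> bool:
    """True iff *members* equals the leaf set under its MRCA on *tree*."""
    taxa = [t for t in tree.taxon_namespace if t.label in set(members)]
    if len(taxa) == 1:
        return True
    tree.is_rooted = True
    mrca = tree.mrca(taxa=taxa)
    clade_leaves = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    return clade_leaves == set(members)


def partition_report(
    partition: GenusPartition,
    aai: SimilarityMatrix,
    evodist: SimilarityMatrix,
    ani: SimilarityMatrix | None = None,
) -> "pd.DataFrame":
    """Per-group summary statistics (min/median/max of each metric over
    intra-group pairs; 'NA' for singletons) plus a global inter/intra split."""
    import pandas as pd

    matrices = [aai, evodist] + ([ani] if ani is not None else [])
    rows = []
    for group in partition.groups:
        row: dict = {"group_id": group.group_id, "n_members": len(group.members),
                     "members": ",".join(group.members)}
        for matrix in matrices:
            vals = [v for v in _pair_values(matrix, group.members) if not math.isnan(v)]
            prefix = matrix.metric.lower()
            if vals:
                row[f"{prefix}_min"] = min(vals)
                row[f"{prefix}_median"] = float(np.median(vals))
                row[f"{prefix}_max"] = max(vals)
            else:
                row[f"{prefix}_min"] = row[f"{prefix}_median"] = row[f"{prefix}_max"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_partition(partition: GenusPartition, path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tgroup_id\n")
        for group in partition.groups:
            for member in group.members:
                fh.write(f"{member}\t{group.group_id}\n")


def annotate_tree(tree: dendropy.Tree, partition: GenusPartition) -> dendropy.Tree:
    """Copy of *tree* with group ids appended to leaf labels."""
    labeled = tree.clone(depth=1)
    lookup = {m: g.group_id for g in partition.groups for m in g.members}
    for leaf in labeled.leaf_node_iter():
        if leaf.taxon.label in lookup:
            leaf.taxon.label = f"{leaf.taxon.label}|{lookup[leaf.taxon.label]}"
    return labeled
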