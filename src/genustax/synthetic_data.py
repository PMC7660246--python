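"""Pan-genome simulator with known ground truth.

Genomes descend from one ancestral gene set along a known tree.  Each gene
evolves at the codon level: amino-acid substitution events arrive as a
Poisson process (``aa_subst_rate`` events per site per unit branch
length), each event drawing the new residue uniformly from the 20 amino
acids and rewriting the affected codon with a uniform synonymous codon.
Because the replacement residue is uniform, the expected pairwise identity
at planted path divergence d has the closed form

    E[identity] = 100 * (exp(-d) + (1 - exp(-d)) / 20)

which the pipeline's AAI estimates can be checked against analytically.
Gene gain (novel random genes), loss, and within-lineage duplication are
Poisson/Bernoulli events on branches; every event is recorded so the
planted orthology, genus labels, and per-pair divergences are exact.

The model is deliberately simple — uniform replacement rather than an
empirical exchangeability matrix, no within-gene indels — because
analytic expectations matter more here than realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from Bio.Data import CodonTable

from .io_formats import GenomeRecord, Manifest, write_fasta, write_manifest

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# codons per residue from the standard genetic code, in sorted order
_CODONS_BY_AA: list[list[str]] = [[] for _ in range(20)]
for _codon, _aa in sorted(CodonTable.unambiguous_dna_by_id[1].forward_table.items()):
    if _aa in _AA_INDEX:
        _CODONS_BY_AA[_AA_INDEX[_aa]].append(_codon)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated pan-genome.

    Defaults plant three genera of four genomes each, with within-genus
    path divergence 0.3 substitutions/site and between-genus divergence
    0.6 — straddling the demarcation thresholds — over a shared core of
    100 genes of 150–300 residues, plus moderate gene gain, loss and
    duplication.
    """

    seed: int
    n_genera: int = 3
    genomes_per_genus: int = 4
    intra_depth: float = 0.3
    inter_depth: float = 0.6
    newick: str | None = None  # overrides the planted-genus tree shape
    n_core: int = 100
    gene_len_range: tuple[int, int] = (150, 300)
    gain_rate: float = 0.2  # novel genes per resident gene per unit branch length
    loss_rate: float = 0.1  # losses per gene per unit branch length
    dup_prob: float = 0.02  # per-gene duplication probability per branch
    aa_subst_rate: float = 1.0  # substitutions per site per unit branch length
    # synonymous codon-resampling events per codon per unit branch length;
    # makes nucleotide identity decay faster than amino-acid identity, as
    # synonymous sites do in real genomes
    syn_subst_rate: float = 3.0
    make_nucleotide: bool = False
    outgroup_depth: float | None = None  # tip-to-root distance of an added outgroup

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for r in (self.gain_rate, self.loss_rate, self.dup_prob, self.aa_subst_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.newick is None and not self.intra_depth < self.inter_depth:
            raise ValueError("planted genera require intra_depth < inter_depth")
        if self.n_core < 1:
            raise ValueError("n_core must be >= 1")


@dataclass
class SimulationTruth:
    newick: str
    genus_labels: dict[str, str]  # genome_id -> genus label (outgroup excluded)
    orthology: dict[tuple[str, str], str]  # (genome_id, protein_id) -> family id
    pair_divergence: dict[tuple[str, str], float]  # unordered, keyed sorted
    inventories: dict[str, int]  # genome_id -> number of proteins
    outgroup_id: str | None = None

    def divergence(self, a: str, b: str) -> float:
        return self.pair_divergence[tuple(sorted((a, b)))]

    def families(self) -> dict[str, set[tuple[str, str]]]:
        fams: dict[str, set[tuple[str, str]]] = {}
        for key, fam in self.orthology.items():
            fams.setdefault(fam, set()).add(key)
        return fams


def _planted_tree(config: SimulationConfig) -> tuple[str, dict[str, str]]:
    tip = config.intra_depth / 2.0
    stem = (config.inter_depth - config.intra_depth) / 2.0
    genera = []
    labels: dict[str, str] = {}
    for g in range(1, config.n_genera + 1):
        tips = []
        for i in range(1, config.genomes_per_genus + 1):
            gid = f"g{g}_{i}"
            labels[gid] = f"genus{g}"
            tips.append(f"{gid}:{tip}")
        genera.append(f"({','.join(tips)}):{stem}")
    return f"({','.join(genera)});", labels


class _Gene:
    __slots__ = ("family", "aa", "codons")

    def __init__(self, family: str, aa: np.ndarray, codons: list[str]):
        self.family = family
        self.aa = aa
        self.codons = codons

    def copy(self) -> "_Gene":
        return _Gene(self.family, self.aa.copy(), list(self.codons))


def _random_gene(rng: np.random.Generator, family: str, length: int) -> _Gene:
    aa = rng.integers(0, 20, size=length).astype(np.int64)
    codons = [
        _CODONS_BY_AA[a][rng.integers(0, len(_CODONS_BY_AA[a]))] for a in aa
    ]
    return _Gene(family, aa, codons)


def _evolve_gene(
    gene: _Gene, t: float, rate: float, syn_rate: float, rng: np.random.Generator
) -> None:
    length = len(gene.aa)
    n_events = rng.poisson(rate * t * length)
    if n_events:
        positions = rng.integers(0, length, size=n_events)
        new_aas = rng.integers(0, 20, size=n_events)
        for pos, aa in zip(positions, new_aas):
            gene.aa[pos] = aa
            gene.codons[pos] = _CODONS_BY_AA[aa][rng.integers(0, len(_CODONS_BY_AA[aa]))]
    if syn_rate > 0:
        n_syn = rng.poisson(syn_rate * t * length)
        for pos in rng.integers(0, length, size=n_syn):
            aa = gene.aa[pos]
            gene.codons[pos] = _CODONS_BY_AA[aa][rng.integers(0, len(_CODONS_BY_AA[aa]))]


def simulate_pangenome(config: SimulationConfig) -> tuple[list[GenomeRecord], SimulationTruth]:
    """Run the simulator; identical seed and config give identical output."""
    rng = np.random.default_rng(config.seed)

    if config.newick is not None:
        newick, labels = config.newick, {}
    else:
        newick, labels = _planted_tree(config)
    outgroup_id = None
    if config.outgroup_depth is not None:
        inner = newick.rstrip(";\n")
        # deepest split: outgroup sister to everything else
        outgroup_id = "outgroup"
        newick = f"({inner}:{config.outgroup_depth / 2.0},outgroup:{config.outgroup_depth / 2.0});"
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True, rooting="force-rooted"
    )

    # ancestral core
    lo, hi = config.gene_len_range
    ancestor = [
        _random_gene(rng, f"fam{i + 1:05d}", int(rng.integers(lo, hi + 1)))
        for i in range(config.n_core)
    ]
    gain_counter = [0]

    genome_genes: dict[str, list[_Gene]] = {}

    genome_depth: dict[str, float] = {}

    def descend(node, genes: list[_Gene], depth: float = 0.0) -> None:
        children = node.child_nodes()
        if not children:
            genome_genes[node.taxon.label] = genes
            genome_depth[node.taxon.label] = depth
            return
        for child in children:
            t = child.edge.length or 0.0
            branch_genes = [g.copy() for g in genes]
            # losses
            if config.loss_rate > 0 and t > 0 and branch_genes:
                p_loss = 1.0 - np.exp(-config.loss_rate * t)
                keep = rng.random(len(branch_genes)) >= p_loss
                branch_genes = [g for g, k in zip(branch_genes, keep) if k]
            # duplications
            if config.dup_prob > 0 and branch_genes:
                dup = rng.random(len(branch_genes)) < config.dup_prob
                branch_genes.extend(g.copy() for g, d in zip(branch_genes, dup) if d)
            # gains
            if config.gain_rate > 0 and t > 0:
                n_gain = rng.poisson(config.gain_rate * t * max(len(branch_genes), 1))
                for _ in range(n_gain):
                    gain_counter[0] += 1
                    branch_genes.append(
                        _random_gene(rng, f"famG{gain_counter[0]:05d}", int(rng.integers(lo, hi + 1)))
                    )
            # substitutions
            for g in branch_genes:
                _evolve_gene(g, t, config.aa_subst_rate, config.syn_subst_rate, rng)
            descend(child, branch_genes, depth + t)

    descend(tree.seed_node, ancestor)

    # shared genome layout so synteny (hence fragment-based ANI) is conserved:
    # every genome places core families in the same order on the same contig,
    # separated by ancestral spacers that accumulate per-genome substitutions
    layout = None
    if config.make_nucleotide:
        n_contigs = int(rng.integers(2, 6))
        core_order = [f"fam{i + 1:05d}" for i in range(config.n_core)]
        layout = {
            "n_contigs": n_contigs,
            "assignment": {fam: int(rng.integers(0, n_contigs)) for fam in core_order},
            "spacers": {
                fam: "".join("ACGT"[b] for b in rng.integers(0, 4, size=int(rng.integers(50, 201))))
                for fam in core_order
            },
            "order": core_order,
        }

    genomes: list[GenomeRecord] = []
    orthology: dict[tuple[str, str], str] = {}
    inventories: dict[str, int] = {}
    for gid in sorted(genome_genes):
        genes = genome_genes[gid]
        fam_counts: dict[str, int] = {}
        proteome: list[tuple[str, str]] = []
        contigs: list[tuple[str, str]] | None = None
        nt_by_family: dict[str, list[str]] = {}
        for gene in genes:
            fam_counts[gene.family] = fam_counts.get(gene.family, 0) + 1
            copy = fam_counts[gene.family]
            pid = f"{gene.family}" if copy == 1 else f"{gene.family}.{copy}"
            seq = "".join(AMINO_ACIDS[a] for a in gene.aa)
            proteome.append((pid, seq))
            orthology[(gid, pid)] = gene.family
            nt_by_family.setdefault(gene.family, []).append("".join(gene.codons))
        if layout is not None:
            contigs = _assemble_contigs(gid, nt_by_family, layout, genome_depth[gid], config, rng)
        if not proteome:
            raise ValueError(f"simulation produced an empty genome for {gid}")
        genomes.append(GenomeRecord(gid, proteome, contigs, is_outgroup=(gid == outgroup_id)))
        inventories[gid] = len(proteome)

    # planted path divergences from the tree (in substitutions/site)
    pdm = tree.phylogenetic_distance_matrix()
    pair_divergence: dict[tuple[str, str], float] = {}
    taxa = list(tree.taxon_namespace)
    for i, ta in enumerate(taxa):
        for tb in taxa[i + 1 :]:
            key = tuple(sorted((ta.label, tb.label)))
            pair_divergence[key] = config.aa_subst_rate * pdm.patristic_distance(ta, tb)

    truth = SimulationTruth(
        newick=newick,
        genus_labels=labels,
        orthology=orthology,
        pair_divergence=pair_divergence,
        inventories=inventories,
        outgroup_id=outgroup_id,
    )
    return genomes, truth


def _assemble_contigs(
    genome_id: str,
    nt_by_family: dict[str, list[str]],
    layout: dict,
    depth: float,
    config: "SimulationConfig",
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    """Lay each genome's genes onto the shared ancestral contig layout.

    Core families sit in a fixed order on fixed contigs behind ancestral
    50–200 bp spacers (mutated per genome at the lineage's nucleotide
    divergence); gained families are appended with genome-private spacers.
    Every second contig is emitted reverse-complemented to exercise strand
    handling downstream.
    """
    n_contigs = layout["n_contigs"]
    # per-site substitution probability of a neutral spacer on this lineage
    p_spacer = 1.0 - expected_identity(depth * config.aa_subst_rate, 4) / 100.0
    parts: list[list[str]] = [[] for _ in range(n_contigs)]
    for fam in layout["order"]:
        copies = nt_by_family.get(fam)
        if not copies:
            continue  # lost on this lineage
        c = layout["assignment"][fam]
        spacer = mutate_nucleotide(layout["spacers"][fam], p_spacer, rng)
        for copy_nt in copies:
            parts[c].append(spacer + copy_nt)
    for fam in sorted(f for f in nt_by_family if f not in layout["assignment"]):
        c = int(fam[4:].lstrip("G") or 0) % n_contigs
        for copy_nt in nt_by_family[fam]:
            spacer = "".join("ACGT"[b] for b in rng.integers(0, 4, size=int(rng.integers(50, 201))))
            parts[c].append(spacer + copy_nt)
    contigs = []
    for c in range(n_contigs):
        seq = "".join(parts[c])
        if not seq:
            seq = "".join("ACGT"[b] for b in rng.integers(0, 4, size=int(rng.integers(200, 401))))
        if c % 2 == 1:
            seq = seq.translate(_COMPLEMENT)[::-1]
        contigs.append((f"{genome_id}_c{c + 1}", seq))
    return contigs


def expected_identity(path_divergence: float, alphabet_size: int = 20) -> float:
    """Closed-form expected percent identity under uniform replacement.

    A site is untouched with probability exp(-d); otherwise its final
    state is uniform over the alphabet and matches with probability
    1/alphabet_size.  Use ``alphabet_size=4`` for nucleotides.
    """
    if path_divergence < 0:
        raise ValueError("divergence must be >= 0")
    p_same = np.exp(-path_divergence)
    return float(100.0 * (p_same + (1.0 - p_same) / alphabet_size))


def mutate_nucleotide(seq: str, p: float, rng: np.random.Generator) -> str:
    """Substitute each site with probability *p* to a uniformly chosen
    different base — expected identity to the input is 100·(1−p)."""
    bases = "ACGT"
    arr = list(seq)
    hits = np.nonzero(rng.random(len(arr)) < p)[0]
    for i in hits:
        alternatives = [b for b in bases if b != arr[i]]
        arr[i] = alternatives[rng.integers(0, 3)]
    return "".join(arr)


def write_simulation(
    genomes: list[GenomeRecord],
    truth: SimulationTruth,
    outdir: str | Path,
) -> Path:
    """Emit the manifest + FASTA layout the pipeline consumes, plus truth files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for g in genomes:
        ppath = f"{g.genome_id}.faa"
        write_fasta(g.proteome, outdir / ppath)
        cpath = None
        if g.contigs:
            cpath = f"{g.genome_id}.fna"
            write_fasta(g.contigs, outdir / cpath)
        entries.append((g.genome_id, ppath, cpath, g.is_outgroup))
    write_manifest(Manifest(entries), outdir / "manifest.tsv")
    (outdir / "truth_tree.nwk").write_text(truth.newick + "\n")
    with open(outdir / "truth_labels.tsv", "w") as fh:
        fh.write("genome_id\tgenus\n")
        for gid, genus in sorted(truth.genus_labels.items()):
            fh.write(f"{gid}\t{genus}\n")
    with open(outdir / "truth_orthology.tsv", "w") as fh:
        fh.write("genome_id\tprotein_id\tfamily\n")
        for (gid, pid), fam in sorted(truth.orthology.items()):
            fh.write(f"{gid}\t{pid}\t{fam}\n")
    return outdir
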