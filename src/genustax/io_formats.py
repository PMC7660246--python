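"""Readers and writers for the pipeline's plain-text formats.

FASTA (protein and nucleotide), Newick trees with branch lengths, the
tab-separated genome manifest, and tab-separated similarity matrices.
Sequence validation lives here so every downstream stage can assume clean
alphabets: proteins use the 20 residues plus ambiguity codes X/B/Z (a stop
``*`` is allowed only at the termini and is stripped), nucleotides use
ACGTN.  All sequences are upper-cased on input.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYXBZ")
NUCLEOTIDE_ALPHABET = frozenset("ACGTN")


class FastaError(ValueError):
    """Malformed or invalid FASTA content."""


@dataclass
class GenomeRecord:
    """One genome: its identifier, proteome and optional assembly contigs.

    ``len(record.proteome)`` is the T term of the POCP formula for this
    genome.  ``is_outgroup`` marks the genome used only to root the tree.
    """

    genome_id: str
    proteome: list[tuple[str, str]]
    contigs: list[tuple[str, str]] | None = None
    is_outgroup: bool = False

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for pid, _seq in self.proteome:
            if pid in seen:
                raise FastaError(
                    f"duplicate protein id {pid!r} in genome {self.genome_id!r}"
                )
            seen.add(pid)

    @property
    def n_proteins(self) -> int:
        return len(self.proteome)

    def protein(self, protein_id: str) -> str:
        for pid, seq in self.proteome:
            if pid == protein_id:
                return seq
        raise KeyError(protein_id)


@dataclass
class Manifest:
    """Tab-separated genome listing: id, proteome path, contigs path, outgroup flag."""

    entries: list[tuple[str, str, str | None, bool]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e[0] for e in self.entries]
        if len(ids) != len(set(ids)):
            dup = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate genome ids in manifest: {dup}")
        if sum(1 for e in self.entries if e[3]) > 1:
            raise ValueError("manifest may declare at most one outgroup genome")


def _validate_sequence(record_id: str, seq: str, alphabet: str) -> str:
    seq = seq.upper()
    if not seq:
        raise FastaError(f"record {record_id!r} has an empty sequence")
    if alphabet == "protein":
        # stop codons at the ends are an artifact of gene calling; inside the
        # sequence they indicate a pseudogene/frameshift and are rejected
        seq = seq.strip("*")
        if not seq:
            raise FastaError(f"record {record_id!r} is only stop codons")
        if "*" in seq:
            raise FastaError(
                f"record {record_id!r} has an internal '*' at position {seq.index('*') + 1}"
            )
        allowed = PROTEIN_ALPHABET
    elif alphabet == "nucleotide":
        allowed = NUCLEOTIDE_ALPHABET
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    for i, ch in enumerate(seq):
        if ch not in allowed:
            raise FastaError(
                f"record {record_id!r} has illegal character {ch!r} at position {i + 1}"
            )
    return seq


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered ``[(id, sequence), ...]`` list.

    Sequences are upper-cased and validated against *alphabet*
    (``"protein"`` or ``"nucleotide"``); terminal ``*`` is stripped from
    proteins.  Duplicate ids, illegal characters and empty files raise
    :class:`FastaError`.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, _validate_sequence(rec.id, str(rec.seq), alphabet)))
    if not records:
        raise FastaError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write ``(id, sequence)`` pairs as FASTA, wrapping lines at *width*."""
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_genome(
    genome_id: str,
    proteome_path: str | Path,
    contigs_path: str | Path | None = None,
    is_outgroup: bool = False,
) -> GenomeRecord:
    proteome = read_fasta(proteome_path, "protein")
    contigs = read_fasta(contigs_path, "nucleotide") if contigs_path else None
    return GenomeRecord(genome_id, proteome, contigs, is_outgroup)


def read_manifest(path: str | Path) -> Manifest:
    """Parse a tab-separated manifest: genome_id, proteome, [contigs], [outgroup flag].

    The contigs column may be ``-`` or empty; the outgroup flag is 1/0
    (default 0).  Lines starting with ``#`` are comments.
    """
    entries: list[tuple[str, str, str | None, bool]] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{ln}: manifest line needs at least genome_id and proteome path")
        gid, prot = parts[0], parts[1]
        contigs = parts[2] if len(parts) > 2 and parts[2] not in ("", "-") else None
        outgroup = len(parts) > 3 and parts[3].strip() in ("1", "true", "True")
        entries.append((gid, prot, contigs, outgroup))
    return Manifest(entries)


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#genome_id\tproteome\tcontigs\toutgroup\n")
        for gid, prot, contigs, outgroup in manifest.entries:
            fh.write(f"{gid}\t{prot}\t{contigs or '-'}\t{1 if outgroup else 0}\n")


def load_genomes(manifest: Manifest, base_dir: str | Path | None = None) -> list[GenomeRecord]:
    """Load every genome listed in *manifest* (paths relative to *base_dir*)."""
    base = Path(base_dir) if base_dir else Path(".")
    genomes = []
    for gid, prot, contigs, outgroup in manifest.entries:
        pp = base / prot if not Path(prot).is_absolute() else Path(prot)
        cp = None
        if contigs:
            cp = base / contigs if not Path(contigs).is_absolute() else Path(contigs)
        genomes.append(read_genome(gid, pp, cp, outgroup))
    return genomes


# -- Newick ------------------------------------------------------------------

def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree (path or literal string) into a dendropy Tree.

    Edges without a branch length default to 0 with a warning; a tree with
    no leaves is an error.
    """
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    tree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True,
        rooting="force-rooted",
    )
    leaves = tree.leaf_nodes()
    if not leaves:
        raise ValueError("Newick tree has no leaves")
    missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            missing += 1
    if missing:
        warnings.warn(f"{missing} edges had no branch length; defaulted to 0", stacklevel=2)
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialize *tree* as Newick with branch lengths; write to *path* if given."""
    text = tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True)
    text = text.strip() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# -- matrices ----------------------------------------------------------------

def write_matrix_tsv(matrix: "SimilarityMatrix", path: str | Path) -> None:
    """Write a similarity matrix as TSV with genome ids as row/column headers."""
    import numpy as np

    with open(path, "w") as fh:
        fh.write("genome_id\t" + "\t".join(matrix.genome_ids) + "\n")
        for i, gid in enumerate(matrix.genome_ids):
            cells = []
            for j in range(len(matrix.genome_ids)):
                v = matrix.values[i, j]
                cells.append("NA" if np.isnan(v) else f"{v:.6f}")
            fh.write(gid + "\t" + "\t".join(cells) + "\n")


def read_matrix_tsv(path: str | Path, metric: str) -> "SimilarityMatrix":
    import numpy as np

    from .similarity_metrics import SimilarityMatrix

    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0].split("\t")[1:]
    rows = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        rows.append([np.nan if c == "NA" else float(c) for c in parts[1:]])
    return SimilarityMatrix(metric=metric, genome_ids=list(header), values=np.array(rows, dtype=float))


# -- basic statistics --------------------------------------------------------

def gc_content(contigs: Sequence[tuple[str, str]]) -> float:
    """G+C percentage over all contigs, with N excluded from the denominator."""
    if not contigs:
        raise ValueError("gc_content requires at least one contig")
    gc = 0
    atgc = 0
    for _cid, seq in contigs:
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        atgc += sum(s.count(b) for b in "ACGT")
    if atgc == 0:
        raise ValueError("gc_content undefined: no unambiguous bases (all-N input)")
    return 100.0 * gc / atgc
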