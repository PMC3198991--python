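"""Readers and writers for the formats the pipeline touches.

All coordinates are 0-based half-open (BED convention) everywhere in the
package.  Reverse-strand genes are reverse-complemented on extraction, so
codon statistics downstream always see the coding strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_ALPHABET = set("ACGTN")
GAP = "-"


class SeqIOError(ValueError):
    """Malformed or inconsistent sequence/annotation input."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence; the unit of classification."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("protein record id must be non-empty")
        if not self.residues:
            raise SeqIOError(f"protein record {self.id!r} is empty")
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise SeqIOError(
                f"protein record {self.id!r} contains illegal residues: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GenomeRecord:
    """A nucleotide sequence (genome or contig)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("genome record id must be non-empty")
        if not self.sequence:
            raise SeqIOError(f"genome record {self.id!r} is empty")
        bad = set(self.sequence) - NUCLEOTIDE_ALPHABET
        if bad:
            raise SeqIOError(
                f"genome record {self.id!r} contains illegal bases: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignedSet:
    """A multiple alignment: equal-length gapped rows over a protein alphabet."""

    records: tuple[tuple[str, str], ...]
    n_columns: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if not self.records:
            raise SeqIOError("alignment contains no sequences")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise SeqIOError(f"ragged alignment: row lengths {sorted(lengths)}")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise SeqIOError("duplicate ids in alignment")
        object.__setattr__(self, "n_columns", lengths.pop())
        empty = [
            c
            for c in range(self.n_columns)
            if all(seq[c] == GAP for _, seq in self.records)
        ]
        if empty:
            warnings.warn(
                f"alignment has {len(empty)} empty (all-gap) columns", stacklevel=3
            )
        # ungapped rows must be valid proteins ("X" stands in for all-gap rows)
        for rid, seq in self.records:
            ProteinRecord(id=rid, residues=seq.replace(GAP, "") or "X")

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def row(self, rid: str) -> str:
        for r, seq in self.records:
            if r == rid:
                return seq
        raise KeyError(rid)

    def ungapped(self) -> list[ProteinRecord]:
        return [
            ProteinRecord(id=rid, residues=seq.replace(GAP, ""))
            for rid, seq in self.records
        ]


@dataclass(frozen=True)
class GeneAnnotation:
    """A CDS location on a genome, 0-based half-open."""

    gene_id: str
    genome_id: str
    start: int
    end: int
    strand: Literal["+", "-"] = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise SeqIOError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise SeqIOError(f"gene {self.gene_id!r}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start


def read_fasta(
    path: str | Path, alphabet: Literal["protein", "nucleotide"]
) -> list[ProteinRecord] | list[GenomeRecord]:
    """Read a FASTA file into validated records.

    Lowercase input is uppercased; duplicate ids and illegal characters for
    the declared alphabet are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cls = ProteinRecord if alphabet == "protein" else GenomeRecord
    records: list = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if alphabet == "protein":
            records.append(cls(id=rec.id, residues=seq, description=rec.description))
        else:
            records.append(cls(id=rec.id, sequence=seq, description=rec.description))
    if not records:
        raise SeqIOError(f"no FASTA records in {path}")
    return records


def write_fasta(
    records: Iterable[ProteinRecord | GenomeRecord], path: str | Path, width: int = 70
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            seq = rec.residues if isinstance(rec, ProteinRecord) else rec.sequence
            header = rec.id if not rec.description or rec.description == rec.id else (
                rec.description if rec.description.startswith(rec.id)
                else f"{rec.id} {rec.description}"
            )
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_aligned_fasta(path: str | Path) -> AlignedSet:
    """Read an aligned FASTA file; rows must share one length."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise SeqIOError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        rows.append((rec.id, str(rec.seq).upper()))
    if not rows:
        raise SeqIOError(f"no FASTA records in {path}")
    return AlignedSet(records=tuple(rows))


def write_aligned_fasta(aln: AlignedSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for rid, seq in aln.records:
            fh.write(f">{rid}\n{seq}\n")


def read_bed(
    path: str | Path, genome: GenomeRecord | None = None
) -> list[GeneAnnotation]:
    """Read a 3-6 column BED file of gene annotations.

    Columns: chrom, start, end[, name, score, strand].  When ``genome`` is
    given, coordinates are validated against its length.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    genes: list[GeneAnnotation] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise SeqIOError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start_s, end_s = cols[0], cols[1], cols[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise SeqIOError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = cols[3] if len(cols) > 3 and cols[3] not in (".", "") else f"gene_{lineno}"
            strand = cols[5] if len(cols) > 5 else "+"
            ann = GeneAnnotation(
                gene_id=name, genome_id=chrom, start=start, end=end, strand=strand
            )
            if genome is not None:
                if ann.genome_id != genome.id:
                    raise SeqIOError(
                        f"{path}:{lineno}: chrom {chrom!r} does not match genome {genome.id!r}"
                    )
                if ann.end > len(genome):
                    raise SeqIOError(
                        f"{path}:{lineno}: end {end} beyond genome length {len(genome)}"
                    )
            genes.append(ann)
    if not genes:
        raise SeqIOError(f"no BED records in {path}")
    return genes


def write_bed(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for g in genes:
            fh.write(f"{g.genome_id}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def read_newick(path: str | Path):
    """Read a Newick tree; internal-node labels are parsed as bootstrap supports."""
    from skbio import TreeNode

    tree = TreeNode.read(str(Path(path)), format="newick")
    tree.assign_supports()
    return tree


def write_newick(tree, path: str | Path) -> None:
    """Write a tree as Newick, branch lengths to 6 decimals, supports as
    internal-node labels."""
    tree = tree.copy()
    for node in tree.traverse(include_self=True):
        if node.length is not None:
            node.length = round(float(node.length), 6)
        support = getattr(node, "support", None)
        if not node.is_tip() and support is not None:
            node.name = format(float(support), "g")
    tree.write(str(Path(path)), format="newick")


def extract_gene(genome: GenomeRecord, gene: GeneAnnotation) -> str:
    """Extract a gene's coding-strand sequence (revcomp for '-' strand)."""
    if gene.genome_id != genome.id:
        raise SeqIOError(
            f"gene {gene.gene_id!r} annotated on {gene.genome_id!r}, not {genome.id!r}"
        )
    if gene.end > len(genome):
        raise SeqIOError(f"gene {gene.gene_id!r} extends beyond genome end")
    seq = genome.sequence[gene.start : gene.end]
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return seq
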