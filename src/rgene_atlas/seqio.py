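"""Readers/writers for the formats the pipeline touches.

Every coordinate handled by the package is 1-based and inclusive, the GFF3
convention; conversion to Python slices happens only inside this module.
FASTA is read/written through Bio.SeqIO, GFF3 through gffutils.  Only the
GFF3 dialect produced by this package is supported: identity via the ``ID``
attribute, parent linkage via ``Parent``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class Chromosome:
    """A named DNA sequence over {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"chromosome {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """Return bases ``start..end`` (1-based, inclusive)."""
        if start < 1 or end > len(self.sequence) or start > end:
            raise ValueError(f"invalid slice {start}..{end} on {self.name}")
        return self.sequence[start - 1 : end]


@dataclass
class GeneModel:
    """A located gene: the unit of clustering, promoter extraction and
    expression mapping.

    ``start``/``end`` are 1-based inclusive genomic positions; ``exons`` are
    stored in ascending genomic order regardless of strand.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_sequence: str = ""
    protein_sequence: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: unknown strand {self.strand!r}")
        self.exons = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.gene_id}: overlapping exons")
        if self.protein_sequence and self.cds_sequence and len(self.cds_sequence) % 3:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, SEQUENCE), ...]`` preserving order.

    Sequences are uppercased.  Duplicate record ids are a hard error; an
    empty file yields an empty list with a warning.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        warnings.warn(f"empty FASTA file: {path}")
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    seqrecs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seqrecs)


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features into :class:`GeneModel` objects.

    Coordinates stay 1-based inclusive as in GFF3.  Features with end <
    start or an unknown strand are hard errors (raised by the GeneModel
    constructor).  Exons of minus-strand genes are still stored in
    ascending genomic order.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="error",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons = []
        for exon in db.children(gene, featuretype="exon", order_by="start"):
            exons.append((exon.start, exon.end))
        if gene.strand not in "+-":
            raise ValueError(f"{gene.id}: unknown strand {gene.strand!r}")
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                exons=exons,
            )
        )
    # gffutils orders within a call by start; restore file order across
    # chromosomes by seqid then start for determinism.
    models.sort(key=lambda g: (g.chromosome, g.start, g.gene_id))
    return models


def write_gff3(models: list[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon/CDS rows for each model (one mRNA per gene)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(models, key=lambda m: (m.chromosome, m.start, m.gene_id)):
            base = f"{g.chromosome}\trgene_atlas\t"
            tail = f"\t.\t{g.strand}\t"
            fh.write(f"{base}gene\t{g.start}\t{g.end}{tail}.\tID={g.gene_id}\n")
            mrna = f"{g.gene_id}.1"
            fh.write(f"{base}mRNA\t{g.start}\t{g.end}{tail}.\tID={mrna};Parent={g.gene_id}\n")
            exons = g.exons or [(g.start, g.end)]
            for i, (s, e) in enumerate(exons, 1):
                fh.write(f"{base}exon\t{s}\t{e}{tail}.\tID={mrna}.exon{i};Parent={mrna}\n")
                fh.write(f"{base}CDS\t{s}\t{e}{tail}0\tID={mrna}.cds{i};Parent={mrna}\n")


def attach_sequences(
    models: list[GeneModel],
    genome: dict[str, str] | None = None,
    proteins: dict[str, str] | None = None,
) -> list[GeneModel]:
    """Fill ``cds_sequence`` (spliced, strand-corrected) and/or
    ``protein_sequence`` in place and return the models."""
    for g in models:
        if genome is not None:
            chrom = genome[g.chromosome]
            exons = g.exons or [(g.start, g.end)]
            cds = "".join(chrom[s - 1 : e] for s, e in exons)
            if g.strand == "-":
                cds = reverse_complement(cds)
            g.cds_sequence = cds
        if proteins is not None and g.gene_id in proteins:
            g.protein_sequence = proteins[g.gene_id]
    return models


_COMPLEMENT = str.maketrans("ACGTNRYSWKM", "TGCANYRSWMK")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def write_newick(tree, path: str | Path) -> None:
    """Write a tree (see :mod:`rgene_atlas.phylogeny`) as Newick with branch
    lengths and integer bootstrap labels on internal nodes.

    Negative branch lengths are clamped to zero with a warning.
    """
    from . import phylogeny

    with open(path, "w") as fh:
        fh.write(phylogeny.to_newick(tree) + "\n")


def read_newick(path: str | Path):
    from . import phylogeny

    with open(path) as fh:
        return phylogeny.from_newick(fh.read())
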