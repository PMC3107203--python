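"""Genome/annotation I/O and strand-aware upstream-region extraction.

Internal coordinates are 0-based half-open throughout; file interfaces keep
each format's native convention (GFF3 and GenBank are 1-based inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    CharacterError,
    ContractError,
    FormatError,
    RecordError,
    UnknownGeneError,
)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A single contig/replicon: uppercase DNA over {A,C,G,T,N}."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise RecordError("genome record id must be nonempty")
        bad = set(self.seq) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise CharacterError(
                f"illegal character {self.seq[pos]!r} at offset {pos} in record {self.id!r}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class GeneAnnotation:
    """A gene/CDS feature in 0-based half-open internal coordinates."""

    contig_id: str
    start: int
    end: int
    strand: str
    gene_id: str
    product: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise RecordError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise RecordError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def translational_start(self) -> int:
        """0-based genomic coordinate of the first transcribed/translated base."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class UpstreamRegion:
    """Sequence immediately upstream of a gene, in the gene's reading orientation."""

    gene_id: str
    seq: str
    contig_id: str
    start: int
    end: int
    strand: str
    requested_len: int
    truncated_by_neighbor: bool = False

    def __post_init__(self) -> None:
        if len(self.seq) > self.requested_len:
            raise RecordError(f"{self.gene_id}: region longer than requested")


def read_genome(path: str | Path, circular: bool = False) -> list[GenomeRecord]:
    """Read a (multi-)FASTA of DNA into :class:`GenomeRecord` objects.

    Lowercase input is uppercased; characters outside {A,C,G,T,N} raise
    :class:`CharacterError` naming the record and offset.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise CharacterError(
                f"illegal character {seq[pos]!r} at offset {pos} in record {rec.id!r}"
            )
        records.append(GenomeRecord(id=rec.id, seq=seq, circular=circular))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def _sniff_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".gff", ".gff3"):
        return "gff3"
    if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
        return "genbank"
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            if line.startswith("##gff-version") or (
                not line.startswith("#") and len(line.split("\t")) == 9
            ):
                return "gff3"
            if line.startswith("LOCUS"):
                return "genbank"
            break
    raise FormatError(f"{path}: cannot determine annotation dialect")


def _gff3_attributes(raw: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in raw.strip().split(";"):
        if not item or "=" not in item:
            continue
        key, value = item.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def _read_gff3(path: Path, feature_types: frozenset[str]) -> list[GeneAnnotation]:
    annotations = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 tab-separated fields")
            contig, _source, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype not in feature_types:
                continue
            start_i, end_i = int(start), int(end)
            if start_i > end_i:
                raise RecordError(f"{path}:{lineno}: start {start_i} > end {end_i}")
            if strand not in ("+", "-"):
                raise RecordError(f"{path}:{lineno}: unstranded feature not supported")
            attr = _gff3_attributes(attrs)
            gene_id = attr.get("locus_tag") or attr.get("ID") or attr.get("Name")
            if gene_id is None:
                raise RecordError(f"{path}:{lineno}: feature has no locus_tag/ID/Name")
            annotations.append(
                GeneAnnotation(
                    contig_id=contig,
                    start=start_i - 1,  # GFF3 is 1-based inclusive
                    end=end_i,
                    strand=strand,
                    gene_id=gene_id,
                    product=attr.get("product"),
                )
            )
    return annotations


def _read_genbank(path: Path, feature_types: frozenset[str]) -> list[GeneAnnotation]:
    annotations = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type not in feature_types:
                continue
            quals = feat.qualifiers
            gene_id = (
                quals.get("locus_tag", [None])[0]
                or quals.get("gene", [None])[0]
                or quals.get("protein_id", [None])[0]
            )
            if gene_id is None:
                continue
            strand = "-" if feat.location.strand == -1 else "+"
            annotations.append(
                GeneAnnotation(
                    contig_id=rec.id,
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                    strand=strand,
                    gene_id=gene_id,
                    product=quals.get("product", [None])[0],
                )
            )
    return annotations


def read_annotations(
    path: str | Path,
    feature_types: Iterable[str] = ("gene", "CDS"),
) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 or GenBank into internal coordinates.

    Only the requested feature types are retained; when a gene and its CDS
    share a locus tag the first occurrence wins. Output is sorted by
    (contig_id, start).
    """
    path = Path(path)
    ftypes = frozenset(feature_types)
    dialect = _sniff_dialect(path)
    if dialect == "gff3":
        annotations = _read_gff3(path, ftypes)
    else:
        annotations = _read_genbank(path, ftypes)
    seen: dict[str, GeneAnnotation] = {}
    for ann in annotations:
        seen.setdefault(ann.gene_id, ann)
    return sorted(seen.values(), key=lambda a: (a.contig_id, a.start, a.end))


def extract_upstream(
    genome: GenomeRecord,
    annotations: Sequence[GeneAnnotation],
    gene_ids: Iterable[str],
    requested_len: int = 300,
    truncate_at_neighbor: bool = True,
) -> list[UpstreamRegion]:
    """Extract up to ``requested_len`` nt upstream of each requested gene.

    The region abuts the gene's translational start side and is returned in
    the gene's reading orientation (reverse-complemented for ``-`` strand
    genes). With ``truncate_at_neighbor`` the window is clipped at the
    nearest boundary of any other annotated gene, regardless of strand.
    Zero-length regions are emitted with an empty sequence and a warning.
    """
    if requested_len < 1:
        raise ContractError(f"requested_len must be >= 1, got {requested_len}")
    by_id = {a.gene_id: a for a in annotations}
    contig = [a for a in annotations if a.contig_id == genome.id]
    out = []
    for gene_id in gene_ids:
        if gene_id not in by_id:
            raise UnknownGeneError(gene_id)
        gene = by_id[gene_id]
        L = genome.length
        truncated = False
        if gene.strand == "+":
            lo, hi = max(0, gene.start - requested_len), gene.start
            if truncate_at_neighbor:
                for other in contig:
                    if other.gene_id == gene_id:
                        continue
                    if other.end > lo and other.start < hi:
                        clip = min(other.end, hi)
                        if clip > lo:
                            lo, truncated = clip, True
            seq = genome.seq[lo:hi]
        else:
            lo, hi = gene.end, min(L, gene.end + requested_len)
            if truncate_at_neighbor:
                for other in contig:
                    if other.gene_id == gene_id:
                        continue
                    if other.start < hi and other.end > lo:
                        clip = max(other.start, lo)
                        if clip < hi:
                            hi, truncated = clip, True
            seq = reverse_complement(genome.seq[lo:hi])
        if not seq:
            warnings.warn(
                f"upstream region of {gene_id} has zero length", stacklevel=2
            )
        out.append(
            UpstreamRegion(
                gene_id=gene_id,
                seq=seq,
                contig_id=genome.id,
                start=lo,
                end=hi,
                strand=gene.strand,
                requested_len=requested_len,
                truncated_by_neighbor=truncated,
            )
        )
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTA."""
    seqrecords = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as (id, uppercase sequence) pairs (any alphabet)."""
    out = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not out:
        raise FormatError(f"{path}: no FASTA records found")
    return out


def write_gff3(
    annotations: Sequence[GeneAnnotation],
    path: str | Path,
    source: str = "corescan",
    feature_type: str = "gene",
) -> None:
    """Write annotations as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in sorted(annotations, key=lambda x: (x.contig_id, x.start)):
            attrs = f"ID={a.gene_id};locus_tag={a.gene_id}"
            if a.product:
                attrs += f";product={a.product}"
            fh.write(
                "\t".join(
                    [
                        a.contig_id,
                        source,
                        feature_type,
                        str(a.start + 1),
                        str(a.end),
                        ".",
                        a.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
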