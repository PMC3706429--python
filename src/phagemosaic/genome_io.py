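"""Genome records, gene features, and the sequence primitives used everywhere else.

Coordinate model
----------------
All coordinates in this package are 1-based and inclusive, matching GenBank
convention: the interval (start, end) covers ``end - start + 1`` bases and
``(5, 5)`` is a single base.  Any half-open representation used internally by
a library is converted at the API boundary.

Sequences are DNA strings over {A, C, G, T, N}.  RNA input is normalised with
U -> T on read so splice-site rules stated on the message (a 3' U at the end
of exon 1) are tested as T at the DNA level.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: NCBI translation table 11 (bacteria/archaea/plant plastid) start codons.
START_CODONS = ("ATG", "GTG", "TTG")


class FormatError(ValueError):
    """Raised for malformed input files (bad FASTA characters, bad TSV rows)."""


class ValidationError(ValueError):
    """Raised when a record or feature violates the coordinate model."""


@dataclass
class GeneFeature:
    """A gene on a genome: 1-based inclusive coordinates, explicit strand.

    ``gene_number`` follows the convention of phage genome maps where genes
    are numbered left to right ("13", "33", ...); it is a label, not an index.
    """

    gene_number: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    product: str = ""
    translation: Optional[str] = None

    def __post_init__(self) -> None:
        self.gene_number = str(self.gene_number)
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"feature {self.gene_number}: bad interval {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"feature {self.gene_number}: strand {self.strand!r}")
        if self.kind not in ("CDS", "tRNA", "other"):
            raise ValidationError(f"feature {self.gene_number}: kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def shifted(self, offset: int) -> "GeneFeature":
        return GeneFeature(self.gene_number, self.start + offset, self.end + offset,
                           self.strand, self.kind, self.product, self.translation)


@dataclass
class GenomeRecord:
    """A named DNA sequence with an ordered list of gene features."""

    id: str
    seq: str
    features: list[GeneFeature] = field(default_factory=list)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValidationError(f"genome {self.id}: empty sequence")
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.end > len(self.seq):
                raise ValidationError(
                    f"genome {self.id}: feature {f.gene_number} end {f.end} "
                    f"beyond length {len(self.seq)}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    def feature_by_number(self, gene_number: str) -> GeneFeature:
        for f in self.features:
            if f.gene_number == str(gene_number):
                return f
        raise KeyError(f"genome {self.id}: no gene {gene_number!r}")

    def cds_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "CDS"]


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def _clean_seq(raw: str, label: str) -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - VALID_BASES
    if bad:
        raise FormatError(
            f"record {label!r}: illegal character(s) {sorted(bad)} outside A/C/G/T/N"
        )
    return seq


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-)FASTA into GenomeRecords, uppercased, U mapped to T."""
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GenomeRecord(rec.id, _clean_seq(str(rec.seq), rec.id),
                                    [], str(path)))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


_TSV_COLUMNS = ["gene_number", "start", "end", "strand", "kind", "product"]


def read_features(path: str | Path, dialect: str = "tsv",
                  genome_length: Optional[int] = None) -> list[GeneFeature]:
    """Read gene features from a TSV feature table or a GenBank flat file.

    The TSV dialect has a header line and columns
    gene_number, start, end, strand, kind, product[, translation].
    GenBank parsing consumes CDS and tRNA features with plain (non-join)
    locations and /product, /translation qualifiers.
    """
    if dialect == "tsv":
        feats = _read_features_tsv(path)
    elif dialect == "genbank":
        feats = _read_features_genbank(path)
    else:
        raise ValueError(f"unknown feature dialect {dialect!r}")
    if genome_length is not None:
        for f in feats:
            if f.end > genome_length:
                raise ValidationError(
                    f"feature {f.gene_number}: end {f.end} beyond genome "
                    f"length {genome_length}")
    return sorted(feats, key=lambda f: (f.start, f.end))


def _read_features_tsv(path: str | Path) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            return []
        if [h.strip() for h in header[:6]] != _TSV_COLUMNS:
            raise FormatError(f"{path}: expected header {_TSV_COLUMNS}, got {header}")
        for i, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 6:
                raise FormatError(f"{path}:{i}: expected >=6 columns, got {len(row)}")
            try:
                start, end = int(row[1]), int(row[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{i}: non-integer coordinate") from exc
            translation = row[6].strip() or None if len(row) > 6 else None
            try:
                feats.append(GeneFeature(row[0], start, end, row[3], row[4],
                                         row[5], translation))
            except ValidationError as exc:
                raise ValidationError(f"{path}:{i}: {exc}") from exc
    return feats


def _read_features_genbank(path: str | Path) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    n = 0
    for rec in SeqIO.parse(str(path), "genbank"):
        for sf in rec.features:
            if sf.type not in ("CDS", "tRNA"):
                continue
            if len(sf.location.parts) > 1:
                raise FormatError(
                    f"{path}: joined/compound location in feature at "
                    f"{sf.location} is not supported")
            n += 1
            number = sf.qualifiers.get("gene", sf.qualifiers.get("locus_tag", [str(n)]))[0]
            translation = sf.qualifiers.get("translation", [None])[0]
            feats.append(GeneFeature(
                number,
                int(sf.location.start) + 1,  # Biopython is 0-based half-open
                int(sf.location.end),
                "+" if sf.location.strand >= 0 else "-",
                sf.type if sf.type in ("CDS", "tRNA") else "other",
                sf.qualifiers.get("product", [""])[0],
                translation,
            ))
    return feats


def write_features_tsv(features: Iterable[GeneFeature], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS + ["translation"])
        for f in features:
            writer.writerow([f.gene_number, f.start, f.end, f.strand, f.kind,
                             f.product, f.translation or ""])


def interval_length(start: int, end: int) -> int:
    """Length in bp of the 1-based inclusive interval (start, end)."""
    if start < 1 or end < start:
        raise ValueError(f"invalid interval {start}..{end}")
    return end - start + 1


def extract_gene_dna(genome: GenomeRecord, feature: GeneFeature) -> str:
    """Gene sequence in reading orientation (reverse-complemented for '-')."""
    if feature.end > len(genome.seq) or feature.start < 1:
        raise ValidationError(
            f"feature {feature.gene_number} out of bounds for {genome.id}")
    sub = genome.seq[feature.start - 1:feature.end]
    return revcomp(sub) if feature.strand == "-" else sub


def translate_cds(dna: str, table: int = 11, initiator: bool = False) -> str:
    """Translate a CDS, stopping at the first stop codon.

    With ``initiator=True`` an alternative start codon (GTG/TTG) is rendered
    as M, as at annotated starts in high-GC actinobacterial genomes.  Codons
    containing N translate to X.
    """
    if len(dna) < 3:
        raise ValueError("CDS shorter than one codon")
    dna = dna.upper().replace("U", "T")
    aa = str(Seq(dna[: len(dna) - len(dna) % 3]).translate(table=table, to_stop=True))
    if initiator and aa and dna[:3] in START_CODONS:
        aa = "M" + aa[1:]
    return aa


def gc_content(genome: GenomeRecord | str) -> float:
    """GC fraction over unambiguous bases; N is excluded from the denominator."""
    seq = genome if isinstance(genome, str) else genome.seq
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return gc / denom
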