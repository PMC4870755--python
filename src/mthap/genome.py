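"""Domain model for a circular mitochondrial genome and the file formats around it.

Coordinates are 1-based inclusive throughout, matching GenBank-style numbering
of a reference accession. The genome is stored linearized at position 1 of the
accession; features that wrap the circular origin carry ``wraps=True`` and are
handled by coordinate unrolling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from Bio import SeqIO


class MthapError(Exception):
    """Base class for all package errors."""


class FormatError(MthapError):
    """A file did not conform to the expected format."""


COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: ETC complex membership of the mtDNA-encoded protein subunits.
COMPLEX_OF_GENE = {
    "NADH1": "I", "NADH2": "I", "NADH3": "I", "NADH4": "I",
    "NADH4L": "I", "NADH5": "I", "NADH6": "I",
    "CYTB": "III",
    "COI": "IV", "COII": "IV", "COIII": "IV",
    "ATPase6": "V", "ATPase8": "V",
}

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "control", "motif")


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# genetic code
# ---------------------------------------------------------------------------

_STANDARD = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
_BASES = "TCAG"


def _standard_table() -> dict[str, str]:
    table = {}
    i = 0
    for b1 in _BASES:
        for b2 in _BASES:
            for b3 in _BASES:
                table[b1 + b2 + b3] = _STANDARD[i]
                i += 1
    return table


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> one-letter amino acid mapping ('*' marks stop)."""

    name: str
    table: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.table) != 64:
            raise ValueError(f"genetic code must map 64 codons, got {len(self.table)}")

    def translate(self, codon: str) -> str:
        codon = codon.upper()
        if codon not in self.table:
            raise MthapError(f"cannot translate ambiguous codon {codon!r}")
        return self.table[codon]


def _vertebrate_mito() -> GeneticCode:
    table = _standard_table()
    # differences from the standard code in vertebrate mitochondria
    table["AGA"] = "*"
    table["AGG"] = "*"
    table["ATA"] = "M"
    table["TGA"] = "W"
    return GeneticCode("vertebrate mitochondrial", table)


VERTEBRATE_MITO = _vertebrate_mito()

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Ter",
}


# ---------------------------------------------------------------------------
# features and genome
# ---------------------------------------------------------------------------

@dataclass
class Feature:
    """One annotated region: a CDS, tRNA, rRNA, the control region, or a motif."""

    name: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    complex: Optional[str] = None  # ETC complex for CDS: I, III, IV or V
    codon_start_offset: int = 0
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.wraps and self.start > self.end:
            raise ValueError(
                f"feature {self.name}: start {self.start} > end {self.end} "
                "without wraps=True"
            )
        if not 0 <= self.codon_start_offset <= 2:
            raise ValueError("codon_start_offset must be 0..2")

    def length(self, genome_length: Optional[int] = None) -> int:
        if self.wraps:
            if genome_length is None:
                raise ValueError("wrapping feature needs the genome length")
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1

    def contains(self, position: int, genome_length: Optional[int] = None) -> bool:
        if self.wraps:
            return position >= self.start or position <= self.end
        return self.start <= position <= self.end


@dataclass
class AnnotatedGenome:
    name: str
    sequence: str
    circular: bool = True
    features: list[Feature] = field(default_factory=list)
    accession: Optional[str] = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("genome sequence must be non-empty")
        bad = set(self.sequence) - set("ACGT")
        if bad:
            raise ValueError(f"genome contains non-ACGT characters: {sorted(bad)}")
        L = len(self.sequence)
        for f in self.features:
            if not (1 <= f.start <= L and 1 <= f.end <= L):
                raise ValueError(f"feature {f.name} outside [1, {L}]")
            if f.kind == "CDS" and (f.length(L) - f.codon_start_offset) % 3 != 0:
                raise ValueError(
                    f"CDS {f.name}: length {f.length(L)} incompatible with codon "
                    f"frame after offset {f.codon_start_offset}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise MthapError(f"position {position} outside [1, {self.length}]")
        return self.sequence[position - 1]


@dataclass
class ReadRecord:
    """A sequencing read with Phred-scaled base qualities."""

    id: str
    bases: str
    quals: list[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id}: {len(self.bases)} bases but {len(self.quals)} quals"
            )
        bad = set(self.bases) - set("ACGTN")
        if bad:
            raise ValueError(f"read {self.id}: invalid bases {sorted(bad)}")

    @property
    def mean_phred(self) -> float:
        return sum(self.quals) / len(self.quals) if self.quals else 0.0


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (name, uppercased sequence) pairs, in file order."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(">"):
            raise FormatError(f"{path}: line 1: expected FASTA header starting with '>'")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream 4-line Phred+33 FASTQ records as ReadRecords."""
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            yield ReadRecord(rec.id, str(rec.seq).upper(), list(quals))
    except ValueError as exc:  # Biopython reports truncation/length mismatch
        raise FormatError(f"{path}: {exc}") from exc


def write_fastq(path, reads: Iterable[ReadRecord]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


ANNOTATION_COLUMNS = ("name", "kind", "start", "end", "strand", "complex",
                      "codon_start_offset")


def read_annotation(path) -> list[Feature]:
    """Read the minimal GFF-like TSV annotation dialect used by this package.

    Columns: name, kind, start, end, strand, complex, codon_start_offset.
    ``complex`` is empty for non-CDS features; a header line is required.
    """
    features = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ANNOTATION_COLUMNS:
            raise FormatError(
                f"{path}: line 1: expected header {list(ANNOTATION_COLUMNS)}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(ANNOTATION_COLUMNS):
                raise FormatError(f"{path}: line {lineno}: expected "
                                  f"{len(ANNOTATION_COLUMNS)} columns")
            name, kind, start, end, strand, cplx, offset = parts
            try:
                features.append(Feature(
                    name=name, kind=kind, start=int(start), end=int(end),
                    strand=strand, complex=cplx or None,
                    codon_start_offset=int(offset or 0),
                ))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return features


def write_annotation(path, features: Iterable[Feature]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for f in features:
            fh.write("\t".join([
                f.name, f.kind, str(f.start), str(f.end), f.strand,
                f.complex or "", str(f.codon_start_offset),
            ]) + "\n")


def write_newick(tree) -> str:
    """Serialize a tree (root node with .children/.name/.length/.support).

    Integer support values are rendered as internal node labels, the common
    convention for bootstrap percentages.
    """

    def render(node) -> str:
        if not node.children:
            if not node.name:
                raise MthapError("tree has an unlabeled leaf")
            return f"{node.name}:{_fmt_len(node.length)}"
        inner = ",".join(render(c) for c in node.children)
        label = ""
        if getattr(node, "support", None) is not None:
            label = str(int(round(node.support)))
        if node is not tree:
            return f"({inner}){label}:{_fmt_len(node.length)}"
        return f"({inner}){label}"

    def _fmt_len(length) -> str:
        if length is None:
            length = 0.0
        if length < 0:
            raise MthapError(f"negative branch length {length}")
        return f"{length:.6g}"

    return render(tree) + ";"


# ---------------------------------------------------------------------------
# position queries and codon-change translation
# ---------------------------------------------------------------------------

def feature_at(genome: AnnotatedGenome, position: int) -> list[Feature]:
    """All features overlapping a 1-based position (empty list = intergenic).

    Overlapping features are all returned: a position shared by two genes is
    counted once per gene in downstream susceptibility tallies.
    """
    if not 1 <= position <= genome.length:
        raise MthapError(f"position {position} outside [1, {genome.length}]")
    return [f for f in genome.features if f.contains(position, genome.length)]


@dataclass(frozen=True)
class CodonChange:
    aa_position: int
    ref_aa: str
    alt_aa: str
    synonymous: bool
    hgvs: str              # three-letter style, e.g. "p.Ile58Met"
    reversed_vs_report: bool = False  # see translate_codon_change notes

    def __iter__(self):
        return iter((self.aa_position, self.ref_aa, self.alt_aa, self.synonymous))


def _cds_offset(feature: Feature, position: int, genome_length: int) -> int:
    """0-based offset of a genome position within the coding sequence."""
    if feature.wraps:
        span = (feature.start <= position <= genome_length)
        linear = (position - feature.start) if span else (
            genome_length - feature.start + 1 + position - 1)
    else:
        linear = position - feature.start
    if feature.strand == "-":
        linear = feature.length(genome_length) - 1 - linear
    return linear - feature.codon_start_offset


def translate_codon_change(
    genome: AnnotatedGenome,
    feature: Feature,
    position: int,
    ref_base: str,
    alt_base: str,
    code: GeneticCode = VERTEBRATE_MITO,
) -> CodonChange:
    """Amino-acid consequence of a substitution inside a CDS.

    ``ref_base``/``alt_base`` are given on the genome (+) strand; minus-strand
    CDSs are handled by complementing into coding orientation. Uses the
    vertebrate mitochondrial code by default (ATA=Met, TGA=Trp, AGA/AGG=stop).
    """
    if feature.kind != "CDS":
        raise MthapError(f"feature {feature.name} is not a CDS")
    if not feature.contains(position, genome.length):
        raise MthapError(f"position {position} not inside CDS {feature.name}")
    if genome.base(position) != ref_base.upper():
        raise MthapError(
            f"reference mismatch at {position}: genome has "
            f"{genome.base(position)}, caller said {ref_base}"
        )
    offset = _cds_offset(feature, position, genome.length)
    if offset < 0:
        raise MthapError(f"position {position} precedes the codon frame of "
                         f"{feature.name}")
    aa_position = offset // 3 + 1
    in_codon = offset % 3

    # genome positions of the codon, in coding order
    if feature.strand == "+":
        first = position - in_codon
        codon_positions = [first, first + 1, first + 2]
    else:
        first = position + in_codon
        codon_positions = [first, first - 1, first - 2]

    def coding_base(p: int) -> str:
        b = genome.base((p - 1) % genome.length + 1)
        return COMPLEMENT[b] if feature.strand == "-" else b

    ref_codon = "".join(coding_base(p) for p in codon_positions)
    alt = alt_base.upper()
    alt_in_coding = COMPLEMENT[alt] if feature.strand == "-" else alt
    alt_codon = (ref_codon[:in_codon] + alt_in_coding + ref_codon[in_codon + 1:])

    ref_aa = code.translate(ref_codon)
    alt_aa = code.translate(alt_codon)
    hgvs = f"p.{AA3[ref_aa]}{aa_position}{AA3[alt_aa]}"
    return CodonChange(
        aa_position=aa_position,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        synonymous=ref_aa == alt_aa,
        hgvs=hgvs,
    )
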