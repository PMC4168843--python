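"""Sequence, annotation and tree I/O plus taxon-label parsing.

All coordinates are 0-based half-open internally; conversion to and from
1-based inclusive conventions (GFF3) happens only at the file boundary.
Sequences are stored uppercased with U mapped to T so RNA-coded records
compare cleanly against DNA. Inputs are assumed co-oriented (alignment
implies orientation); no reverse-complementing is performed.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import AlignIO, SeqIO

from .errors import (
    AlignmentShapeError,
    BoundsError,
    FormatError,
    LabelParseError,
    SerializationError,
)

# IUPAC nucleotide codes plus gap and unknown characters.
ALPHABET = set("ACGTRYSWKMBDHVN-?")

_NORMALIZE = str.maketrans({"u": "T", "U": "T"})


def normalize_sequence(seq: str) -> str:
    """Uppercase, map U to T, and validate against the nucleotide alphabet."""
    s = seq.translate(_NORMALIZE).upper()
    bad = set(s) - ALPHABET
    if bad:
        raise FormatError(f"sequence contains invalid characters: {sorted(bad)!r}")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """A labeled nucleotide sequence (possibly gapped)."""

    label: str
    sequence: str

    def __post_init__(self):
        if not self.label:
            raise FormatError("sequence record has an empty label")
        if not self.sequence:
            raise FormatError(f"record {self.label!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceAlignment:
    """An ordered set of equal-length gapped sequences with unique labels."""

    records: list[SequenceRecord]

    def __post_init__(self):
        if len(self.records) < 2:
            raise AlignmentShapeError("an alignment needs at least 2 records")
        length = len(self.records[0])
        for rec in self.records:
            if len(rec) != length:
                raise AlignmentShapeError(
                    f"record {rec.label!r} has length {len(rec)}, expected {length}"
                )
        labels = [r.label for r in self.records]
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise FormatError(f"duplicate labels in alignment: {dup}")

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i) -> SequenceRecord:
        return self.records[i]


@dataclass(frozen=True)
class TaxonName:
    """Genus / epithet / qualifier parsed from a sequence label.

    ``qualifier`` is one of ``none``, ``sp`` (identified only to genus),
    ``cf`` or ``aff`` (uncertain species assignment). ``cf.`` and ``aff.``
    receive identical downstream treatment.
    """

    genus: str
    epithet: Optional[str]
    qualifier: str  # none | sp | cf | aff
    raw_label: str

    def __post_init__(self):
        if not self.genus:
            raise LabelParseError(f"no genus in label {self.raw_label!r}")
        if self.qualifier not in ("none", "sp", "cf", "aff"):
            raise LabelParseError(f"bad qualifier {self.qualifier!r}")


@dataclass(frozen=True)
class RegionAnnotation:
    """A named interval on the alignment/genome, 0-based half-open."""

    name: str
    start: int
    end: int
    category: str = "other"  # coding | ribosomal | other

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise BoundsError(
                f"region {self.name!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.category not in ("coding", "ribosomal", "other"):
            raise BoundsError(f"region {self.name!r}: bad category {self.category!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# alignment readers / writers
# ---------------------------------------------------------------------------

def _records_to_alignment(pairs: Iterable[tuple[str, str]]) -> SequenceAlignment:
    records = [SequenceRecord(label, normalize_sequence(seq)) for label, seq in pairs]
    if not records:
        raise FormatError("no sequences found in file")
    if len(records) == 1:
        raise AlignmentShapeError("an alignment needs at least 2 records")
    return SequenceAlignment(records)


def read_fasta(path) -> SequenceAlignment:
    """Read a FASTA file as an alignment (equal lengths enforced)."""
    path = Path(path)
    parsed = list(SeqIO.parse(str(path), "fasta"))
    return _records_to_alignment((r.description or r.id, str(r.seq)) for r in parsed)


def read_nexus_alignment(path) -> SequenceAlignment:
    """Read a NEXUS DATA/CHARACTERS block (sequential or interleaved)."""
    path = Path(path)
    try:
        aln = AlignIO.read(str(path), "nexus")
    except Exception as exc:  # Bio raises assorted exception types here
        raise FormatError(f"cannot parse NEXUS alignment from {path}: {exc}") from exc
    return _records_to_alignment((r.id, str(r.seq)) for r in aln)


def read_alignment(path, fmt: Optional[str] = None) -> SequenceAlignment:
    """Read an alignment, inferring FASTA vs NEXUS from the extension."""
    path = Path(path)
    if fmt is None:
        fmt = "nexus" if path.suffix.lower() in (".nex", ".nexus", ".nxs") else "fasta"
    if fmt == "nexus":
        return read_nexus_alignment(path)
    if fmt == "fasta":
        return read_fasta(path)
    raise FormatError(f"unknown alignment format {fmt!r}")


def write_fasta(alignment: SequenceAlignment, path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in alignment:
            fh.write(f">{rec.label}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_nexus(alignment: SequenceAlignment, path) -> None:
    """Write a sequential NEXUS DATA block (labels quoted when needed)."""
    path = Path(path)

    def q(label: str) -> str:
        return f"'{label}'" if re.search(r"[\s()\[\]{}/\\,;:=*'\"`+<>-]", label) else label

    with path.open("w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(alignment)} NCHAR={alignment.length};\n")
        fh.write('  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n')
        for rec in alignment:
            fh.write(f"    {q(rec.label)}  {rec.sequence}\n")
        fh.write("  ;\nEND;\n")


# ---------------------------------------------------------------------------
# taxon label parsing
# ---------------------------------------------------------------------------

_QUALIFIERS = {"sp": "sp", "sp.": "sp", "cf": "cf", "cf.": "cf", "aff": "aff", "aff.": "aff"}


def parse_taxon_label(label: str) -> TaxonName:
    """Parse ``Genus[_qualifier]_epithet[_suffixes]`` style labels.

    Underscores and spaces are both accepted as separators. The genus is the
    first alphabetic token; ``sp``/``sp.`` in epithet position means the
    specimen is identified only to genus; ``cf.``/``aff.`` preceding the
    epithet marks an uncertain identification. Trailing tokens (accession
    numbers etc.) are retained only in ``raw_label``.
    """
    if not label or not label.strip():
        raise LabelParseError("empty label")
    tokens = [t for t in re.split(r"[\s_]+", label.strip()) if t]

    genus = None
    idx = 0
    for i, tok in enumerate(tokens):
        if tok.rstrip(".").isalpha():
            genus, idx = tok, i
            break
    if genus is None:
        raise LabelParseError(f"label {label!r} contains no alphabetic token")
    genus = genus.rstrip(".")

    epithet: Optional[str] = None
    qualifier = "none"
    rest = tokens[idx + 1 :]
    if rest:
        head = rest[0].lower()
        if head in _QUALIFIERS:
            qualifier = _QUALIFIERS[head]
            if qualifier in ("cf", "aff") and len(rest) > 1 and rest[1].rstrip(".").isalpha():
                epithet = rest[1].rstrip(".")
        elif rest[0].rstrip(".").isalpha():
            epithet = rest[0].rstrip(".")
    return TaxonName(genus=genus, epithet=epithet, qualifier=qualifier, raw_label=label)


# ---------------------------------------------------------------------------
# region annotations (BED / GFF3)
# ---------------------------------------------------------------------------

_GFF_CATEGORY = {
    "cds": "coding",
    "gene": "coding",
    "mrna": "coding",
    "rrna": "ribosomal",
}

_CATEGORIES = ("coding", "ribosomal", "other")


def read_regions(path, fmt: Optional[str] = None, seq_length: Optional[int] = None) -> list[RegionAnnotation]:
    """Read region annotations from BED (0-based half-open) or GFF3
    (1-based inclusive, converted to half-open).

    BED: columns chrom, start, end, name[, category]. A missing category
    column defaults to ``coding`` (the file is expected to mark the regions
    of interest). GFF3: category is derived from the feature type
    (CDS/gene/mRNA -> coding, rRNA -> ribosomal, otherwise other) and the
    name from ``Name=`` or ``ID=`` attributes.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "gff" if suffix in (".gff", ".gff3") else "bed"
    if fmt not in ("bed", "gff"):
        raise FormatError(f"unknown region format {fmt!r}")

    regions: list[RegionAnnotation] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if fmt == "bed":
                if len(fields) < 4:
                    raise FormatError(f"{path}:{lineno}: BED needs >= 4 columns")
                start, end, name = int(fields[1]), int(fields[2]), fields[3]
                category = "coding"
                if len(fields) >= 5 and fields[4].lower() in _CATEGORIES:
                    category = fields[4].lower()
            else:
                if len(fields) < 9:
                    raise FormatError(f"{path}:{lineno}: GFF3 needs 9 columns")
                ftype = fields[2].lower()
                start, end = int(fields[3]) - 1, int(fields[4])
                category = _GFF_CATEGORY.get(ftype, "other")
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                name = attrs.get("Name") or attrs.get("ID") or f"{fields[2]}_{lineno}"
            if start >= end:
                raise BoundsError(f"{path}:{lineno}: empty or inverted interval [{start}, {end})")
            if seq_length is not None and end > seq_length:
                raise BoundsError(
                    f"{path}:{lineno}: region {name!r} end {end} exceeds sequence length {seq_length}"
                )
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate region name {name!r}")
            seen.add(name)
            regions.append(RegionAnnotation(name=name, start=start, end=end, category=category))
    return regions


def write_regions_bed(regions: Sequence[RegionAnnotation], path, chrom: str = "chrM") -> None:
    with Path(path).open("w") as fh:
        for r in regions:
            fh.write(f"{chrom}\t{r.start}\t{r.end}\t{r.name}\t{r.category}\n")


# ---------------------------------------------------------------------------
# trees (Newick) and tabular output
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """A node of a phylogenetic tree. The tree is held rooted for
    serialization; an unrooted binary tree has a trifurcating root."""

    label: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


_NEWICK_UNQUOTED = re.compile(r"^[A-Za-z0-9_.|\-]+$")


def _newick_label(label: str) -> str:
    if _NEWICK_UNQUOTED.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def newick_string(tree: TreeNode) -> str:
    """Serialize a tree to Newick with branch lengths at full precision."""
    tips = [leaf.label for leaf in tree.leaves()]
    if any(t is None for t in tips):
        raise SerializationError("tree has unlabeled tips")
    if len(set(tips)) != len(tips):
        dup = sorted({t for t in tips if tips.count(t) > 1})
        raise SerializationError(f"duplicate tip labels: {dup}")

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return _newick_label(node.label)
        inner = ",".join(
            f"{render(child)}:{length:.10g}" for child, length in node.children
        )
        lab = _newick_label(node.label) if node.label else ""
        return f"({inner}){lab}"

    return render(tree) + ";"


def write_newick(tree: TreeNode, path) -> None:
    Path(path).write_text(newick_string(tree) + "\n")


def write_tsv(rows: Iterable[Sequence], path, header: Sequence[str]) -> None:
    """Write rows as TSV with a header line."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)
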