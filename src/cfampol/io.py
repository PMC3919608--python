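"""Sequence and metadata I/O plus basic sequence surgery.

Proteomes arrive as amino-acid FASTA, one file (or record block) per
genome; genome-level metadata (size, GC content, oxygen class, taxonomy)
arrives as a TSV keyed by genome id.  Intein excision is supported as an
explicit coordinate-driven operation: coordinates are always an input,
never inferred from sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_LETTERS = frozenset(AMINO_ACIDS + "X")

REPLICON_TYPES = ("chromosome", "plasmid", "unknown")
OXYGEN_CLASSES = ("aerobe", "facultative", "microaerophile", "anaerobe", "unknown")

#: Tolerant normalisation of free-text oxygen annotations (IMG-style).
_OXYGEN_ALIASES = {
    "aerobe": "aerobe",
    "aerobic": "aerobe",
    "obligate aerobe": "aerobe",
    "facultative": "facultative",
    "facultative aerobe": "facultative",
    "facultative anaerobe": "facultative",
    "microaerophile": "microaerophile",
    "microaerophilic": "microaerophile",
    "anaerobe": "anaerobe",
    "anaerobic": "anaerobe",
    "obligate anaerobe": "anaerobe",
}

GENOME_TABLE_COLUMNS = (
    "genome_id",
    "size_bp",
    "gc_percent",
    "oxygen_class",
    "phylum",
    "class_name",
)


class FastaParseError(ValueError):
    """Raised when a FASTA file violates format or alphabet constraints."""


class MetadataError(ValueError):
    """Raised when the genome metadata table is malformed."""


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence tied to its source genome."""

    protein_id: str
    genome_id: str
    sequence: str
    replicon: str = "unknown"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - ALLOWED_LETTERS
        if bad:
            raise ValueError(
                f"{self.protein_id}: illegal sequence character(s) "
                f"{sorted(bad)!r}; allowed are the 20 amino acids plus X"
            )
        if self.replicon not in REPLICON_TYPES:
            raise ValueError(f"{self.protein_id}: unknown replicon {self.replicon!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomeRecord:
    """Genome-level metadata used for trait correlation analyses."""

    genome_id: str
    size_bp: int
    gc_percent: float
    oxygen_class: str = "unknown"
    phylum: str = ""
    class_name: str = ""

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise ValueError(f"{self.genome_id}: size_bp must be positive")
        if not 0.0 <= self.gc_percent <= 100.0:
            raise ValueError(
                f"{self.genome_id}: gc_percent {self.gc_percent} outside [0, 100]"
            )
        if self.oxygen_class not in OXYGEN_CLASSES:
            raise ValueError(
                f"{self.genome_id}: unknown oxygen class {self.oxygen_class!r}"
            )


def normalize_oxygen(value: str) -> str:
    """Map a free-text oxygen annotation to one of the canonical classes."""
    return _OXYGEN_ALIASES.get(str(value).strip().lower(), "unknown")


def _genome_from_description(description: str, key: str) -> str | None:
    for token in description.split():
        if token.startswith(key + "="):
            return token[len(key) + 1 :]
    return None


def read_fasta(
    path: str | Path,
    genome_key: str = "genome",
    genome_id: str | None = None,
) -> list[ProteinRecord]:
    """Read an amino-acid FASTA file into :class:`ProteinRecord` objects.

    The header token before the first whitespace becomes ``protein_id``.
    The genome id is taken from a ``genome=<id>`` key-value in the
    description; ``genome_id`` supplies a per-file fallback for headers
    without one.  Sequences are upper-cased; any character outside the 20
    amino acids plus ``X`` is a parse error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as handle:
        first = handle.readline()
        while first and not first.strip():
            first = handle.readline()
        if first and not first.startswith(">"):
            raise FastaParseError(f"{path}: line 1 is not a FASTA header: {first!r}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq).upper()
        if not seq:
            raise FastaParseError(f"{path}: entry {entry.id!r} has an empty sequence")
        bad = set(seq) - ALLOWED_LETTERS
        if bad:
            line = _find_offending_line(path, bad)
            raise FastaParseError(
                f"{path}: entry {entry.id!r} contains illegal character(s) "
                f"{sorted(bad)!r} (first offending line {line})"
            )
        if entry.id in seen:
            raise FastaParseError(f"{path}: duplicate protein id {entry.id!r}")
        seen.add(entry.id)
        gid = _genome_from_description(entry.description, genome_key) or genome_id
        records.append(
            ProteinRecord(
                protein_id=entry.id,
                genome_id=gid or "unknown",
                sequence=seq,
                description=entry.description,
            )
        )
    return records


def _find_offending_line(path: Path, bad: set[str]) -> int:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith(">"):
                continue
            if bad & set(line.strip().upper()):
                return lineno
    return 0


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA, embedding the genome id as ``genome=<id>``."""
    out = []
    for rec in records:
        desc = rec.description
        if f"genome={rec.genome_id}" not in desc:
            desc = (desc + f" genome={rec.genome_id}").strip()
        # SeqIO prepends the id to the description on write
        desc_tail = desc[len(rec.protein_id) :].strip() if desc.startswith(rec.protein_id) else desc
        out.append(SeqRecord(Seq(rec.sequence), id=rec.protein_id, description=desc_tail))
    SeqIO.write(out, str(path), "fasta")


def read_genome_table(path: str | Path) -> dict[str, GenomeRecord]:
    """Read the genome metadata TSV into a ``genome_id -> GenomeRecord`` map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GENOME_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise MetadataError(f"{path}: missing required column(s): {', '.join(missing)}")
    genomes: dict[str, GenomeRecord] = {}
    for row in df.itertuples(index=False):
        rec = GenomeRecord(
            genome_id=row.genome_id,
            size_bp=int(row.size_bp),
            gc_percent=float(row.gc_percent),
            oxygen_class=normalize_oxygen(row.oxygen_class),
            phylum=row.phylum if isinstance(row.phylum, str) else "",
            class_name=row.class_name if isinstance(row.class_name, str) else "",
        )
        genomes[rec.genome_id] = rec
    return genomes


def write_genome_table(genomes: Mapping[str, GenomeRecord], path: str | Path) -> None:
    rows = [
        {
            "genome_id": g.genome_id,
            "size_bp": g.size_bp,
            "gc_percent": g.gc_percent,
            "oxygen_class": g.oxygen_class,
            "phylum": g.phylum,
            "class_name": g.class_name,
        }
        for g in genomes.values()
    ]
    pd.DataFrame(rows, columns=list(GENOME_TABLE_COLUMNS)).to_csv(path, sep="\t", index=False)


def excise_segments(
    rec: ProteinRecord, segments: Sequence[tuple[int, int]]
) -> ProteinRecord:
    """Remove 0-based half-open intervals (e.g. intein spans) from a sequence.

    Intervals must lie within the sequence and be mutually non-overlapping;
    the retained spans are concatenated in their original order.
    """
    n = len(rec.sequence)
    segs = sorted(tuple(s) for s in segments)
    prev_end = 0
    for start, end in segs:
        if start < 0 or end > n or start >= end:
            raise ValueError(
                f"{rec.protein_id}: interval ({start}, {end}) out of range for length {n}"
            )
        if start < prev_end:
            raise ValueError(f"{rec.protein_id}: overlapping intervals")
        prev_end = end
    if not segs:
        return rec
    kept: list[str] = []
    cursor = 0
    for start, end in segs:
        kept.append(rec.sequence[cursor:start])
        cursor = end
    kept.append(rec.sequence[cursor:])
    return replace(rec, sequence="".join(kept))
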