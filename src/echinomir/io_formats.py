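"""On-disk formats for the small-RNA pipeline.

FASTQ libraries (4-line records, Phred+33 or Phred+64), FASTA reference
sets, the collapsed-tag FASTA dialect (``>id_xCOUNT``) consumed by
hairpin-discovery tools, and tab-separated reports.

The internal alphabet is DNA: ``U`` is normalised to ``T`` on ingest so
that miRBase-style RNA references compare directly against genomic
sequence and sequencer output.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "Read",
    "Tag",
    "ReferenceSet",
    "FormatError",
    "FastqParseError",
    "QualityEncodingError",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "write_tag_fasta",
    "read_tag_fasta",
    "reverse_complement",
]

MAX_PHRED = 62

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Malformed on-disk input."""


class FastqParseError(FormatError):
    """Structurally invalid FASTQ record."""


class QualityEncodingError(FormatError):
    """Decoded Phred quality outside the legal range for the chosen offset."""


@dataclass(frozen=True)
class Read:
    """One sequenced record: identifier, bases, per-base Phred qualities."""

    read_id: str
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )
        if any(q < 0 or q > MAX_PHRED for q in self.qual):
            raise ValueError(
                f"read {self.read_id!r}: Phred quality outside [0, {MAX_PHRED}]"
            )
        object.__setattr__(self, "qual", tuple(self.qual))

    def __len__(self) -> int:
        return len(self.seq)

    def prefix(self, n: int) -> "Read":
        """The first ``n`` bases as a new Read (n >= 1)."""
        return Read(self.read_id, self.seq[:n], self.qual[:n])

    def suffix_from(self, n: int) -> "Read":
        """Drop the first ``n`` bases."""
        return Read(self.read_id, self.seq[n:], self.qual[n:])


@dataclass
class Tag:
    """A collapsed read group: the pipeline's expression unit.

    ``count`` is the number of independent reads the tag absorbed;
    ``members`` maps each distinct member sequence to its read count.
    """

    tag_id: str
    seq: str
    count: int
    members: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            self.members = {self.seq: self.count}
        if self.count < 1:
            raise ValueError(f"tag {self.tag_id!r}: count must be >= 1")
        if self.seq not in self.members:
            raise ValueError(f"tag {self.tag_id!r}: representative not a member")
        if sum(self.members.values()) != self.count:
            raise ValueError(
                f"tag {self.tag_id!r}: count {self.count} != sum of member counts"
            )


REFERENCE_CLASSES = (
    "tRNA",
    "rRNA",
    "snRNA_snoRNA",
    "miRNA_mature",
    "miRNA_hairpin",
    "mRNA",
    "genome",
)


@dataclass
class ReferenceSet:
    """A labelled FASTA reference collection (upper-case DNA, unique ids)."""

    class_label: str
    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        norm: list[tuple[str, str]] = []
        for rid, seq in self.records:
            if rid in seen:
                raise FormatError(
                    f"reference set {self.class_label!r}: duplicate id {rid!r}"
                )
            seen.add(rid)
            norm.append((rid, seq.upper().replace("U", "T")))
        self.records = norm

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.records)

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def get(self, rid: str) -> str:
        for r, s in self.records:
            if r == rid:
                return s
        raise KeyError(rid)

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.records)


def read_fastq(path: str | Path, quality_offset: int = 33) -> Iterator[Read]:
    """Stream 4-line FASTQ records as :class:`Read` objects.

    ``quality_offset`` selects Phred+33 (Sanger/modern Illumina) or
    Phred+64 (Illumina GA era). A decoded quality outside [0, 62] raises
    :class:`QualityEncodingError` suggesting the other offset.
    """
    if quality_offset not in (33, 64):
        raise ValueError("quality_offset must be 33 or 64")
    other = 97 - quality_offset
    n_records = 0
    with open(path) as handle:
        iterator = FastqGeneralIterator(handle)
        while True:
            try:
                title, seq, qual_str = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:  # malformed framing / length mismatch
                raise FastqParseError(
                    f"{path}: malformed FASTQ near line {4 * n_records + 1}: {exc}"
                ) from exc
            n_records += 1
            qual = tuple(ord(c) - quality_offset for c in qual_str)
            if any(q < 0 or q > MAX_PHRED for q in qual):
                raise QualityEncodingError(
                    f"{path}: record {title.split()[0]!r} (near line "
                    f"{4 * (n_records - 1) + 1}) decodes to a Phred quality "
                    f"outside [0, {MAX_PHRED}] with offset {quality_offset}; "
                    f"the file is probably Phred+{other}"
                )
            yield Read(title.split()[0], seq.upper().replace("U", "T"), qual)


def write_fastq(reads: Iterable[Read], path: str | Path, quality_offset: int = 33) -> None:
    """Serialize reads as 4-line FASTQ with the given quality offset."""
    with open(path, "w") as out:
        for read in reads:
            qual = "".join(chr(q + quality_offset) for q in read.qual)
            out.write(f"@{read.read_id}\n{read.seq}\n+\n{qual}\n")


def read_fasta(path: str | Path, class_label: str) -> ReferenceSet:
    """Load a FASTA file as a :class:`ReferenceSet`.

    Multi-line sequences are joined, ids are the first whitespace token,
    U is normalised to T. Empty files and duplicate ids are errors.
    """
    records: list[tuple[str, str]] = []
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            records.append((title.split()[0], seq))
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    return ReferenceSet(class_label=class_label, records=records)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as out:
        for rid, seq in records:
            out.write(f">{rid}\n{seq}\n")


_TAG_HEADER = re.compile(r"^(?P<tid>.+)_x(?P<count>\d+)$")


def write_tag_fasta(tags: list[Tag], path: str | Path) -> None:
    """Write collapsed tags as FASTA with headers ``>{tag_id}_x{count}``."""
    if not tags:
        raise ValueError("no tags to write")
    seen: set[str] = set()
    for tag in tags:
        if tag.tag_id in seen:
            raise FormatError(f"duplicate tag id {tag.tag_id!r}")
        seen.add(tag.tag_id)
    write_fasta(((f"{t.tag_id}_x{t.count}", t.seq) for t in tags), path)


def read_tag_fasta(path: str | Path) -> list[Tag]:
    """Read the collapsed-tag dialect back into :class:`Tag` objects.

    Member multisets are not stored on disk; each tag round-trips as a
    single-member tag with the representative sequence and total count.
    """
    tags: list[Tag] = []
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            name = title.split()[0]
            m = _TAG_HEADER.match(name)
            if m is None:
                raise FormatError(f"{path}: header {name!r} is not 'id_xCOUNT'")
            seq = seq.upper().replace("U", "T")
            tags.append(Tag(m["tid"], seq, int(m["count"])))
    if not tags:
        raise FormatError(f"{path}: empty tag FASTA")
    return tags
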