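"""File I/O for the pipeline: FASTA, FASTQ (Phred+33), SAM, and report emission.

Basecalled nanopore reads arrive as 4-line FASTQ records whose fourth line
carries one Phred+33 quality character per base; alignments arrive as SAM
produced by any long-read mapper.  This module converts those external
formats into the pipeline's domain types (:class:`SequenceRecord`,
:class:`ReadRecord`, :class:`AlignmentRecord`) and back.

Conventions
-----------
* Coordinates are 0-based half-open internally; SAM's 1-based ``POS`` is
  converted on read.
* A read's strand class (template / complement / 2D consensus) is inferred
  from an id suffix (default ``.template`` / ``.complement`` / ``.2d``,
  anything else -> plain 1D), the convention used by the common
  FAST5-to-FASTQ converters.  The suffix is stripped from the stored id and
  re-appended on write, so FASTQ round-trips are exact.
* Hard clips never appear in the stored sequence (SAM semantics); soft-clipped
  bases are part of the read but not of the aligned portion.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO

PHRED_OFFSET = 33
MAX_PHRED = 93

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

CIGAR_OPS = "MIDNSHP=XB"
#: CIGAR ops that consume query sequence / reference sequence.
QUERY_OPS = frozenset("MIS=X")
REF_OPS = frozenset("MDN=X")


class FormatError(ValueError):
    """Raised for malformed input files."""


class ReadClass(str, enum.Enum):
    """Strand class of a basecalled read.

    A 2D library molecule carries template and complement strands joined by a
    hairpin; the basecaller emits a read per strand plus a 2D consensus.
    Reads without strand information (1D libraries, failed hairpins) are
    ``RAW_1D``.
    """

    TEMPLATE = "template"
    COMPLEMENT = "complement"
    CONSENSUS_2D = "consensus2d"
    RAW_1D = "raw1d"


#: default id-suffix convention for strand classes
DEFAULT_CLASS_SUFFIXES: Mapping[str, ReadClass] = {
    ".template": ReadClass.TEMPLATE,
    ".complement": ReadClass.COMPLEMENT,
    ".2d": ReadClass.CONSENSUS_2D,
}

_CLASS_TO_SUFFIX = {
    ReadClass.TEMPLATE: ".template",
    ReadClass.COMPLEMENT: ".complement",
    ReadClass.CONSENSUS_2D: ".2d",
    ReadClass.RAW_1D: "",
}


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (e.g. a reference genome contig)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"sequence of {self.id!r} is empty")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ValueError(
                f"sequence of {self.id!r} contains invalid characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ReadRecord:
    """One basecalled read with its per-base Phred quality scores."""

    id: str
    read_class: ReadClass
    sequence: str
    qualities: list[int]

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        if self.qualities and (min(self.qualities) < 0 or max(self.qualities) > MAX_PHRED):
            raise ValueError(f"read {self.id!r}: Phred scores must be in [0, {MAX_PHRED}]")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def qualified_id(self) -> str:
        """Id with the strand-class suffix re-attached (as written to files)."""
        return self.id + _CLASS_TO_SUFFIX[self.read_class]


@dataclass
class AlignmentRecord:
    """One read-to-reference mapping parsed from SAM.

    ``cigar`` is an ordered list of ``(op, length)`` pairs with op one of
    ``M = X I D S H N``; ``nm`` is the SAM edit distance (substituted +
    inserted + deleted bases).  ``ref_start`` is 0-based.
    """

    read_id: str
    cigar: list[tuple[str, int]] = field(default_factory=list)
    nm: int | None = None
    ref_name: str | None = None
    ref_start: int = 0
    strand: str = "+"
    is_mapped: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.is_mapped:
            if not self.cigar:
                raise ValueError(f"mapped record {self.read_id!r} has empty CIGAR")
            if self.nm is not None and self.nm < 0:
                raise ValueError(f"record {self.read_id!r}: NM must be >= 0")
        for op, length in self.cigar:
            if op not in "MIDNSHP=X":
                raise ValueError(f"record {self.read_id!r}: bad CIGAR op {op!r}")
            if length < 1:
                raise ValueError(f"record {self.read_id!r}: CIGAR length must be >= 1")

    def op_total(self, ops: str) -> int:
        """Summed length of the given CIGAR op characters."""
        return sum(n for op, n in self.cigar if op in ops)

    @property
    def ref_end(self) -> int:
        """0-based exclusive end on the reference."""
        return self.ref_start + self.op_total("MDN=X")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def split_class_suffix(
    read_id: str, class_suffixes: Mapping[str, ReadClass] = DEFAULT_CLASS_SUFFIXES
) -> tuple[str, ReadClass]:
    """Split the strand-class suffix off a read id; no suffix means RAW_1D."""
    for suffix, cls in class_suffixes.items():
        if read_id.endswith(suffix):
            return read_id[: -len(suffix)], cls
    return read_id, ReadClass.RAW_1D


def read_fastq(
    path: str | Path,
    class_suffixes: Mapping[str, ReadClass] = DEFAULT_CLASS_SUFFIXES,
) -> list[ReadRecord]:
    """Parse a Phred+33 FASTQ file into :class:`ReadRecord` objects.

    Malformed records (sequence/quality length mismatch, quality characters
    below ``'!'``) raise :class:`FormatError` naming the offending record.
    """
    path = Path(path)
    records: list[ReadRecord] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            base_id, cls = split_class_suffix(rec.id, class_suffixes)
            records.append(
                ReadRecord(
                    id=base_id,
                    read_class=cls,
                    sequence=str(rec.seq).upper(),
                    qualities=list(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:  # Biopython's parse errors name the record title
        raise FormatError(f"malformed FASTQ {path}: {exc}") from exc
    return records


def write_fastq(records: Iterable[ReadRecord], path: str | Path) -> None:
    """Write reads as 4-line Phred+33 FASTQ, re-attaching class suffixes."""
    with open(path, "w") as fh:
        for rec in records:
            qual = "".join(chr(q + PHRED_OFFSET) for q in rec.qualities)
            fh.write(f"@{rec.qualified_id}\n{rec.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse FASTA; sequences are uppercased and U is mapped to T."""
    path = Path(path)
    records = [
        SequenceRecord(id=rec.id, sequence=str(rec.seq).upper().replace("U", "T"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def read_sam(
    path: str | Path,
    include_secondary: bool = False,
    missing_nm: str = "error",
) -> list[AlignmentRecord]:
    """Parse a SAM file into :class:`AlignmentRecord` objects.

    Secondary (0x100) and supplementary (0x800) alignments are excluded by
    default.  Unmapped records (0x4) yield ``is_mapped=False``.  A mapped
    record without an NM tag is a hard error unless ``missing_nm="count_x"``
    and the CIGAR uses ``=``/``X`` ops, in which case NM falls back to the
    mismatch count (indel lengths included).
    """
    if missing_nm not in ("error", "count_x"):
        raise ValueError("missing_nm must be 'error' or 'count_x'")
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if (aln.is_secondary or aln.is_supplementary) and not include_secondary:
                continue
            if aln.is_unmapped:
                records.append(AlignmentRecord(read_id=aln.query_name, is_mapped=False))
                continue
            cigar = [(CIGAR_OPS[op], length) for op, length in aln.cigartuples]
            if aln.has_tag("NM"):
                nm = int(aln.get_tag("NM"))
            elif missing_nm == "count_x" and any(op in "=X" for op, _ in cigar):
                nm = sum(n for op, n in cigar if op in "XID")
            else:
                raise FormatError(f"mapped record {aln.query_name!r} lacks an NM tag")
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    cigar=cigar,
                    nm=nm,
                    ref_name=aln.reference_name,
                    ref_start=aln.reference_start,
                    strand="-" if aln.is_reverse else "+",
                    is_mapped=True,
                )
            )
    return records


def write_sam(
    pairs: Iterable[tuple[ReadRecord, AlignmentRecord]],
    references: Sequence[SequenceRecord],
    path: str | Path,
) -> None:
    """Write (read, alignment) pairs as SAM.

    For minus-strand alignments the sequence and qualities are stored
    reverse-complemented / reversed and the CIGAR is emitted in reference
    orientation, per the SAM convention.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": ref.id, "LN": len(ref)} for ref in references],
    }
    ref_index = {ref.id: i for i, ref in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read, aln in pairs:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.qualified_id
            if aln.is_mapped and aln.strand == "-":
                seg.query_sequence = reverse_complement(read.sequence)
                seg.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + PHRED_OFFSET) for q in reversed(read.qualities))
                )
            else:
                seg.query_sequence = read.sequence
                seg.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + PHRED_OFFSET) for q in read.qualities)
                )
            if aln.is_mapped:
                seg.flag = 16 if aln.strand == "-" else 0
                seg.reference_id = ref_index[aln.ref_name]
                seg.reference_start = aln.ref_start
                seg.cigarstring = "".join(f"{n}{op}" for op, n in aln.cigar)
                seg.mapping_quality = 60
                if aln.nm is not None:
                    seg.set_tag("NM", aln.nm)
            else:
                seg.flag = 4
            out.write(seg)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

SCHEMA_VERSION = "1.0"


def write_tsv(df, path: str | Path) -> None:
    """Write a DataFrame as a TSV report with a header line."""
    df.to_csv(path, sep="\t", index=False)


def write_json(obj: dict, path: str | Path) -> None:
    """Write a JSON report with a top-level ``schema_version`` key."""
    payload = {"schema_version": SCHEMA_VERSION, **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
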