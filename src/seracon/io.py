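"""File formats: FASTQ, FASTA, SAM flag ingestion, TSV/JSON helpers.

All genomic coordinates handled by this package are 0-based, half-open on
the forward strand. Quality strings are PHRED+33 throughout; PHRED+64 input
is rejected rather than auto-detected.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _stdio
import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "Read",
    "FormatError",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "write_fasta",
    "read_sam_mapped",
    "phred_values",
    "open_text",
    "sha256_of",
]

_GZIP_MAGIC = b"\x1f\x8b"

# Valid PHRED+33 quality characters span '!' (Q0) .. '~' (Q93).
_QUAL_MIN = 33
_QUAL_MAX = 126


class FormatError(ValueError):
    """A file does not conform to its expected format."""


@dataclass(frozen=True)
class Read:
    """A single sequencing read with its PHRED+33 quality string."""

    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise FormatError(
                f"read {self.id!r}: sequence length {len(self.seq)} != "
                f"quality length {len(self.qual)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def phred_values(qual: str) -> list[int]:
    """Decode a PHRED+33 quality string to integer scores."""
    return [ord(c) - 33 for c in qual]


def open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """Open a text file, transparently decompressing gzip (detected by magic
    bytes, not by file extension)."""
    path = Path(path)
    if "r" in mode:
        with open(path, "rb") as fh:
            magic = fh.read(2)
        if magic == _GZIP_MAGIC:
            return gzip.open(path, mode)  # type: ignore[return-value]
        return open(path, mode)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _check_quality(qual: str, record_no: int, read_id: str) -> None:
    for ch in qual:
        o = ord(ch)
        if o < _QUAL_MIN or o > _QUAL_MAX:
            raise FormatError(
                f"record {record_no} ({read_id!r}): quality character "
                f"{ch!r} (ord {o}) outside the PHRED+33 range"
            )


def read_fastq(path: str | Path) -> list[Read]:
    """Read a 4-line-record PHRED+33 FASTQ file (optionally gzipped).

    Raises :class:`FormatError` naming the offending record on truncation,
    sequence/quality length mismatch, or out-of-range quality bytes.
    Returns an empty list for an empty file.
    """
    reads: list[Read] = []
    with open_text(path) as fh:
        record_no = 0
        while True:
            header = fh.readline()
            if not header:
                break
            record_no += 1
            lines = [header] + [fh.readline() for _ in range(3)]
            if any(not ln for ln in lines):
                raise FormatError(f"record {record_no}: truncated FASTQ record")
            header, seq, plus, qual = (ln.rstrip("\n") for ln in lines)
            if not header.startswith("@"):
                raise FormatError(
                    f"record {record_no}: expected '@' header, got {header[:30]!r}"
                )
            if not plus.startswith("+"):
                raise FormatError(
                    f"record {record_no}: expected '+' separator, got {plus[:30]!r}"
                )
            read_id = header[1:].split()[0] if len(header) > 1 else ""
            if len(seq) != len(qual):
                raise FormatError(
                    f"record {record_no} ({read_id!r}): sequence length "
                    f"{len(seq)} != quality length {len(qual)}"
                )
            _check_quality(qual, record_no, read_id)
            reads.append(Read(read_id, seq, qual))
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open_text(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping.

    Multi-line sequences are concatenated; the name is the first whitespace
    token of the header.
    """
    out: dict[str, str] = {}
    with open_text(path) as fh:
        first = fh.read(1)
        if not first:
            return out
        if first != ">":
            raise FormatError("line 1: FASTA file must start with '>'")
        fh.seek(0)
        for title, seq in SimpleFastaParser(fh):
            name = title.split()[0]
            out[name] = seq.upper()
    return out


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open_text(path, "wt") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# SAM flag bits used for ingestion.
_FLAG_UNMAPPED = 0x4
_FLAG_SECONDARY = 0x100
_FLAG_SUPPLEMENTARY = 0x800


def read_sam_mapped(path: str | Path) -> dict[str, bool]:
    """Extract mapped/unmapped status per read from a SAM text file.

    Only primary records count (secondary 0x100 and supplementary 0x800 are
    skipped); a read is mapped iff flag bit 0x4 is unset on any primary
    record. Raises :class:`FormatError` with the line number on malformed
    records.
    """
    status: dict[str, bool] = {}
    with open_text(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise FormatError(
                    f"line {line_no}: SAM record has {len(fields)} fields, "
                    "expected at least 11"
                )
            qname = fields[0]
            try:
                flag = int(fields[1])
            except ValueError:
                raise FormatError(
                    f"line {line_no}: non-integer FLAG field {fields[1]!r}"
                ) from None
            if flag & (_FLAG_SECONDARY | _FLAG_SUPPLEMENTARY):
                continue
            mapped = not flag & _FLAG_UNMAPPED
            status[qname] = status.get(qname, False) or mapped
    return status


def write_json(obj: object, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
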