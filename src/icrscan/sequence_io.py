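"""Chromosome FASTA reading and normalization.

Sequences are normalized for exact-string scanning: uppercased, with every
IUPAC ambiguity code other than A/C/G/T mapped to N.  N never participates
in a motif match downstream, so assembly gaps are handled transparently.

Coordinates are 0-based half-open throughout the package; conversion to the
1-based convention happens only in genome-browser track writers.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

logger = logging.getLogger(__name__)

# IUPAC nucleotide codes; everything outside A/C/G/T becomes N.
_IUPAC = "ACGTUNRYSWKMBDHV"
_NORMALIZE = str.maketrans(
    _IUPAC.lower() + _IUPAC,
    "ACGT" + "N" * (len(_IUPAC) - 4) + "ACGT" + "N" * (len(_IUPAC) - 4),
)
_VALID_OUT = frozenset("ACGTN")


class FastaError(ValueError):
    """Malformed or inconsistent FASTA input."""


@dataclass(frozen=True)
class ChromRecord:
    """One normalized chromosome/contig: name, length, and ACGTN sequence."""

    name: str
    length: int
    sequence: str

    def __post_init__(self):
        if self.length != len(self.sequence):
            raise FastaError(
                f"record {self.name}: declared length {self.length} != "
                f"sequence length {len(self.sequence)}"
            )


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[ChromRecord]:
    """Read all records from a (optionally gzip-compressed) FASTA file.

    Returns one ChromRecord per header in file order.  Record names are the
    header token up to the first whitespace.  Duplicate names and characters
    outside the IUPAC nucleotide set are rejected; ambiguity codes are mapped
    to N with a logged substitution count.
    """
    path = Path(path)
    if not path.exists():
        raise FastaError(f"FASTA file not found: {path}")
    records: list[ChromRecord] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            name = rec.id
            if name in seen:
                raise FastaError(f"duplicate FASTA record name: {name!r}")
            seen.add(name)
            raw = str(rec.seq)
            seq = raw.translate(_NORMALIZE)
            bad = set(seq) - _VALID_OUT
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise FastaError(
                    f"record {name}: character {raw[pos]!r} at position {pos} "
                    f"is outside the IUPAC nucleotide alphabet"
                )
            n_sub = sum(1 for a, b in zip(raw.upper(), seq) if a != b and b == "N" and a != "N")
            if n_sub:
                logger.info(
                    "record %s: mapped %d IUPAC ambiguity base(s) to N", name, n_sub
                )
            records.append(ChromRecord(name=name, length=len(seq), sequence=seq))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: list[ChromRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA with fixed-width line wrapping and UNIX newlines."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")
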