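"""Exact-string motif scanning along chromosomes.

Every occurrence of the hexamer and of each ZMO is located by exact string
matching (overlapping matches included).  Under the both-strands policy a
motif is also searched as its reverse complement, reported on the minus
strand at the forward coordinates of the reverse-complement match; a
double-helical element is present regardless of the strand it is read from.

Position-level deduplication: occurrences identical in (chrom, start, end,
strand) within a category are collapsed to one record, so palindromic
double-matches and redundantly configured motifs never inflate the counts
that feed the density statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from .motif_model import MotifSet, StrandPolicy, reverse_complement
from .sequence_io import ChromRecord

logger = logging.getLogger(__name__)

CATEGORY_HEXAMER = "hexamer"
CATEGORY_ZMO = "zmo"


@dataclass(frozen=True, order=True)
class Occurrence:
    """One exact motif match: 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str
    motif_id: str
    category: str

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def _forward_starts(sequence: str, motif: str) -> list[int]:
    starts = []
    i = sequence.find(motif)
    while i != -1:
        starts.append(i)
        i = sequence.find(motif, i + 1)
    return starts


def find_matches(
    sequence: str, motif: str, strand_policy: StrandPolicy = StrandPolicy.both_strands
) -> set[tuple[int, str]]:
    """All exact (possibly overlapping) matches of ``motif`` in ``sequence``.

    Returns (start, strand) pairs.  Under both_strands, forward matches of
    the reverse complement are reported with strand '-'.  For a palindromic
    motif (reverse complement equal to itself) the +/- duplicates collapse
    to the '+' record.  N in the sequence never matches.
    """
    motif = motif.upper()
    if not motif:
        raise ValueError("motif must be nonempty")
    hits = {(s, "+") for s in _forward_starts(sequence, motif)}
    if strand_policy is StrandPolicy.both_strands:
        rc = reverse_complement(motif)
        if rc != motif:
            hits |= {(s, "-") for s in _forward_starts(sequence, rc)}
    return hits


def scan_genome(
    chroms: Iterable[ChromRecord], motifset: MotifSet
) -> list[Occurrence]:
    """Locate every hexamer and ZMO occurrence across all chromosomes.

    Output is sorted by (chrom, start, end, strand).  Within the zmo
    category, occurrences identical in coordinates and strand but arising
    from different motif strings are collapsed to one record, keeping the
    motif_id of the first motif in the set's deterministic order.
    """
    if not motifset.zmos:
        logger.warning("motif set has no ZMOs; emitting hexamer-only occurrences")
    out: list[Occurrence] = []
    for chrom in chroms:
        seq = chrom.sequence
        for start, strand in find_matches(seq, motifset.hexamer, motifset.strand_policy):
            out.append(
                Occurrence(
                    chrom=chrom.name,
                    start=start,
                    end=start + len(motifset.hexamer),
                    strand=strand,
                    motif_id=motifset.hexamer,
                    category=CATEGORY_HEXAMER,
                )
            )
        seen: dict[tuple[str, int, int, str], str] = {}
        for zmo in motifset.zmos:
            for start, strand in find_matches(seq, zmo, motifset.strand_policy):
                key = (chrom.name, start, start + len(zmo), strand)
                seen.setdefault(key, zmo)
        for (name, start, end, strand), zmo in seen.items():
            out.append(
                Occurrence(
                    chrom=name,
                    start=start,
                    end=end,
                    strand=strand,
                    motif_id=zmo,
                    category=CATEGORY_ZMO,
                )
            )
    out.sort(key=lambda o: (o.chrom, o.start, o.end, o.strand))
    return out
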