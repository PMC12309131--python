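"""Sliding-window ZMO density profile.

A fixed-length window (default 850 nt) slides along each chromosome in
fixed steps (default 6 nt), starting at 0-based position 5 (1-based
nucleotide 6).  A window is emitted only when it encompasses at least
``min_count`` ZMO occurrences (default 2, the definitional rule for a
candidate peak); the emitted point records the window midpoint, the raw
occurrence count, and the count capped at the 0-5 display scale used on
the genome browser.  The cap is display-only: the raw count is preserved
for peak scoring.

Window membership defaults to "an occurrence belongs to a window iff its
start lies in the window", which counts every occurrence in the same number
of windows regardless of motif length; full containment is available as an
alternative rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .scanner import CATEGORY_ZMO, Occurrence

logger = logging.getLogger(__name__)

MEMBERSHIP_START = "start"
MEMBERSHIP_CONTAINED = "contained"


class ContractViolation(ValueError):
    """Input does not satisfy a documented precondition."""


@dataclass(frozen=True)
class DensityParams:
    """Sliding-window parameters; defaults are the method's published values."""

    window_length: int = 850
    step: int = 6
    start_offset: int = 5
    min_count: int = 2
    display_cap: int = 5
    membership: str = MEMBERSHIP_START

    def __post_init__(self):
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.start_offset < 0:
            raise ValueError("start_offset must be >= 0")
        if not 2 <= self.min_count <= self.display_cap:
            raise ValueError(
                f"min_count must satisfy 2 <= min_count <= display_cap "
                f"(got min_count={self.min_count}, display_cap={self.display_cap})"
            )
        if self.membership not in (MEMBERSHIP_START, MEMBERSHIP_CONTAINED):
            raise ValueError(f"unknown membership rule {self.membership!r}")


@dataclass(frozen=True)
class DensityPoint:
    """One qualifying window: start, midpoint, raw ZMO count, capped display value."""

    chrom: str
    window_start: int
    midpoint: int
    raw_count: int
    display_value: int


def compute_density(
    occurrences: Sequence[Occurrence],
    chrom_length: int,
    params: DensityParams,
    chrom: str | None = None,
) -> list[DensityPoint]:
    """Emit a DensityPoint for every window holding >= min_count ZMO occurrences.

    Windows are [w, w + window_length) for w = start_offset, start_offset +
    step, ... while the window still fits on the chromosome (the slide stops
    at the last full window).  ``occurrences`` must be ZMO occurrences from a
    single chromosome, sorted by start.
    """
    occurrences = list(occurrences)
    for occ in occurrences:
        if occ.category != CATEGORY_ZMO:
            raise ContractViolation(f"expected only zmo occurrences, got {occ.category}")
    chrom_names = {occ.chrom for occ in occurrences}
    if len(chrom_names) > 1:
        raise ContractViolation(f"occurrences span multiple chromosomes: {sorted(chrom_names)}")
    if chrom is None:
        chrom = next(iter(chrom_names)) if chrom_names else ""
    elif chrom_names and chrom_names != {chrom}:
        raise ContractViolation(
            f"occurrences are on {chrom_names.pop()!r}, not the requested {chrom!r}"
        )
    starts = np.array([occ.start for occ in occurrences], dtype=np.int64)
    if np.any(np.diff(starts) < 0):
        raise ContractViolation("occurrences must be sorted by start")

    L = params.window_length
    if chrom_length < L:
        logger.warning(
            "chromosome %s (length %d) is shorter than the %d nt window; no density output",
            chrom, chrom_length, L,
        )
        return []

    window_starts = np.arange(params.start_offset, chrom_length - L + 1, params.step, dtype=np.int64)
    if window_starts.size == 0:
        return []

    if params.membership == MEMBERSHIP_START:
        counts = np.searchsorted(starts, window_starts + L, side="left") - np.searchsorted(
            starts, window_starts, side="left"
        )
    else:
        ends = np.array([occ.end for occ in occurrences], dtype=np.int64)
        counts = np.array(
            [int(np.sum((starts >= w) & (ends <= w + L))) for w in window_starts],
            dtype=np.int64,
        )

    points: list[DensityPoint] = []
    half = L // 2
    for w, c in zip(window_starts.tolist(), counts.tolist()):
        if c >= params.min_count:
            points.append(
                DensityPoint(
                    chrom=chrom,
                    window_start=w,
                    midpoint=w + half,
                    raw_count=c,
                    display_value=min(c, params.display_cap),
                )
            )
    return points
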