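"""Candidate-ICR peak calling from density points.

Maximal runs of qualifying windows whose intervals overlap or abut are
merged into one peak spanning the union of the contributing windows, so
every ZMO occurrence counted by any contributing window lies inside the
reported interval.  The peak score is the maximum raw window count capped
at the display scale (2-5): 5 is more robust than 4, 4 than 3, 3 than 2.
Peaks whose maximum raw count is exactly 2 are flagged low-confidence —
two-ZMO peaks can be true or false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .density_profile import ContractViolation, DensityParams, DensityPoint


@dataclass(frozen=True)
class Peak:
    """A candidate ICR: union of overlapping qualifying windows, with robustness score."""

    chrom: str
    start: int
    end: int
    score: int
    n_points: int
    max_raw: int
    low_confidence: bool | None = None


def call_peaks(
    points: Sequence[DensityPoint],
    params: DensityParams,
    max_gap: int = 0,
) -> list[Peak]:
    """Merge overlapping-or-abutting window intervals into scored peaks.

    ``points`` must come from one chromosome and one parameter set, sorted by
    window_start.  Two successive windows merge when the next window starts
    no more than ``max_gap`` bases after the previous union ends (max_gap=0
    is the overlap-or-abut rule; larger values bridge small gaps for
    sensitivity analysis).
    """
    points = list(points)
    if not points:
        return []
    chroms = {p.chrom for p in points}
    if len(chroms) > 1:
        raise ContractViolation(f"density points span multiple chromosomes: {sorted(chroms)}")
    ws = [p.window_start for p in points]
    if any(b < a for a, b in zip(ws, ws[1:])):
        raise ContractViolation("density points must be sorted by window_start")

    L = params.window_length
    peaks: list[Peak] = []
    run_start = points[0].window_start
    run_end = run_start + L
    run_max = points[0].raw_count
    run_n = 1
    chrom = points[0].chrom
    for p in points[1:]:
        if p.window_start <= run_end + max_gap:
            run_end = max(run_end, p.window_start + L)
            run_max = max(run_max, p.raw_count)
            run_n += 1
        else:
            peaks.append(
                Peak(chrom, run_start, run_end, min(run_max, params.display_cap), run_n, run_max)
            )
            run_start = p.window_start
            run_end = run_start + L
            run_max = p.raw_count
            run_n = 1
    peaks.append(
        Peak(chrom, run_start, run_end, min(run_max, params.display_cap), run_n, run_max)
    )
    return peaks


def flag_low_confidence(peaks: Sequence[Peak]) -> list[Peak]:
    """Mark each peak low-confidence iff its maximum raw count is exactly 2."""
    return [replace(p, low_confidence=(p.max_raw == 2)) for p in peaks]
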