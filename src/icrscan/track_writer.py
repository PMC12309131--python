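"""UCSC custom-track serialization: BED6, bedGraph, and variableStep WIG.

Conventions mirror the browser figures the method was designed for: the
hexamer track is suggested dense, the ZMO track pack, the density track
full; motif tracks default to hunter green and the peak track to maroon.
Visibility and color are advisory track-line metadata and never alter data.

All BED/bedGraph records are 0-based half-open, sorted by (chrom, start),
tab-delimited, UNIX newlines; output is byte-identical across runs for
identical inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .density_profile import DensityPoint
from .peak_caller import Peak
from .scanner import CATEGORY_HEXAMER, CATEGORY_ZMO, Occurrence

logger = logging.getLogger(__name__)

HUNTER_GREEN = "53,94,59"
MAROON = "128,0,0"


@dataclass(frozen=True)
class TrackBundle:
    """Paths of one run's custom-track files plus the genome label."""

    hexamer_track: Path
    zmo_track: Path
    density_track: Path
    peak_track: Path
    peak_report: Path
    genome_label: str


def track_line(name: str, description: str, visibility: str,
               color: str | None = None, track_type: str | None = None) -> str:
    parts = ["track"]
    if track_type:
        parts.append(f"type={track_type}")
    parts.append(f'name="{name}"')
    parts.append(f'description="{description}"')
    parts.append(f"visibility={visibility}")
    if color:
        parts.append(f"color={color}")
    return " ".join(parts)


def write_occurrence_bed(path: str | Path, occurrences: Sequence[Occurrence],
                         header: str) -> None:
    """Write occurrences as BED6: chrom, start, end, name=motif_id, score=0, strand."""
    rows = sorted(occurrences, key=lambda o: (o.chrom, o.start, o.end, o.strand))
    with open(path, "w", newline="\n") as fh:
        fh.write(header + "\n")
        for o in rows:
            fh.write(f"{o.chrom}\t{o.start}\t{o.end}\t{o.motif_id}\t0\t{o.strand}\n")


def read_occurrence_bed(path: str | Path, category: str) -> list[Occurrence]:
    """Read a BED6 occurrence file back into Occurrence records."""
    out: list[Occurrence] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")
            out.append(Occurrence(chrom, int(start), int(end), strand, name, category))
    return out


def write_density_bedgraph(path: str | Path, points: Sequence[DensityPoint],
                           header: str) -> None:
    """Write density points as bedGraph: one 1-bp bin at each window midpoint."""
    rows = sorted(points, key=lambda p: (p.chrom, p.midpoint))
    with open(path, "w", newline="\n") as fh:
        fh.write(header + "\n")
        for p in rows:
            fh.write(f"{p.chrom}\t{p.midpoint}\t{p.midpoint + 1}\t{p.display_value}\n")


def read_density_bedgraph(path: str | Path) -> list[tuple[str, int, int, int]]:
    """Read a bedGraph back as (chrom, start, end, value) rows."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split("\t")
            out.append((chrom, int(start), int(end), int(value)))
    return out


def write_density_wig(path: str | Path, points: Sequence[DensityPoint],
                      header: str) -> None:
    """variableStep WIG alternative for the density track (1-based positions)."""
    rows = sorted(points, key=lambda p: (p.chrom, p.midpoint))
    with open(path, "w", newline="\n") as fh:
        fh.write(header + "\n")
        current = None
        for p in rows:
            if p.chrom != current:
                fh.write(f"variableStep chrom={p.chrom}\n")
                current = p.chrom
            fh.write(f"{p.midpoint + 1} {p.display_value}\n")


def write_peak_bed(path: str | Path, peaks: Sequence[Peak], header: str) -> None:
    """Write peaks as BED6 (name=ICR_candidate_<n>, score=100*robustness, strand '.')."""
    rows = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    with open(path, "w", newline="\n") as fh:
        fh.write(header + "\n")
        for n, p in enumerate(rows, start=1):
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tICR_candidate_{n}\t{100 * p.score}\t.\n")


def write_peak_report(path: str | Path, peaks: Sequence[Peak]) -> None:
    """TSV report with the uncapped statistics behind each peak."""
    rows = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))
    with open(path, "w", newline="\n") as fh:
        fh.write("chrom\tstart\tend\tname\tscore\tn_points\tmax_raw\tlow_confidence\n")
        for n, p in enumerate(rows, start=1):
            low = "" if p.low_confidence is None else str(p.low_confidence).lower()
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tICR_candidate_{n}\t{p.score}\t"
                f"{p.n_points}\t{p.max_raw}\t{low}\n"
            )


def read_peak_bed(path: str | Path) -> list[tuple[str, int, int, str, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, name, score, strand = line.split("\t")
            out.append((chrom, int(start), int(end), name, int(score), strand))
    return out


def check_chrom_sizes(chroms: Iterable[str], sizes_path: str | Path) -> list[str]:
    """Warn about chromosome names absent from a chrom.sizes file (browser upload would fail)."""
    known = set()
    with open(sizes_path) as fh:
        for line in fh:
            fields = line.split()
            if fields:
                known.add(fields[0])
    missing = sorted(set(chroms) - known)
    if missing:
        logger.warning("chromosome name(s) absent from %s: %s", sizes_path, ", ".join(missing))
    return missing


def write_tracks(
    occurrences: Sequence[Occurrence],
    density_points: Sequence[DensityPoint],
    peaks: Sequence[Peak],
    outdir: str | Path,
    genome_label: str = "synthetic",
    hexamer_name: str = "ZFP57_hexamer",
    wig: bool = False,
    chrom_sizes: str | Path | None = None,
) -> TrackBundle:
    """Serialize one run's occurrences, density profile, and peaks as custom tracks."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hex_occ = [o for o in occurrences if o.category == CATEGORY_HEXAMER]
    zmo_occ = [o for o in occurrences if o.category == CATEGORY_ZMO]

    paths = TrackBundle(
        hexamer_track=outdir / "hexamer.bed",
        zmo_track=outdir / "zmo.bed",
        density_track=outdir / ("density.wig" if wig else "density.bedGraph"),
        peak_track=outdir / "peaks.bed",
        peak_report=outdir / "peaks.tsv",
        genome_label=genome_label,
    )
    write_occurrence_bed(
        paths.hexamer_track, hex_occ,
        track_line(hexamer_name, f"ZFP57 hexamer sites ({genome_label})", "dense", HUNTER_GREEN),
    )
    write_occurrence_bed(
        paths.zmo_track, zmo_occ,
        track_line("ZMOs", f"ZFBS-morph overlaps ({genome_label})", "pack", HUNTER_GREEN),
    )
    density_header = track_line(
        "ZMO_density", f"ZMO density, 850 nt window ({genome_label})", "full",
        track_type=None if wig else "bedGraph",
    )
    if wig:
        write_density_wig(paths.density_track, density_points, density_header)
    else:
        write_density_bedgraph(paths.density_track, density_points, density_header)
    write_peak_bed(
        paths.peak_track, peaks,
        track_line("candidate_ICRs", f"candidate ICR peaks ({genome_label})", "pack", MAROON),
    )
    write_peak_report(paths.peak_report, peaks)

    if chrom_sizes is not None:
        names = {o.chrom for o in occurrences} | {p.chrom for p in density_points} | {
            p.chrom for p in peaks
        }
        check_chrom_sizes(names, chrom_sizes)
    return paths
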