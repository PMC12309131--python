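"""Seeded synthetic genomes with known planted motif structure.

Stands in for real chromosomal DNA at desk scale: an i.i.d. background of
configurable GC content in which every accidental hexamer/ZMO match is
destroyed by local resampling, then ZMO clusters and isolated singletons
are planted at known coordinates.  Because the background is made exactly
motif-free, planted-truth recovery tests are sharp: the scanner must find
exactly the planted occurrences, and the density/peak stages must recover
each cluster as one peak with the expected robustness score.

The background model is per-base i.i.d. with a GC parameter; it does not
emulate repeat structure, CpG islands, or dinucleotide composition of real
assemblies — sufficient for correctness testing, not for realism.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .motif_model import MotifSet, StrandPolicy, reverse_complement
from .scanner import CATEGORY_ZMO, scan_genome
from .sequence_io import ChromRecord, write_fasta

logger = logging.getLogger(__name__)

_MAX_CLEAN_ITER = 60


@dataclass(frozen=True)
class ClusterSpec:
    """A planted ZMO cluster: k motifs spread over at most ``spread`` bases."""

    anchor: int
    k: int
    spread: int


@dataclass(frozen=True)
class SyntheticSpec:
    """Blueprint for one synthetic chromosome with planted truth."""

    chrom_length: int
    gc_content: float
    clusters: tuple[ClusterSpec, ...] = ()
    singletons: tuple[int, ...] = ()
    seed: int = 0
    chrom_name: str = "chrS"
    window_length: int = 850  # used for spread caps and separation checks

    def __post_init__(self):
        object.__setattr__(
            self, "clusters", tuple(c if isinstance(c, ClusterSpec) else ClusterSpec(*c)
                                    for c in self.clusters)
        )
        object.__setattr__(self, "singletons", tuple(self.singletons))
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        for c in self.clusters:
            if c.k < 2:
                raise ValueError(f"cluster at {c.anchor}: k must be >= 2, got {c.k}")
            if c.spread > self.window_length:
                raise ValueError(
                    f"cluster at {c.anchor}: spread {c.spread} exceeds window {self.window_length}"
                )

    def _element_intervals(self, motif_len: int) -> list[tuple[int, int]]:
        iv = [(c.anchor, c.anchor + c.spread + motif_len) for c in self.clusters]
        iv += [(s, s + motif_len) for s in self.singletons]
        return sorted(iv)

    def validate_layout(self, max_motif_len: int) -> None:
        """Bounds and pairwise-separation checks; raises before any generation."""
        iv = self._element_intervals(max_motif_len)
        for lo, hi in iv:
            if lo < 0 or hi > self.chrom_length:
                raise ValueError(f"planted element [{lo}, {hi}) outside chromosome bounds")
        for (_, hi), (lo2, _) in zip(iv, iv[1:]):
            if lo2 - hi <= 2 * self.window_length:
                raise ValueError(
                    f"planted elements separated by {lo2 - hi} <= 2 x window "
                    f"({2 * self.window_length}); truth labels would be ambiguous"
                )
        for c in self.clusters:
            if c.k > 1 and c.spread // (c.k - 1) <= max_motif_len:
                raise ValueError(
                    f"cluster at {c.anchor}: spread {c.spread} too small to place "
                    f"{c.k} non-overlapping motifs of length {max_motif_len}"
                )


@dataclass(frozen=True)
class PlantedZmo:
    start: int
    motif: str


@dataclass(frozen=True)
class SyntheticTruth:
    """Generated FASTA plus the planted ground truth for recovery testing."""

    fasta_path: Path
    cluster_bed_path: Path
    singleton_bed_path: Path
    spec_json_path: Path
    chrom: ChromRecord
    cluster_truth: tuple[tuple[int, int, int, int], ...]  # (start, end, k, expected_score)
    singleton_truth: tuple[PlantedZmo, ...]
    planted: tuple[PlantedZmo, ...]


def _check_motifset_unambiguous(motifset: MotifSet) -> None:
    """Reject ZMO sets whose planted occurrences could not be counted exactly."""
    zmos = motifset.zmos
    if not zmos:
        raise ValueError("synthetic generation requires a motif set with >= 1 ZMO")
    for z in zmos:
        for other in zmos:
            if other != z and other in z:
                raise ValueError(
                    f"nested ZMO strings ({other!r} inside {z!r}): planted-truth "
                    f"counts would be ambiguous"
                )
            if motifset.strand_policy is StrandPolicy.both_strands and reverse_complement(other) in z:
                raise ValueError(
                    f"ZMO {other!r} reverse-complement occurs inside {z!r}: planted-truth "
                    f"counts would be ambiguous under both-strand scanning"
                )


def _find_all(text: str, word: str) -> list[int]:
    hits = []
    i = text.find(word)
    while i != -1:
        hits.append(i)
        i = text.find(word, i + 1)
    return hits


def _cluster_starts(cluster: ClusterSpec) -> list[int]:
    # evenly spaced, endpoints included, so first-to-last distance equals spread
    if cluster.k == 1:
        return [cluster.anchor]
    return [cluster.anchor + round(i * cluster.spread / (cluster.k - 1)) for i in range(cluster.k)]


def generate(spec: SyntheticSpec, motifset: MotifSet, outdir: str | Path) -> SyntheticTruth:
    """Generate a synthetic chromosome with exact planted truth.

    The background is drawn base-wise from the GC model, accidental matches
    of every motif (and reverse complement) are destroyed by resampling,
    planted ZMOs are written at truth positions, and junction-created
    matches are destroyed the same way.  The result is verified by a full
    scan: the ZMO occurrence set must equal the planted set exactly.
    Identical seeds give byte-identical FASTA output.
    """
    _check_motifset_unambiguous(motifset)
    max_len = max(len(z) for z in motifset.zmos)
    spec.validate_layout(max_len)

    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seq = bytearray(bases[rng.choice(4, size=spec.chrom_length, p=probs)].tobytes())

    kill_words = {motifset.hexamer} | set(motifset.zmos)
    kill_words |= {reverse_complement(w) for w in kill_words}

    def resample(positions: list[int]) -> None:
        draw = bases[rng.choice(4, size=len(positions), p=probs)]
        for p, b in zip(positions, draw):
            seq[p] = b

    def clean(protected: list[tuple[int, int]]) -> None:
        """Destroy every match not fully inside a protected footprint."""
        for _ in range(_MAX_CLEAN_ITER):
            text = seq.decode()
            dirty: set[int] = set()
            for word in kill_words:
                for s in _find_all(text, word):
                    e = s + len(word)
                    if any(s >= lo and e <= hi for lo, hi in protected):
                        continue
                    dirty.update(
                        p for p in range(s, e)
                        if not any(lo <= p < hi for lo, hi in protected)
                    )
            if not dirty:
                return
            resample(sorted(dirty))
        raise RuntimeError(
            "failed to clear accidental motif matches; GC content may make the "
            "motif vocabulary too dense for rejection sampling"
        )

    clean([])

    planted: list[PlantedZmo] = []
    cluster_truth: list[tuple[int, int, int, int]] = []
    for c in spec.clusters:
        starts = _cluster_starts(c)
        chosen = [motifset.zmos[i] for i in rng.integers(0, len(motifset.zmos), size=c.k)]
        for s, z in zip(starts, chosen):
            seq[s : s + len(z)] = z.encode()
            planted.append(PlantedZmo(s, z))
        end = starts[-1] + len(chosen[-1])
        cluster_truth.append((c.anchor, end, c.k, min(c.k, 5)))
    singleton_truth: list[PlantedZmo] = []
    for s in spec.singletons:
        z = motifset.zmos[int(rng.integers(0, len(motifset.zmos)))]
        seq[s : s + len(z)] = z.encode()
        planted.append(PlantedZmo(s, z))
        singleton_truth.append(PlantedZmo(s, z))

    footprints = [(p.start, p.start + len(p.motif)) for p in planted]
    clean(footprints)

    chrom = ChromRecord(spec.chrom_name, spec.chrom_length, seq.decode())

    expected = {(p.start, p.start + len(p.motif), "+") for p in planted}
    observed = {
        (o.start, o.end, o.strand)
        for o in scan_genome([chrom], motifset)
        if o.category == CATEGORY_ZMO
    }
    if observed != expected:
        raise RuntimeError(
            f"planted-truth verification failed: {len(observed ^ expected)} "
            f"occurrence(s) differ between scan and plan"
        )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta_path = outdir / f"{spec.chrom_name}.fa"
    write_fasta([chrom], fasta_path)

    cluster_bed = outdir / "truth_clusters.bed"
    with open(cluster_bed, "w", newline="\n") as fh:
        for n, (start, end, k, score) in enumerate(cluster_truth, start=1):
            fh.write(f"{spec.chrom_name}\t{start}\t{end}\tcluster_{n}_k{k}\t{score}\t.\n")
    singleton_bed = outdir / "truth_singletons.bed"
    with open(singleton_bed, "w", newline="\n") as fh:
        for n, p in enumerate(singleton_truth, start=1):
            fh.write(
                f"{spec.chrom_name}\t{p.start}\t{p.start + len(p.motif)}\tsingleton_{n}\t0\t.\n"
            )
    spec_json = outdir / "synthetic_spec.json"
    with open(spec_json, "w", newline="\n") as fh:
        json.dump(asdict(spec), fh, indent=2, sort_keys=True)
        fh.write("\n")

    return SyntheticTruth(
        fasta_path=fasta_path,
        cluster_bed_path=cluster_bed,
        singleton_bed_path=singleton_bed,
        spec_json_path=spec_json,
        chrom=chrom,
        cluster_truth=tuple(cluster_truth),
        singleton_truth=tuple(singleton_truth),
        planted=tuple(sorted(planted, key=lambda p: p.start)),
    )
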