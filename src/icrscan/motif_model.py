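"""Motif vocabulary for candidate-ICR scanning.

The scan vocabulary has two parts: the ZFP57 binding hexamer (TGCCGC, bound
by ZFP57 when the internal CpG is methylated) and the composite ZFBS-morph
overlap elements ("ZMOs") formed by overlapping the hexamer with short
CpG-rich morphemes.  A composite is any minimal string obtained by sliding
the morpheme across the hexamer, requiring the two words to agree at every
shared position, and taking the union of their footprints.

The published ZMO set is not reproduced here; the motif set is runtime
configuration, given either as an explicit string list or derived from a
morpheme lexicon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

DNA_ALPHABET = frozenset("ACGT")
DEFAULT_HEXAMER = "TGCCGC"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MotifValidationError(ValueError):
    """A motif or sequence string violates the DNA alphabet or a motif-set invariant."""


class ConfigError(ValueError):
    """A motif configuration file is missing or inconsistent."""


class StrandPolicy(str, Enum):
    forward_only = "forward_only"
    both_strands = "both_strands"


class MotifSource(str, Enum):
    explicit_list = "explicit_list"
    derived_from_morphemes = "derived_from_morphemes"


def _check_dna(seq: str, *, allow_n: bool = False, what: str = "sequence") -> None:
    allowed = DNA_ALPHABET | ({"N"} if allow_n else set())
    for i, ch in enumerate(seq):
        if ch not in allowed:
            raise MotifValidationError(
                f"{what} contains non-nucleotide character {ch!r} at position {i}"
            )


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}; N maps to N.

    Applying the function twice returns the input (involution).
    """
    seq = seq.upper()
    _check_dna(seq, allow_n=True)
    return seq.translate(_COMPLEMENT)[::-1]


def build_overlap_composites(hexamer: str, morpheme: str, min_overlap: int = 1) -> set[str]:
    """Enumerate every distinct composite of ``hexamer`` and ``morpheme``.

    The hexamer is anchored at offset 0 and the morpheme placed at every
    integer offset at which the two footprints share at least ``min_overlap``
    positions; a placement contributes a composite only if the words agree at
    every shared position.  The composite is the union of the two placed
    words (full containment of one word in the other yields the longer word).

    Returns the deduplicated set of composite strings; empty if no offset is
    consistent.
    """
    hexamer = hexamer.upper()
    morpheme = morpheme.upper()
    _check_dna(hexamer, what="hexamer")
    _check_dna(morpheme, what="morpheme")
    if not hexamer or not morpheme:
        raise MotifValidationError("hexamer and morpheme must be nonempty")
    if not 1 <= min_overlap <= min(len(hexamer), len(morpheme)):
        raise ValueError(
            f"min_overlap must be in [1, {min(len(hexamer), len(morpheme))}], got {min_overlap}"
        )

    composites: set[str] = set()
    h, m = len(hexamer), len(morpheme)
    for offset in range(-(m - 1), h):
        lo = max(0, offset)
        hi = min(h, offset + m)
        if hi - lo < min_overlap:
            continue
        if any(hexamer[i] != morpheme[i - offset] for i in range(lo, hi)):
            continue
        start = min(0, offset)
        end = max(h, offset + m)
        union = []
        for i in range(start, end):
            union.append(hexamer[i] if 0 <= i < h else morpheme[i - offset])
        composites.add("".join(union))
    return composites


@dataclass(frozen=True)
class MorphemeLexicon:
    """An ordered collection of morpheme words with a minimum-overlap constraint."""

    morphemes: tuple[str, ...]
    min_overlap: int = 1

    def __post_init__(self):
        if not self.morphemes:
            raise MotifValidationError("morpheme lexicon must be nonempty")
        upper = tuple(m.upper() for m in self.morphemes)
        seen = set()
        deduped = []
        for m in upper:
            _check_dna(m, what="morpheme")
            if m not in seen:
                seen.add(m)
                deduped.append(m)
        object.__setattr__(self, "morphemes", tuple(deduped))
        shortest = min(len(m) for m in self.morphemes)
        if self.min_overlap < 1 or self.min_overlap > shortest:
            raise ValueError(
                f"min_overlap must be in [1, {shortest}] for this lexicon, got {self.min_overlap}"
            )


@dataclass(frozen=True)
class MotifSet:
    """The hexamer plus the deduplicated ZMO collection and strand policy.

    ZMO identifiers are the motif strings themselves: they are unique after
    deduplication, stable across runs, and self-documenting in browser tracks.
    """

    hexamer: str = DEFAULT_HEXAMER
    zmos: tuple[str, ...] = ()
    strand_policy: StrandPolicy = StrandPolicy.both_strands
    source: MotifSource = MotifSource.explicit_list

    def __post_init__(self):
        hexamer = self.hexamer.upper()
        if not hexamer:
            raise MotifValidationError("hexamer must be nonempty")
        _check_dna(hexamer, what="hexamer")
        object.__setattr__(self, "hexamer", hexamer)

        upper = [z.upper() for z in self.zmos]
        seen = set()
        deduped = []
        for z in upper:
            if not z:
                raise MotifValidationError("ZMO strings must be nonempty")
            _check_dna(z, what=f"ZMO {z!r}")
            if z not in seen:
                seen.add(z)
                deduped.append(z)
        object.__setattr__(self, "zmos", tuple(deduped))

        if self.source is MotifSource.derived_from_morphemes:
            for z in self.zmos:
                if hexamer not in z:
                    raise MotifValidationError(
                        f"derived ZMO {z!r} does not contain the hexamer {hexamer!r}"
                    )
        if isinstance(self.strand_policy, str) and not isinstance(self.strand_policy, StrandPolicy):
            object.__setattr__(self, "strand_policy", StrandPolicy(self.strand_policy))

    @property
    def zmo_ids(self) -> tuple[str, ...]:
        return self.zmos


def derive_motifset(
    hexamer: str,
    lexicon: MorphemeLexicon,
    strand_policy: StrandPolicy = StrandPolicy.both_strands,
) -> MotifSet:
    """Build a MotifSet whose ZMOs are all composites of the hexamer with any morpheme.

    Composites are deduplicated across morphemes and sorted lexicographically,
    so identical inputs always yield identical ordering.  A lexicon that
    yields no composite produces an empty ZMO set with a warning; scanning
    then degenerates to hexamer-only tracks.
    """
    composites: set[str] = set()
    for morpheme in lexicon.morphemes:
        composites |= build_overlap_composites(hexamer, morpheme, lexicon.min_overlap)
    if not composites:
        logger.warning(
            "morpheme lexicon yields zero composites with hexamer %s; "
            "ZMO set is empty and scanning degenerates to hexamer-only output",
            hexamer,
        )
    return MotifSet(
        hexamer=hexamer,
        zmos=tuple(sorted(composites)),
        strand_policy=strand_policy,
        source=MotifSource.derived_from_morphemes,
    )


def load_motif_config(path: str | Path) -> MotifSet:
    """Load a MotifSet from a YAML config file.

    Recognized keys: ``hexamer`` (default TGCCGC), ``zmos`` (explicit string
    list), ``morphemes`` (lexicon for derivation), ``min_overlap`` (default 1),
    ``strand_policy`` (default both_strands).  An explicit ``zmos`` list takes
    precedence over ``morphemes`` when both are present (with a warning).
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"motif config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"motif config {path} must be a mapping of keys to values")

    hexamer = str(raw.get("hexamer", DEFAULT_HEXAMER))
    policy_name = str(raw.get("strand_policy", StrandPolicy.both_strands.value))
    try:
        policy = StrandPolicy(policy_name)
    except ValueError:
        raise ConfigError(
            f"unknown strand_policy {policy_name!r}; expected one of "
            f"{[p.value for p in StrandPolicy]}"
        ) from None

    zmos = raw.get("zmos")
    morphemes = raw.get("morphemes")
    if zmos is not None and morphemes is not None:
        logger.warning(
            "motif config %s declares both 'zmos' and 'morphemes'; "
            "the explicit zmo list takes precedence",
            path,
        )
    if zmos is not None:
        if not isinstance(zmos, list) or not zmos:
            raise ConfigError("'zmos' must be a nonempty list of DNA strings")
        return MotifSet(
            hexamer=hexamer,
            zmos=tuple(str(z) for z in zmos),
            strand_policy=policy,
            source=MotifSource.explicit_list,
        )
    if morphemes is not None:
        if not isinstance(morphemes, list) or not morphemes:
            raise ConfigError("'morphemes' must be a nonempty list of DNA strings")
        lexicon = MorphemeLexicon(
            morphemes=tuple(str(m) for m in morphemes),
            min_overlap=int(raw.get("min_overlap", 1)),
        )
        return derive_motifset(hexamer, lexicon, policy)
    raise ConfigError(
        f"motif config {path} declares neither 'zmos' nor 'morphemes'; one is required"
    )
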