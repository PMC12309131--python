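"""Independent brute-force oracles used to cross-check the production code.

These deliberately share no code with the package: composites by exhaustive
offset enumeration, matching by per-position slice comparison, window counts
by naive recounting.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq.upper()))


def oracle_composites(hexamer: str, morpheme: str, min_overlap: int) -> set[str]:
    """Try every relative offset, check per-position agreement, take unions."""
    h, m = len(hexamer), len(morpheme)
    out = set()
    for d in range(-(m - 1), h):
        shared = [i for i in range(min(0, d), max(h, d + m)) if 0 <= i < h and d <= i < d + m]
        if len(shared) < min_overlap:
            continue
        if all(hexamer[i] == morpheme[i - d] for i in shared):
            union = "".join(
                hexamer[i] if 0 <= i < h else morpheme[i - d]
                for i in range(min(0, d), max(h, d + m))
            )
            out.add(union)
    return out


def oracle_find(sequence: str, motif: str, both_strands: bool) -> set[tuple[int, str]]:
    """Naive per-position comparator; palindromic +/- duplicates collapse to '+'."""
    hits = set()
    n, m = len(sequence), len(motif)
    for i in range(n - m + 1):
        if sequence[i : i + m] == motif:
            hits.add((i, "+"))
    if both_strands:
        rc = oracle_revcomp(motif)
        if rc != motif:
            for i in range(n - m + 1):
                if sequence[i : i + m] == rc:
                    hits.add((i, "-"))
    return hits


def oracle_window_count(starts: list[int], window_start: int, window_length: int) -> int:
    """Naive recount of occurrence starts inside [window_start, window_start + L)."""
    return sum(window_start <= s < window_start + window_length for s in starts)
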