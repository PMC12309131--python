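from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers_oracles import oracle_composites, oracle_revcomp
from icrscan.motif_model import (
    ConfigError,
    MorphemeLexicon,
    MotifSet,
    MotifSource,
    MotifValidationError,
    build_overlap_composites,
    derive_motifset,
    load_motif_config,
    reverse_complement,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=12)
dna_n = st.text(alphabet="ACGTN", min_size=0, max_size=30)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("TGCCGC", "GCGGCA"), ("", ""), ("ACGT", "ACGT"), ("NNA", "TNN")],
    )
    def test_known_values(self, seq, expected):
        assert reverse_complement(seq) == expected

    @given(dna_n)
    @settings(deadline=None)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq.upper()

    def test_invalid_character_names_position(self):
        with pytest.raises(MotifValidationError, match="position 2"):
            reverse_complement("ACXGT")


class TestOverlapComposites:
    @pytest.mark.parametrize(
        "hexamer,morpheme,min_overlap,expected",
        [
            ("TGCCGC", "CGCA", 2, {"TGCCGCA"}),
            ("TGCCGC", "CGCA", 1, {"TGCCGCA", "TGCCGCGCA"}),
            ("TGCCGC", "AAAA", 1, set()),
            # morpheme contained in the hexamer yields the hexamer itself;
            # the terminal GC..CC agreement at offset 4 adds a second union
            ("TGCCGC", "GCCG", 1, {"TGCCGC", "TGCCGCCG"}),
        ],
    )
    def test_worked_examples(self, hexamer, morpheme, min_overlap, expected):
        assert build_overlap_composites(hexamer, morpheme, min_overlap) == expected

    def test_full_containment_yields_longer_word(self):
        # contained placement (offset +1) contributes the hexamer itself
        assert "TGCCGC" in build_overlap_composites("TGCCGC", "GCCG", 1)

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(300):
            h = "".join(rng.choice(bases, size=rng.integers(4, 9)))
            m = "".join(rng.choice(bases, size=rng.integers(4, 9)))
            mo = int(rng.integers(1, 4))
            assert build_overlap_composites(h, m, mo) == oracle_composites(h, m, mo)

    @given(dna.filter(lambda s: len(s) >= 4), dna.filter(lambda s: len(s) >= 4))
    @settings(deadline=None, max_examples=200)
    def test_composites_contain_both_parents(self, h, m):
        for comp in build_overlap_composites(h, m, 1):
            assert h in comp
            assert m in comp
            if h not in m and m not in h:
                assert len(comp) < len(h) + len(m)

    def test_min_overlap_out_of_range(self):
        with pytest.raises(ValueError):
            build_overlap_composites("TGCCGC", "CGCA", 5)

    def test_invalid_alphabet(self):
        with pytest.raises(MotifValidationError):
            build_overlap_composites("TGCXGC", "CGCA", 1)


class TestDeriveMotifSet:
    def test_single_morpheme(self):
        ms = derive_motifset("TGCCGC", MorphemeLexicon(("CGCA",), min_overlap=2))
        assert ms.zmos == ("TGCCGCA",)
        assert ms.source is MotifSource.derived_from_morphemes

    def test_no_composites_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            ms = derive_motifset("TGCCGC", MorphemeLexicon(("AAAA",)))
        assert ms.zmos == ()
        assert "zero composites" in caplog.text

    def test_duplicate_morphemes_equivalent_to_one(self):
        once = derive_motifset("TGCCGC", MorphemeLexicon(("CGCA",), min_overlap=2))
        twice = derive_motifset("TGCCGC", MorphemeLexicon(("CGCA", "cgca"), min_overlap=2))
        assert once.zmos == twice.zmos

    def test_deterministic_ordering(self):
        lex = MorphemeLexicon(("CGCA", "GCCGCC"), min_overlap=1)
        a = derive_motifset("TGCCGC", lex)
        b = derive_motifset("TGCCGC", lex)
        assert a.zmos == b.zmos == tuple(sorted(a.zmos))

    def test_every_derived_zmo_contains_hexamer(self):
        ms = derive_motifset("TGCCGC", MorphemeLexicon(("GCCGCC", "CGCA"), min_overlap=1))
        assert all("TGCCGC" in z for z in ms.zmos)


class TestMotifSetInvariants:
    def test_case_fold_dedupe(self):
        ms = MotifSet(zmos=("TGCCGCA", "tgccgca", "TGCCGCC"))
        assert ms.zmos == ("TGCCGCA", "TGCCGCC")

    def test_derived_source_requires_hexamer_substring(self):
        with pytest.raises(MotifValidationError):
            MotifSet(zmos=("AAAA",), source=MotifSource.derived_from_morphemes)


class TestLoadMotifConfig:
    def _write(self, tmp_path, text):
        p = tmp_path / "m.yaml"
        p.write_text(text)
        return p

    def test_explicit_list(self, tmp_path):
        ms = load_motif_config(
            self._write(tmp_path, "zmos: [TGCCGCA, TGCCGCC]\n")
        )
        assert ms.zmos == ("TGCCGCA", "TGCCGCC")
        assert ms.source is MotifSource.explicit_list

    def test_case_fold_dedupe(self, tmp_path):
        ms = load_motif_config(self._write(tmp_path, "zmos: [TGCCGCA, tgccgca]\n"))
        assert ms.zmos == ("TGCCGCA",)

    def test_invalid_string_names_position(self, tmp_path):
        with pytest.raises(MotifValidationError, match="position 3"):
            load_motif_config(self._write(tmp_path, "zmos: [TGCXGC]\n"))

    def test_neither_list_nor_lexicon(self, tmp_path):
        with pytest.raises(ConfigError):
            load_motif_config(self._write(tmp_path, "hexamer: TGCCGC\n"))

    def test_missing_file(self, tmp_path):
        with pytest.raises(ConfigError):
            load_motif_config(tmp_path / "nope.yaml")

    def test_explicit_list_precedence_over_lexicon(self, tmp_path, caplog):
        with caplog.at_level("WARNING"):
            ms = load_motif_config(
                self._write(tmp_path, "zmos: [TGCCGCA]\nmorphemes: [GCCGCC]\n")
            )
        assert ms.zmos == ("TGCCGCA",)
        assert "precedence" in caplog.text

    def test_lexicon_derivation(self, tmp_path):
        ms = load_motif_config(
            self._write(tmp_path, "morphemes: [CGCA]\nmin_overlap: 2\n")
        )
        assert ms.zmos == ("TGCCGCA",)
        assert ms.source is MotifSource.derived_from_morphemes
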