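from __future__ import annotations

import pytest
from hypothesis import settings

from icrscan import MotifSet, StrandPolicy

settings.register_profile("repro", deadline=None, derandomize=True)
settings.load_profile("repro")

# Illustrative ZMO set: the hexamer extended by one base on either side.
# Nesting-free (all length 7, no string or reverse complement inside another),
# so planted synthetic truth is exact.
EXAMPLE_ZMOS = ("TGCCGCA", "TGCCGCC", "TGCCGCT", "ATGCCGC", "CTGCCGC", "GTGCCGC")


@pytest.fixture(scope="session")
def motifset() -> MotifSet:
    return MotifSet(hexamer="TGCCGC", zmos=EXAMPLE_ZMOS)


@pytest.fixture(scope="session")
def motifset_forward() -> MotifSet:
    return MotifSet(hexamer="TGCCGC", zmos=EXAMPLE_ZMOS,
                    strand_policy=StrandPolicy.forward_only)


@pytest.fixture
def motif_config_path(tmp_path):
    path = tmp_path / "motifs.yaml"
    path.write_text(
        "hexamer: TGCCGC\nstrand_policy: both_strands\nzmos:\n"
        + "".join(f"  - {z}\n" for z in EXAMPLE_ZMOS)
    )
    return path
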