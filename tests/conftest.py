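import numpy as np
import pytest

from polyq_ens import (
    HELIX_OFFSET,
    NUCLEI,
    STRAND_OFFSET,
    RandomCoilTable,
    ShiftTable,
)


@pytest.fixture(scope="session")
def rc() -> RandomCoilTable:
    return RandomCoilTable.default()


def offset_shift_table(
    sequence: str,
    rc: RandomCoilTable,
    offsets: dict[str, float] | None = None,
    scale: float = 1.0,
    nuclei: tuple[str, ...] = NUCLEI,
) -> ShiftTable:
    """Random-coil values plus ``scale`` times a per-nucleus offset."""
    offsets = offsets or {}
    shifts = {}
    for i, aa in enumerate(sequence, start=1):
        for nuc in nuclei:
            if rc.has(aa, nuc):
                shifts[(i, nuc)] = rc.lookup(aa, nuc) + scale * offsets.get(
                    nuc, 0.0
                )
    return ShiftTable(sequence=sequence, shifts=shifts)


@pytest.fixture(scope="session")
def helix_table(rc) -> ShiftTable:
    return offset_shift_table("AQ" * 10, rc, HELIX_OFFSET)


@pytest.fixture(scope="session")
def strand_table(rc) -> ShiftTable:
    return offset_shift_table("AQ" * 10, rc, STRAND_OFFSET)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
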