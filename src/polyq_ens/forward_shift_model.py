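"""Simplified forward model: backbone chemical shifts from a conformation.

The predictor is deliberately linear in the secondary-structure state:

    delta_pred(i, nucleus) = delta_rc(aa_i, nucleus) + s(ss_i) * offset(nucleus)

where ``offset`` is the fully-formed helix (ss = H) or extended-strand
(ss = E) average secondary shift and s(C) = 0, so a fully coil conformer
predicts exactly random-coil values. Because ensemble-averaged predicted
shifts are then linear in the conformer weights, the reweighting problem
keeps the same structure it has with any precomputed prediction matrix;
an externally predicted matrix can be dropped in through the CSV adapter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .conformer_model import Conformer
from .refdata import HELIX_OFFSET, NUCLEI, STRAND_OFFSET
from .shift_data import RandomCoilTable, ShiftTable

__all__ = ["ShiftMatrix", "predict_shifts", "pool_matrix", "supported_observables"]


@dataclass
class ShiftMatrix:
    """Predicted shifts for a pool: rows = conformers, columns = observables.

    ``observables`` is the fixed column order as (residue index, aa, nucleus).
    """

    observables: list[tuple[int, str, str]]
    values: np.ndarray  # shape (K, J), ppm

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.observables):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.observables)} observables"
            )

    @property
    def n_conformers(self) -> int:
        return self.values.shape[0]

    def column_index(self) -> dict[tuple[int, str], int]:
        return {(idx, nuc): j for j, (idx, _aa, nuc) in enumerate(self.observables)}

    def to_csv(self, path: str | Path) -> None:
        columns = [f"{idx}:{aa}:{nuc}" for idx, aa, nuc in self.observables]
        frame = pd.DataFrame(self.values, columns=columns)
        frame.insert(0, "conformer", np.arange(1, self.n_conformers + 1))
        frame.to_csv(path, index=False, float_format="%.4f")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ShiftMatrix":
        frame = pd.read_csv(path)
        columns = [c for c in frame.columns if c != "conformer"]
        observables = []
        for name in columns:
            idx, aa, nuc = name.split(":")
            observables.append((int(idx), aa, nuc))
        return cls(observables=observables, values=frame[columns].to_numpy())


def supported_observables(
    sequence: str, rc: RandomCoilTable, nuclei: tuple[str, ...] = NUCLEI
) -> list[tuple[int, str, str]]:
    """All (index, aa, nucleus) the model can predict for a sequence.

    Excludes combinations without a random-coil reference (Gly CB, Pro H).
    """
    out = []
    for i, aa in enumerate(sequence, start=1):
        for nuc in nuclei:
            if rc.has(aa, nuc):
                out.append((i, aa, nuc))
    return out


def predict_shifts(
    conformer: Conformer,
    rc: RandomCoilTable,
    nuclei: tuple[str, ...] = NUCLEI,
    helix_offsets: dict[str, float] | None = None,
    strand_offsets: dict[str, float] | None = None,
) -> ShiftTable:
    """Predict backbone shifts of one conformer (SS assigned on demand)."""
    helix = dict(HELIX_OFFSET if helix_offsets is None else helix_offsets)
    strand = dict(STRAND_OFFSET if strand_offsets is None else strand_offsets)
    ss = conformer.ss
    shifts: dict[tuple[int, str], float] = {}
    seq = conformer.sequence
    for i, aa in enumerate(seq, start=1):
        state = ss[i - 1]
        for nuc in nuclei:
            if not rc.has(aa, nuc):
                continue
            next_is_pro = i < len(seq) and seq[i] == "P"
            value = rc.lookup(aa, nuc, next_is_pro=next_is_pro)
            if state == "H":
                value += helix.get(nuc, 0.0)
            elif state == "E":
                value += strand.get(nuc, 0.0)
            shifts[(i, nuc)] = value
    return ShiftTable(sequence=seq, shifts=shifts, label=conformer.source)


def pool_matrix(
    pool: list[Conformer],
    observables: list[tuple[int, str, str]],
    rc: RandomCoilTable,
    **predict_kwargs,
) -> ShiftMatrix:
    """Stack per-conformer predictions into the pool's prediction matrix."""
    if not pool:
        raise ValueError("empty pool")
    sequence = pool[0].sequence
    supported = set()
    nuclei = tuple(dict.fromkeys(nuc for _i, _aa, nuc in observables))
    for obs in supported_observables(sequence, rc, nuclei):
        supported.add(obs)
    for obs in observables:
        if obs not in supported:
            raise ValueError(f"unsupported observable {obs[0]}:{obs[1]}:{obs[2]}")
    values = np.zeros((len(pool), len(observables)))
    for k, conf in enumerate(pool):
        predicted = predict_shifts(conf, rc, nuclei=nuclei, **predict_kwargs)
        for j, (idx, _aa, nuc) in enumerate(observables):
            values[k, j] = predicted.shifts[(idx, nuc)]
    return ShiftMatrix(observables=observables, values=values)
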