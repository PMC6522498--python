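"""Secondary chemical shifts and SSP helix/strand propensity scores.

The secondary shift of a nucleus is the observed (or predicted) shift minus
the residue-type random-coil value, Δδ = δ_obs − δ_rc. Positive ΔδCα and
negative ΔδCβ indicate helical population, so the per-residue difference
(ΔCα − ΔCβ) is a sensitive indicator of residual helicity in disordered
chains.

The SSP score condenses all available nuclei of a sliding window into one
dimensionless propensity per residue: each secondary shift is normalised by
the average secondary shift of a fully-formed helix (when it deviates in the
helical direction) or a fully-formed extended strand (when it deviates the
other way), the normalised values are averaged with per-nucleus sensitivity
weights, and window members inconsistent with the window consensus (beyond
one weighted standard deviation) are excluded. A residue in a well-formed
helix thus scores +1, a well-formed strand −1 and a random coil 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .refdata import HELIX_OFFSET, NUCLEI, NUCLEUS_WEIGHT, STRAND_OFFSET
from .shift_data import RandomCoilTable, ShiftTable

__all__ = [
    "SecondaryShiftProfile",
    "SSPProfile",
    "secondary_shifts",
    "ssp_score",
    "call_segments",
]


@dataclass
class SecondaryShiftProfile:
    """Δδ per (residue, nucleus) plus the (ΔCα − ΔCβ) indicator."""

    sequence: str
    delta: dict[tuple[int, str], float]
    label: str = ""

    @property
    def dcacb(self) -> dict[int, float]:
        """(ΔCα − ΔCβ) per residue; present only where both carbons are."""
        out: dict[int, float] = {}
        for idx in range(1, len(self.sequence) + 1):
            ca = self.delta.get((idx, "CA"))
            cb = self.delta.get((idx, "CB"))
            if ca is not None and cb is not None:
                out[idx] = ca - cb
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        dcacb = self.dcacb
        for idx in range(1, len(self.sequence) + 1):
            row: dict[str, object] = {"index": idx, "aa": self.sequence[idx - 1]}
            for nuc in NUCLEI:
                row[f"d{nuc}"] = self.delta.get((idx, nuc), math.nan)
            row["dCaCb"] = dcacb.get(idx, math.nan)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class SSPProfile:
    """Per-residue helix(+)/strand(−) propensity; absent where coverage fails."""

    sequence: str
    scores: dict[int, float]
    window: int
    nuclei: tuple[str, ...]
    label: str = ""
    params: dict = field(default_factory=dict)

    def as_array(self) -> np.ndarray:
        """Scores as an array with NaN where no score is defined."""
        out = np.full(len(self.sequence), np.nan)
        for idx, score in self.scores.items():
            out[idx - 1] = score
        return out


def secondary_shifts(
    shifts: ShiftTable, rc: RandomCoilTable
) -> SecondaryShiftProfile:
    """Δδ = observed − random-coil for every entry with a reference value."""
    if not shifts.shifts:
        raise ValueError("cannot compute secondary shifts of an empty table")
    seq = shifts.sequence
    delta: dict[tuple[int, str], float] = {}
    for (idx, nuc), value in shifts.shifts.items():
        aa = seq[idx - 1]
        if not rc.has(aa, nuc):
            continue
        next_is_pro = idx < len(seq) and seq[idx] == "P"
        delta[(idx, nuc)] = value - rc.lookup(aa, nuc, next_is_pro=next_is_pro)
    return SecondaryShiftProfile(sequence=seq, delta=delta, label=shifts.label)


def _normalise(delta: float, helix: float, strand: float) -> float:
    """Map Δδ onto the −1 (strand) … +1 (helix) propensity axis."""
    if delta == 0.0 or helix == 0.0 or strand == 0.0:
        return 0.0
    if delta * helix > 0:
        return delta / helix
    return -delta / strand


def ssp_score(
    profile: SecondaryShiftProfile,
    window: int = 5,
    nuclei: tuple[str, ...] = NUCLEI,
    helix_offsets: dict[str, float] | None = None,
    strand_offsets: dict[str, float] | None = None,
    nucleus_weights: dict[str, float] | None = None,
    outlier_sd: float = 1.0,
) -> SSPProfile:
    """Windowed, nucleus-weighted SSP propensity per residue.

    Parameters
    ----------
    window:
        Odd sliding-window length in residues (default 5).
    nuclei:
        Nuclei entering the average; carbons dominate by default weighting.
    outlier_sd:
        Window members deviating from the weighted window mean by more than
        ``outlier_sd`` weighted standard deviations are excluded and the mean
        recomputed once.

    A score is reported only where at least three window residues — and at
    least half of the residues the window covers — contribute a usable
    nucleus.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    helix = dict(HELIX_OFFSET if helix_offsets is None else helix_offsets)
    strand = dict(STRAND_OFFSET if strand_offsets is None else strand_offsets)
    weights = dict(NUCLEUS_WEIGHT if nucleus_weights is None else nucleus_weights)
    use = tuple(n for n in nuclei if n in helix and n in strand)

    n = len(profile.sequence)
    usable: dict[int, list[tuple[float, float]]] = {}
    for idx in range(1, n + 1):
        items = []
        for nuc in use:
            d = profile.delta.get((idx, nuc))
            if d is not None:
                items.append((_normalise(d, helix[nuc], strand[nuc]),
                              weights.get(nuc, 1.0)))
        if items:
            usable[idx] = items
    if not usable:
        raise ValueError("no usable nuclei anywhere in the profile")

    half = window // 2
    scores: dict[int, float] = {}
    for idx in range(1, n + 1):
        positions = range(max(1, idx - half), min(n, idx + half) + 1)
        contributing = [p for p in positions if p in usable]
        if len(contributing) < 3 or 2 * len(contributing) < len(positions):
            continue
        x = np.array([v for p in contributing for v, _ in usable[p]])
        w = np.array([wt for p in contributing for _, wt in usable[p]])
        mean = float(np.average(x, weights=w))
        sd = float(math.sqrt(np.average((x - mean) ** 2, weights=w)))
        if sd > 0:
            keep = np.abs(x - mean) <= outlier_sd * sd
            if keep.any():
                mean = float(np.average(x[keep], weights=w[keep]))
        scores[idx] = mean

    return SSPProfile(
        sequence=profile.sequence,
        scores=scores,
        window=window,
        nuclei=use,
        label=profile.label,
        params={
            "outlier_sd": outlier_sd,
            "nucleus_weights": {n: weights.get(n, 1.0) for n in use},
        },
    )


def call_segments(
    ssp: SSPProfile, threshold: float, min_length: int = 3
) -> list[tuple[int, int, float]]:
    """Maximal runs of >= ``min_length`` consecutive residues scoring
    >= ``threshold``, as (start, end, mean_score) with inclusive 1-based ends.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    segments: list[tuple[int, int, float]] = []
    run: list[int] = []
    indices = range(1, len(ssp.sequence) + 1)
    for idx in list(indices) + [None]:  # sentinel flushes the final run
        score = ssp.scores.get(idx) if idx is not None else None
        if score is not None and score >= threshold:
            run.append(idx)
        else:
            if len(run) >= min_length:
                mean = sum(ssp.scores[i] for i in run) / len(run)
                segments.append((run[0], run[-1], mean))
            run = []
    return segments
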