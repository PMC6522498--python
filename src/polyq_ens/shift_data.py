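"""Chemical-shift tables and random-coil references.

The central container is :class:`ShiftTable`: per-residue, per-nucleus
backbone chemical shifts (ppm) together with the one-letter sequence they
belong to. Tables can be read from NMR-STAR 2.1/3.1 assigned-chemical-shift
loops or from a simple ``index,aa,nucleus,ppm`` CSV, and written back to CSV.

Residues are numbered 1-based in the normal-polyQ (10Q) frame; expanded
variants carry extra glutamines as fractional insertion codes (39.1, 39.2, …)
handled by the synthetic-data and comparison layers.
"""

from __future__ import annotations

import logging
import math
import shlex
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .refdata import (
    AMINO_ACIDS,
    NUCLEI,
    PRO_SUCCESSOR_CORRECTION,
    RANDOM_COIL,
    RANDOM_COIL_PROVENANCE,
    THREE_TO_ONE,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueId",
    "ShiftTable",
    "RandomCoilTable",
    "ShiftFormatError",
    "ShiftDataError",
    "read_star",
    "read_csv_shifts",
    "write_csv_shifts",
    "random_coil_lookup",
]


class ShiftFormatError(ValueError):
    """A file could not be parsed as the expected shift format."""


class ShiftDataError(ValueError):
    """Parsed data violates a shift-table invariant."""


@dataclass(frozen=True, order=True)
class ResidueId:
    """1-based position in the 10Q-numbered sequence plus one-letter code."""

    index: int
    aa: str

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ShiftDataError(f"residue index must be >= 1, got {self.index}")
        if self.aa not in AMINO_ACIDS:
            raise ShiftDataError(f"unknown amino-acid code {self.aa!r}")


@dataclass
class ShiftTable:
    """Backbone chemical shifts (ppm) keyed by (residue index, nucleus)."""

    sequence: str
    shifts: dict[tuple[int, str], float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for (idx, nuc), value in self.shifts.items():
            if not 1 <= idx <= n:
                raise ShiftDataError(
                    f"residue index {idx} outside sequence of length {n}"
                )
            if nuc not in NUCLEI:
                raise ShiftDataError(f"unsupported nucleus {nuc!r} at residue {idx}")
            if self.sequence[idx - 1] == "G" and nuc == "CB":
                raise ShiftDataError(f"Gly {idx} cannot carry a CB shift")
            if not math.isfinite(value):
                raise ShiftDataError(f"non-finite shift at residue {idx} {nuc}")

    def __len__(self) -> int:
        return len(self.shifts)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ShiftTable):
            return NotImplemented
        return (
            self.sequence == other.sequence
            and self.shifts.keys() == other.shifts.keys()
            and all(
                math.isclose(v, other.shifts[k], abs_tol=5e-4)
                for k, v in self.shifts.items()
            )
        )

    def aa(self, index: int) -> str:
        return self.sequence[index - 1]

    def residue(self, index: int) -> ResidueId:
        return ResidueId(index, self.aa(index))

    def get(self, index: int, nucleus: str) -> float | None:
        return self.shifts.get((index, nucleus))

    def observables(self) -> list[tuple[int, str]]:
        """Sorted (index, nucleus) keys, nucleus order as in NUCLEI."""
        order = {n: i for i, n in enumerate(NUCLEI)}
        return sorted(self.shifts, key=lambda k: (k[0], order[k[1]]))

    def restrict(self, nuclei: Iterable[str]) -> "ShiftTable":
        keep = set(nuclei)
        return replace(
            self,
            shifts={k: v for k, v in self.shifts.items() if k[1] in keep},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"index": i, "aa": self.aa(i), "nucleus": n, "ppm": v}
            for (i, n), v in sorted(self.shifts.items())
        ]
        return pd.DataFrame(rows, columns=["index", "aa", "nucleus", "ppm"])


@dataclass(frozen=True)
class RandomCoilTable:
    """Map (one-letter aa, nucleus) -> random-coil shift (ppm)."""

    values: Mapping[tuple[str, str], float]
    provenance: str
    pro_successor_correction: bool = False

    @classmethod
    def default(cls, pro_successor_correction: bool = False) -> "RandomCoilTable":
        values = {
            (aa, nuc): ppm
            for aa, per_nuc in RANDOM_COIL.items()
            for nuc, ppm in per_nuc.items()
        }
        return cls(
            values=values,
            provenance=RANDOM_COIL_PROVENANCE,
            pro_successor_correction=pro_successor_correction,
        )

    def lookup(self, aa: str, nucleus: str, next_is_pro: bool = False) -> float:
        if aa not in AMINO_ACIDS:
            raise ShiftDataError(f"unknown amino-acid code {aa!r}")
        if nucleus not in NUCLEI:
            raise ShiftDataError(f"unsupported nucleus {nucleus!r}")
        try:
            value = self.values[(aa, nucleus)]
        except KeyError:
            raise ShiftDataError(
                f"no random-coil value for ({aa}, {nucleus})"
            ) from None
        if next_is_pro and self.pro_successor_correction:
            value += PRO_SUCCESSOR_CORRECTION.get(nucleus, 0.0)
        return value

    def has(self, aa: str, nucleus: str) -> bool:
        return (aa, nucleus) in self.values


def random_coil_lookup(
    table: RandomCoilTable, aa: str, nucleus: str, next_is_pro: bool = False
) -> float:
    """Random-coil shift for a residue type; errors on e.g. (G, CB)."""
    return table.lookup(aa, nucleus, next_is_pro=next_is_pro)


# --------------------------------------------------------------------------
# NMR-STAR input
# --------------------------------------------------------------------------

# column names per NMR-STAR dialect, lower-cased
_STAR_COLUMNS = {
    "3.1": {
        "seq": ("_atom_chem_shift.seq_id", "_atom_chem_shift.comp_index_id"),
        "comp": ("_atom_chem_shift.comp_id",),
        "atom": ("_atom_chem_shift.atom_id",),
        "val": ("_atom_chem_shift.val",),
    },
    "2.1": {
        "seq": ("_residue_seq_code",),
        "comp": ("_residue_label",),
        "atom": ("_atom_name",),
        "val": ("_chem_shift_value",),
    },
}

# atom names folded into the supported nucleus set
_ATOM_ALIASES = {
    "H": "H", "HN": "H", "N": "N", "CA": "CA", "CB": "CB",
    "HA": "HA", "HA2": "HA", "HA3": "HA",
}


def _iter_star_loops(text: str) -> Iterator[tuple[list[str], list[list[str]]]]:
    """Yield (tags, rows) for each loop_ in a STAR file, whitespace-tokenised."""
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        if lines[i].strip().lower() == "loop_":
            i += 1
            tags: list[str] = []
            while i < len(lines) and lines[i].strip().startswith("_"):
                tags.append(lines[i].strip().split()[0].lower())
                i += 1
            rows: list[list[str]] = []
            tokens: list[str] = []
            while i < len(lines):
                stripped = lines[i].strip()
                if stripped.lower() in ("stop_", "loop_") or stripped.startswith(
                    ("save_", "data_")
                ):
                    break
                if stripped and not stripped.startswith("#"):
                    tokens.extend(shlex.split(stripped))
                i += 1
            for start in range(0, len(tokens) - len(tags) + 1, len(tags)):
                rows.append(tokens[start : start + len(tags)])
            yield tags, rows
        i += 1


def read_star(path: str | Path, label: str = "") -> ShiftTable:
    """Read a ShiftTable from an NMR-STAR 2.1 or 3.1 chemical-shift loop.

    Nuclei outside {H, N, HA, CA, CB} are dropped (with a logged count);
    glycine HA2/HA3 are averaged into a single HA value. Duplicate
    (residue, nucleus) entries with differing values are a data error.
    """
    text = Path(path).read_text()
    for tags, rows in _iter_star_loops(text):
        for dialect, cols in _STAR_COLUMNS.items():
            try:
                idx = {
                    key: next(tags.index(t) for t in names if t in tags)
                    for key, names in cols.items()
                }
            except StopIteration:
                continue
            return _table_from_star_rows(rows, idx, dialect, label)
    raise ShiftFormatError(f"{path}: no assigned chemical-shift loop found")


def _table_from_star_rows(
    rows: list[list[str]], idx: dict[str, int], dialect: str, label: str
) -> ShiftTable:
    collected: dict[tuple[int, str], list[float]] = {}
    residues: dict[int, str] = {}
    dropped = 0
    for row in rows:
        seq = int(row[idx["seq"]])
        comp = row[idx["comp"]].upper()
        aa = THREE_TO_ONE.get(comp, comp if comp in AMINO_ACIDS else None)
        if aa is None:
            raise ShiftFormatError(f"unknown residue type {comp!r} at {seq}")
        atom = row[idx["atom"]].upper()
        value = float(row[idx["val"]])
        nucleus = _ATOM_ALIASES.get(atom)
        if nucleus is None:
            dropped += 1
            continue
        prev = residues.setdefault(seq, aa)
        if prev != aa:
            raise ShiftDataError(
                f"residue {seq} listed as both {prev} and {aa}"
            )
        collected.setdefault((seq, nucleus), []).append(value)
    if dropped:
        logger.info("read_star: dropped %d unsupported-nucleus rows", dropped)

    shifts: dict[tuple[int, str], float] = {}
    for (seq, nucleus), values in collected.items():
        if len(values) > 1 and nucleus != "HA":
            if max(values) - min(values) > 1e-6:
                raise ShiftDataError(
                    f"duplicate shift for residue {seq} {nucleus} "
                    f"with differing values {values}"
                )
        # Gly HA2/HA3 (and exact duplicates) are averaged
        shifts[(seq, nucleus)] = sum(values) / len(values)

    n = max(residues) if residues else 0
    sequence = "".join(residues.get(i, "G") for i in range(1, n + 1))
    return ShiftTable(sequence=sequence, shifts=shifts, label=label)


# --------------------------------------------------------------------------
# CSV round trip
# --------------------------------------------------------------------------

def read_csv_shifts(path: str | Path, label: str = "") -> ShiftTable:
    """Read a ShiftTable from a CSV with columns ``index,aa,nucleus,ppm``."""
    try:
        frame = pd.read_csv(path, dtype={"aa": str, "nucleus": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ShiftFormatError(f"{path}: {exc}") from exc
    required = {"index", "aa", "nucleus", "ppm"}
    if not required.issubset(frame.columns):
        raise ShiftFormatError(
            f"{path}: missing columns {sorted(required - set(frame.columns))}"
        )
    shifts: dict[tuple[int, str], float] = {}
    residues: dict[int, str] = {}
    columns = zip(frame["index"], frame["aa"], frame["nucleus"], frame["ppm"])
    for line, (raw_idx, aa, nucleus, raw_ppm) in enumerate(columns, start=2):
        try:
            idx = int(raw_idx)
            ppm = float(raw_ppm)
        except (TypeError, ValueError) as exc:
            raise ShiftFormatError(f"{path}:{line}: malformed row ({exc})") from exc
        if not math.isfinite(ppm):
            raise ShiftFormatError(f"{path}:{line}: non-finite ppm")
        residues.setdefault(idx, str(aa))
        shifts[(idx, str(nucleus))] = ppm
    n = max(residues) if residues else 0
    sequence = "".join(residues.get(i, "G") for i in range(1, n + 1))
    return ShiftTable(sequence=sequence, shifts=shifts, label=label)


def write_csv_shifts(table: ShiftTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, index=False, float_format="%.3f")
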