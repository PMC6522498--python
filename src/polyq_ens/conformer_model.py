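"""Backbone conformers: geometry from dihedrals and secondary structure.

Pool members are represented by their backbone (N, CA, C, O) coordinates,
built from per-residue (phi, psi) dihedrals with ideal bond lengths and
angles and trans peptide bonds (omega = 180 deg). Secondary structure is
assigned from dihedral basins — a deliberately simple, declared stand-in for
H-bond-based assignment: a residue is helical (H) when (phi, psi) falls in
the alpha basin for at least 3 consecutive residues, extended (E) in the
beta basin for at least 2, and coil (C) otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .refdata import ONE_TO_THREE, THREE_TO_ONE

__all__ = [
    "Conformer",
    "SSAssignment",
    "build_chain",
    "assign_ss",
    "helix_content",
    "write_pool_pdb",
    "read_pool_pdb",
    "write_dihedral_csv",
    "read_dihedral_csv",
    "IDEAL_GEOMETRY",
    "HELIX_BASIN",
    "EXTENDED_BASIN",
]

#: Ideal backbone geometry (lengths in Angstrom, angles in degrees).
IDEAL_GEOMETRY = {
    "N-CA": 1.46,
    "CA-C": 1.52,
    "C-N": 1.33,
    "C-O": 1.23,
    "N-CA-C": 111.0,
    "CA-C-N": 116.2,
    "C-N-CA": 121.7,
    "CA-C-O": 120.5,
    "omega": 180.0,
}

#: Dihedral basins: ((phi_min, phi_max), (psi_min, psi_max)), degrees.
HELIX_BASIN = ((-100.0, -30.0), (-80.0, 0.0))
EXTENDED_BASIN = ((-180.0, -90.0), (90.0, 180.0))

#: Minimum consecutive-residue run lengths for H and E assignment.
MIN_RUN = {"H": 3, "E": 2}

SSAssignment = str  # string over {H, E, C}, one char per residue

_BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Conformer:
    """Backbone conformation: sequence, dihedrals (deg) and coordinates (A).

    ``phi[0]`` and ``psi[-1]`` are undefined (NaN). ``coords`` has shape
    (n_residues, 4, 3) over atoms (N, CA, C, O).
    """

    sequence: str
    phi: np.ndarray
    psi: np.ndarray
    coords: np.ndarray | None = None
    source: str = ""
    _ss: str | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        n = len(self.sequence)
        if len(self.phi) != n or len(self.psi) != n:
            raise ValueError(
                f"sequence length {n} does not match dihedral arrays "
                f"({len(self.phi)}, {len(self.psi)})"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ss(self) -> SSAssignment:
        if self._ss is None:
            self._ss = assign_ss(self)
        return self._ss


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """Position d with |c-d| = bond, angle(b,c,d) and dihedral(a,b,c,d)."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_chain(
    sequence: str,
    dihedrals: np.ndarray | list[tuple[float, float]],
    source: str = "",
) -> Conformer:
    """Build backbone coordinates from (phi, psi) with ideal geometry.

    ``dihedrals`` is an (n, 2) array of (phi, psi) in degrees; phi of the
    first and psi of the last residue are ignored (NaN accepted). The build
    is deterministic: identical inputs give bitwise-identical coordinates.
    """
    dih = np.asarray(dihedrals, dtype=float)
    n = len(sequence)
    if dih.shape != (n, 2):
        raise ValueError(
            f"need one (phi, psi) pair per residue: expected {(n, 2)}, "
            f"got {dih.shape}"
        )
    phi = dih[:, 0].copy()
    psi = dih[:, 1].copy()
    phi[0] = np.nan
    psi[-1] = np.nan
    if np.isnan(phi[1:]).any() or np.isnan(psi[:-1]).any():
        raise ValueError("interior dihedrals must be finite")

    g = IDEAL_GEOMETRY
    coords = np.zeros((n, 4, 3))
    atom = {a: i for i, a in enumerate(_BACKBONE_ATOMS)}

    # first residue in the xy-plane
    coords[0, atom["N"]] = (0.0, 0.0, 0.0)
    coords[0, atom["CA"]] = (g["N-CA"], 0.0, 0.0)
    theta = math.radians(180.0 - g["N-CA-C"])
    coords[0, atom["C"]] = coords[0, atom["CA"]] + g["CA-C"] * np.array(
        [math.cos(theta), math.sin(theta), 0.0]
    )

    for i in range(n - 1):
        n_i, ca_i, c_i = (coords[i, atom[a]] for a in ("N", "CA", "C"))
        n_next = _place_atom(n_i, ca_i, c_i, g["C-N"], g["CA-C-N"], psi[i])
        ca_next = _place_atom(ca_i, c_i, n_next, g["N-CA"], g["C-N-CA"], g["omega"])
        c_next = _place_atom(c_i, n_next, ca_next, g["CA-C"], g["N-CA-C"], phi[i + 1])
        coords[i + 1, atom["N"]] = n_next
        coords[i + 1, atom["CA"]] = ca_next
        coords[i + 1, atom["C"]] = c_next
        # carbonyl O anti to the next amide N
        coords[i, atom["O"]] = _place_atom(
            n_next, ca_i, c_i, g["C-O"], g["CA-C-O"], 180.0
        )
    # last carbonyl O: psi undefined, orientation fixed by convention
    n_l, ca_l, c_l = (coords[-1, atom[a]] for a in ("N", "CA", "C"))
    coords[-1, atom["O"]] = _place_atom(n_l, ca_l, c_l, g["C-O"], g["CA-C-O"], 0.0)

    return Conformer(sequence=sequence, phi=phi, psi=psi, coords=coords,
                     source=source)


def _in_basin(phi: float, psi: float, basin) -> bool:
    (phi_lo, phi_hi), (psi_lo, psi_hi) = basin
    return phi_lo <= phi <= phi_hi and psi_lo <= psi <= psi_hi


def assign_ss(conformer: Conformer) -> SSAssignment:
    """Dihedral-basin secondary structure: H / E / C per residue.

    Residues lacking a dihedral (chain termini) are coil.
    """
    n = len(conformer)
    in_h = np.zeros(n, dtype=bool)
    in_e = np.zeros(n, dtype=bool)
    for i in range(n):
        phi, psi = conformer.phi[i], conformer.psi[i]
        if math.isnan(phi) or math.isnan(psi):
            continue
        in_h[i] = _in_basin(phi, psi, HELIX_BASIN)
        in_e[i] = _in_basin(phi, psi, EXTENDED_BASIN)

    ss = ["C"] * n
    for label, mask in (("H", in_h), ("E", in_e)):
        i = 0
        while i < n:
            if mask[i]:
                j = i
                while j < n and mask[j]:
                    j += 1
                if j - i >= MIN_RUN[label]:
                    for k in range(i, j):
                        ss[k] = label
                i = j
            else:
                i += 1
    return "".join(ss)


def helix_content(ss: SSAssignment, region: tuple[int, int]) -> float:
    """Fraction of H in an inclusive 1-based (start, end) region."""
    start, end = region
    if start < 1 or end > len(ss) or end < start:
        raise ValueError(f"empty or out-of-range region {region}")
    segment = ss[start - 1 : end]
    return segment.count("H") / len(segment)


# --------------------------------------------------------------------------
# Pool I/O: multi-model PDB (backbone only) and dihedral CSV
# --------------------------------------------------------------------------

def write_pool_pdb(pool: list[Conformer], path: str | Path) -> None:
    """Write a conformer pool as a multi-model backbone PDB (chain A)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if not pool:
        raise ValueError("empty pool")
    template = pool[0]
    n = len(template)
    n_atoms = n * len(_BACKBONE_ATOMS)
    arrays = []
    for conf in pool:
        if conf.sequence != template.sequence:
            raise ValueError("pool members must share one sequence")
        if conf.coords is None:
            raise ValueError("conformer lacks coordinates; run build_chain")
        array = struc.AtomArray(n_atoms)
        array.coord = conf.coords.reshape(n_atoms, 3)
        array.chain_id = np.full(n_atoms, "A")
        array.res_id = np.repeat(np.arange(1, n + 1), len(_BACKBONE_ATOMS))
        array.res_name = np.repeat(
            [ONE_TO_THREE[aa] for aa in conf.sequence], len(_BACKBONE_ATOMS)
        )
        array.atom_name = np.tile(np.array(_BACKBONE_ATOMS), n)
        array.element = np.tile(np.array(["N", "C", "C", "O"]), n)
        arrays.append(array)
    pdb = PDBFile()
    pdb.set_structure(struc.stack(arrays))
    pdb.write(str(path))


def read_pool_pdb(path: str | Path) -> list[Conformer]:
    """Read a multi-model backbone PDB into a conformer pool.

    Dihedrals are recomputed from the coordinates.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    pool: list[Conformer] = []
    for model in stack:
        backbone = model[np.isin(model.atom_name, _BACKBONE_ATOMS)]
        res_ids = np.unique(backbone.res_id)
        n = len(res_ids)
        sequence = "".join(
            THREE_TO_ONE[backbone.res_name[backbone.res_id == rid][0]]
            for rid in res_ids
        )
        coords = np.zeros((n, 4, 3))
        for r, rid in enumerate(res_ids):
            res = backbone[backbone.res_id == rid]
            for a, name in enumerate(_BACKBONE_ATOMS):
                coords[r, a] = res.coord[res.atom_name == name][0]
        phi, psi, _omega = struc.dihedral_backbone(model)
        pool.append(
            Conformer(
                sequence=sequence,
                phi=np.degrees(phi),
                psi=np.degrees(psi),
                coords=coords,
            )
        )
    return pool


def write_dihedral_csv(pool: list[Conformer], path: str | Path) -> None:
    rows = [
        {"model": k + 1, "index": i + 1,
         "phi": conf.phi[i], "psi": conf.psi[i]}
        for k, conf in enumerate(pool)
        for i in range(len(conf))
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.3f")


def read_dihedral_csv(
    path: str | Path, sequence: str, build: bool = True
) -> list[Conformer]:
    """Read ``model,index,phi,psi`` rows into a pool over one sequence."""
    frame = pd.read_csv(path)
    pool = []
    for _model, group in frame.groupby("model", sort=True):
        group = group.sort_values("index")
        dih = np.column_stack([group["phi"].to_numpy(), group["psi"].to_numpy()])
        if build:
            pool.append(build_chain(sequence, dih))
        else:
            pool.append(Conformer(sequence, dih[:, 0], dih[:, 1]))
    return pool
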