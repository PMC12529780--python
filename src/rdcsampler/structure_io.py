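"""PDB structures, proton construction, and RDC bond vectors.

Reads a protein structure from PDB, resolves alternate conformations by
occupancy, constructs the amide H^N and virtual H^alpha hydrogens that X-ray
structures lack, and extracts the unit internuclear vectors for the four
backbone RDC types.  Also reads/writes the plain TSV target-RDC tables.

Coordinates are stored in nm throughout (PDB angstroms are converted on
read and back on write).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gemmi
import numpy as np
import pandas as pd

from rdcsampler.core_rdc import BOND_CLASSES, RDCTarget

__all__ = [
    "Residue",
    "Structure",
    "RDCVector",
    "read_pdb",
    "write_pdb",
    "build_amide_protons",
    "build_virtual_ha",
    "extract_rdc_vectors",
    "read_rdc_table",
    "write_rdc_table",
]

B_NH = 0.1  # nm, rigid N-H bond
B_CAHA = 0.109  # nm, rigid CA-HA bond
_TET_COS = -1.0 / 3.0  # cos of the tetrahedral angle


@dataclass
class Residue:
    seqid: int
    name: str
    atoms: Dict[str, np.ndarray] = field(default_factory=dict)
    icode: str = ""

    def __contains__(self, atom: str) -> bool:
        return atom in self.atoms

    def __getitem__(self, atom: str) -> np.ndarray:
        return self.atoms[atom]


@dataclass
class Structure:
    """An ordered single-chain protein backbone in nm coordinates."""

    residues: List[Residue]
    name: str = ""
    chain: str = "A"

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, seqid: int) -> Residue:
        for res in self.residues:
            if res.seqid == seqid:
                return res
        raise KeyError(f"no residue {seqid} in structure {self.name!r}")

    def index_of(self, seqid: int) -> int:
        for i, res in enumerate(self.residues):
            if res.seqid == seqid:
                return i
        raise KeyError(f"no residue {seqid} in structure {self.name!r}")

    def copy(self) -> "Structure":
        return Structure(
            [Residue(r.seqid, r.name, {k: v.copy() for k, v in r.atoms.items()}, r.icode)
             for r in self.residues],
            name=self.name,
            chain=self.chain,
        )

    def coords(self, selection: Iterable[Tuple[int, str]]) -> np.ndarray:
        return np.array([self.residue(s)[a] for s, a in selection])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        out = self.copy()
        for res in out.residues:
            for k in res.atoms:
                res.atoms[k] = rotation @ res.atoms[k] + translation
        return out


@dataclass
class RDCVector:
    """Unit internuclear vector of one RDC in the molecular frame."""

    residue: int
    bond_class: str
    u: np.ndarray
    b: float  # actual bond length, nm

    def __post_init__(self):
        n = float(np.linalg.norm(self.u))
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"RDC vector not unit-normalized (|u|={n})")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("degenerate zero-length vector")
    return v / n


def read_pdb(path, altloc_policy: str = "occupancy", chain: Optional[str] = None,
             model_index: int = 0) -> Structure:
    """Read a PDB file into a Structure.

    Keeps the first model and a single protein chain (the first one, or
    ``chain``), drops waters and heteroatom residues, converts angstrom to
    nm, and resolves alternate locations by highest occupancy (ties go to
    altloc 'A').
    """
    if altloc_policy != "occupancy":
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    st = gemmi.read_pdb(str(path))
    st.setup_entities()
    model = st[model_index]
    picked = None
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        picked = ch
        break
    if picked is None:
        raise ValueError(f"chain {chain!r} not found in {path}")
    residues: List[Residue] = []
    for res in picked:
        info = gemmi.find_tabulated_residue(res.name)
        if info is None or not info.is_amino_acid():
            continue
        atoms: Dict[str, Tuple[float, str]] = {}
        coords: Dict[str, np.ndarray] = {}
        for atom in res:
            key = atom.name
            occ, alt = atom.occ, atom.altloc or "A"
            if key in atoms:
                best_occ, best_alt = atoms[key]
                if occ < best_occ or (occ == best_occ and alt >= best_alt):
                    continue
            atoms[key] = (occ, alt)
            coords[key] = np.array([atom.pos.x, atom.pos.y, atom.pos.z]) * 0.1
        residues.append(Residue(res.seqid.num, res.name, coords,
                                res.seqid.icode.strip()))
    if not residues:
        raise ValueError(f"no protein residues found in {path}")
    for res in residues:
        for v in res.atoms.values():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite coordinates in residue {res.seqid}")
    return Structure(residues, name=str(path), chain=picked.name)


def write_pdb(structure: Structure, path) -> None:
    """Write the structure as minimal PDB ATOM records (nm -> angstrom)."""
    serial = 1
    with open(path, "w") as fh:
        for res in structure.residues:
            for name, xyz in res.atoms.items():
                x, y, z = (xyz * 10.0).tolist()
                el = name[0] if name[0].isalpha() else name[1]
                atom_field = f" {name:<3s}" if len(name) < 4 else name
                fh.write(
                    f"ATOM  {serial:5d} {atom_field}{'':1s}{res.name:<3s} "
                    f"{structure.chain:1s}{res.seqid:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {el:>2s}\n"
                )
                serial += 1
        fh.write("END\n")


def build_amide_protons(structure: Structure) -> Structure:
    """Place backbone amide protons H at 0.1 nm from N.

    H lies in the C'(i-1)-N(i)-CA(i) plane along the negative bisector of
    that angle at N.  The N-terminal residue and prolines are skipped;
    residues with missing neighbours are skipped with a warning.
    """
    for i, res in enumerate(structure.residues):
        if i == 0 or res.name == "PRO":
            continue
        prev = structure.residues[i - 1]
        if "C" not in prev or "N" not in res or "CA" not in res:
            warnings.warn(
                f"cannot build H for residue {res.seqid}: missing backbone atoms"
            )
            continue
        n = res["N"]
        u1 = _unit(prev["C"] - n)
        u2 = _unit(res["CA"] - n)
        res.atoms["H"] = n + B_NH * _unit(-(u1 + u2))
    return structure


def _tetrahedral_completion(u1: np.ndarray, u2: np.ndarray) -> np.ndarray:
    """First of the two directions completing a tetrahedron over bonds u1, u2.

    The returned unit vector makes the tetrahedral angle (109.47 deg) with
    both inputs; "first" is fixed by taking the +(u1 x u2) side.
    """
    bis = _unit(-(u1 + u2))
    perp = _unit(np.cross(u1, u2))
    cos_half = -float(np.dot(bis, u1))  # cos of half the u1-u2 angle
    ct = -_TET_COS / cos_half
    if not 0.0 < ct < 1.0:
        raise ValueError("degenerate geometry for tetrahedral completion")
    return ct * bis + math.sqrt(1.0 - ct * ct) * perp


def build_virtual_ha(structure: Structure) -> Structure:
    """Place virtual H^alpha atoms at 0.109 nm from CA.

    For residues with a CB the direction is the tetrahedral completion
    -(u_N + u_C' + u_CB) normalized; for glycine the first of the two
    completion directions over the N and C' bonds by a fixed chirality
    rule (+(u_N x u_C') side).
    """
    for res in structure.residues:
        if not {"N", "CA", "C"} <= set(res.atoms):
            continue
        ca = res["CA"]
        u_n = _unit(res["N"] - ca)
        u_c = _unit(res["C"] - ca)
        if abs(float(np.dot(u_n, u_c))) > 1.0 - 1e-9:
            raise ValueError(f"collinear N, CA, C in residue {res.seqid}")
        if "CB" in res:
            u_b = _unit(res["CB"] - ca)
            direction = _unit(-(u_n + u_c + u_b))
        else:
            direction = _tetrahedral_completion(u_n, u_c)
        res.atoms["HA"] = ca + B_CAHA * direction
    return structure


# atom pair per bond class: (residue offset, atom) for k1 and k2; the target
# residue index is the one carrying the N (N-H, C'-N) or the CA (CA-HA,
# CA-C') of the coupling.
_BOND_ATOMS = {
    "N-HN": ((0, "N"), (0, "H")),
    "CA-HA": ((0, "CA"), (0, "HA")),
    "CA-C": ((0, "CA"), (0, "C")),
    "C-N": ((-1, "C"), (0, "N")),
}


def extract_rdc_vectors(structure: Structure,
                        targets: Sequence[RDCTarget]) -> List[RDCVector]:
    """One unit internuclear vector per target, index-aligned with targets."""
    vectors: List[RDCVector] = []
    missing: List[str] = []
    for tgt in targets:
        (off1, a1), (off2, a2) = _BOND_ATOMS[tgt.bond_class]
        try:
            i = structure.index_of(tgt.residue)
            i1, i2 = i + off1, i + off2
            if i1 < 0 or i2 < 0:
                raise KeyError
            r1 = structure.residues[i1][a1]
            r2 = structure.residues[i2][a2]
        except KeyError:
            missing.append(f"residue {tgt.residue} {tgt.bond_class}")
            continue
        d = r1 - r2
        b = float(np.linalg.norm(d))
        vectors.append(RDCVector(tgt.residue, tgt.bond_class, d / b, b))
    if missing:
        raise ValueError(
            "unresolvable atoms for targets: " + ", ".join(missing)
        )
    return vectors


_TABLE_COLUMNS = {"residue", "bond_class", "d0_hz"}


def read_rdc_table(path) -> List[RDCTarget]:
    """Read a target-RDC table (TSV: residue, bond_class, d0_hz [, d0_hz_2]).

    Rows with two measurement columns are merged by arithmetic mean
    (provenance ``averaged-duplicate``); duplicate (residue, bond_class)
    rows are an error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if not _TABLE_COLUMNS <= set(df.columns):
        raise ValueError(
            f"{path}: header must contain columns {sorted(_TABLE_COLUMNS)}"
        )
    has_dup = "d0_hz_2" in df.columns
    targets: List[RDCTarget] = []
    seen = set()
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        cls = str(row["bond_class"]).strip()
        if cls not in BOND_CLASSES:
            raise ValueError(f"{path}:{line}: unknown bond class {cls!r}")
        try:
            residue = int(row["residue"])
            d0 = float(row["d0_hz"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}:{line}: non-numeric field ({exc})") from exc
        provenance = "measured"
        if has_dup and not pd.isna(row["d0_hz_2"]) and str(row["d0_hz_2"]).strip():
            try:
                d0 = 0.5 * (d0 + float(row["d0_hz_2"]))
            except ValueError as exc:
                raise ValueError(f"{path}:{line}: non-numeric field ({exc})") from exc
            provenance = "averaged-duplicate"
        key = (residue, cls)
        if key in seen:
            raise ValueError(f"{path}:{line}: duplicate entry for {key}")
        seen.add(key)
        targets.append(RDCTarget(residue, cls, d0, provenance=provenance))
    return targets


def write_rdc_table(targets: Sequence[RDCTarget], path) -> None:
    with open(path, "w") as fh:
        fh.write("residue\tbond_class\td0_hz\n")
        for t in targets:
            fh.write(f"{t.residue}\t{t.bond_class}\t{t.d0:.4f}\n")
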