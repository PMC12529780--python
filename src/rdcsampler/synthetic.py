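"""Synthetic fixtures: ideal backbones and RDC targets from a known tensor.

Everything downstream (proton construction, vector extraction, the
alignment-tensor fit, the rotational-sampling engine and the metrics) can
be exercised without any external structure or measurement: an ideal
polyalanine backbone is built from internal coordinates, and target RDCs
are generated from a known alignment tensor, optionally with Gaussian
noise, at the Hz scale of measured backbone couplings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from rdcsampler.core_rdc import RDCTarget
from rdcsampler.structure_io import (Residue, Structure, build_amide_protons,
                                     build_virtual_ha, extract_rdc_vectors)

__all__ = [
    "SyntheticSpec",
    "BackboneGeometry",
    "make_helix",
    "dihedral",
    "default_tensor_components",
    "synth_targets",
    "invert_sequence",
]


@dataclass(frozen=True)
class BackboneGeometry:
    """Ideal backbone internal coordinates (nm / degrees)."""

    b_n_ca: float = 0.147
    b_ca_c: float = 0.153
    b_c_n: float = 0.133
    b_c_o: float = 0.123
    b_ca_cb: float = 0.153
    ang_n_ca_c: float = 111.0
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.8
    omega: float = 180.0


GEOMETRY = BackboneGeometry()

# alignment-tensor components (Sxx, Syy, Sxy, Sxz, Syz) sized so that
# noise-free synthetic N-H / CA-HA RDCs span roughly +-30 Hz, the scale of
# the measured backbone sets
_DEFAULT_S = np.array([5.0e-4, -2.0e-4, 3.0e-4, -1.5e-4, 2.5e-4])


def default_tensor_components() -> np.ndarray:
    return _DEFAULT_S.copy()


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic fixture."""

    n_residues: int = 30
    phi: float = -57.0
    psi: float = -47.0
    s: np.ndarray = field(default_factory=default_tensor_components)
    sigma: float = 0.0  # Hz
    seed: int = 0

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        if self.s.shape != (5,):
            raise ValueError("tensor needs 5 components")
        if self.sigma < 0:
            raise ValueError("noise sigma must be non-negative")


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           r: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Natural-extension placement of the next atom from three predecessors."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    local = r * np.array([
        -math.cos(ang),
        math.sin(ang) * math.cos(dih),
        -math.sin(ang) * math.sin(dih),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.column_stack([bc, np.cross(n, bc), n])
    return c + m @ local


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, IUPAC sign convention."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    return math.degrees(math.atan2(float(m @ n2), float(n1 @ n2)))


def make_helix(n_residues: int, phi: float = -57.0, psi: float = -47.0,
               geometry: BackboneGeometry = GEOMETRY) -> Structure:
    """Ideal polyalanine backbone (N, CA, C, O, CB) with given dihedrals.

    Default dihedrals are the canonical alpha-helix; any (phi, psi) pair
    builds the corresponding regular conformation.
    """
    if n_residues < 4:
        raise ValueError("need at least 4 residues")
    g = geometry
    # seed frame for the first residue
    ang = math.radians(g.ang_n_ca_c)
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([g.b_n_ca, 0.0, 0.0])
    c0 = ca0 + g.b_ca_c * np.array([-math.cos(ang), math.sin(ang), 0.0])
    ns, cas, cs = [n0], [ca0], [c0]
    for i in range(1, n_residues):
        n_next = _place(ns[-1], cas[-1], cs[-1], g.b_c_n, g.ang_ca_c_n, psi)
        ca_next = _place(cas[-1], cs[-1], n_next, g.b_n_ca, g.ang_c_n_ca,
                         g.omega)
        c_next = _place(cs[-1], n_next, ca_next, g.b_ca_c, g.ang_n_ca_c, phi)
        ns.append(n_next)
        cas.append(ca_next)
        cs.append(c_next)
    residues: List[Residue] = []
    for i in range(n_residues):
        atoms = {"N": ns[i], "CA": cas[i], "C": cs[i]}
        # carbonyl O anti to the following amide N
        atoms["O"] = _place(ns[i], cas[i], cs[i], g.b_c_o, g.ang_ca_c_o,
                            psi + 180.0)
        # CB by tetrahedral completion, fixed chirality (-(uN x uC) side)
        u_n = (ns[i] - cas[i]) / np.linalg.norm(ns[i] - cas[i])
        u_c = (cs[i] - cas[i]) / np.linalg.norm(cs[i] - cas[i])
        bis = -(u_n + u_c)
        bis /= np.linalg.norm(bis)
        perp = np.cross(u_n, u_c)
        perp /= np.linalg.norm(perp)
        cos_half = -float(bis @ u_n)
        ct = (1.0 / 3.0) / cos_half
        cb_dir = ct * bis - math.sqrt(1.0 - ct * ct) * perp
        atoms["CB"] = cas[i] + g.b_ca_cb * cb_dir
        residues.append(Residue(i + 1, "ALA", atoms))
    return Structure(residues, name=f"helix{n_residues}")


def synth_targets(structure: Structure, s: np.ndarray,
                  bond_classes: Sequence[str] = ("N-HN", "CA-HA", "CA-C", "C-N"),
                  sigma: float = 0.0, seed: int = 0,
                  rng: Optional[np.random.Generator] = None) -> List[RDCTarget]:
    """Targets D0 = Dc R (u^T S u) + N(0, sigma^2) for a known tensor.

    Protons are built if absent.  Provenance is ``synthetic``.
    """
    from rdcsampler.at_method import AlignmentTensor, predict_rdc

    if rng is None:
        rng = np.random.default_rng(seed)
    has_h = any("H" in r for r in structure.residues)
    has_ha = any("HA" in r for r in structure.residues)
    if ("N-HN" in bond_classes and not has_h) or \
       ("CA-HA" in bond_classes and not has_ha):
        structure = build_virtual_ha(build_amide_protons(structure.copy()))
    targets: List[RDCTarget] = []
    for cls in bond_classes:
        for i, res in enumerate(structure.residues):
            if cls == "N-HN" and ("H" not in res):
                continue
            if cls == "CA-HA" and ("HA" not in res):
                continue
            if cls == "C-N" and i == 0:
                continue
            targets.append(RDCTarget(res.seqid, cls, 0.0, provenance="synthetic"))
    vectors = extract_rdc_vectors(structure, targets)
    clean = predict_rdc(AlignmentTensor(np.asarray(s, dtype=float)), vectors)
    noise = rng.normal(0.0, sigma, clean.size) if sigma > 0 else 0.0
    d0 = clean + noise
    for t, v in zip(targets, d0):
        t.d0 = float(v)
    return targets


def invert_sequence(targets: Sequence[RDCTarget]) -> List[RDCTarget]:
    """Reverse the ordered D0 values of a single-class set along the chain.

    The reversed values are reassigned to the same ordered residue
    positions; applying the operation twice restores the input.
    """
    classes = {t.bond_class for t in targets}
    if len(classes) != 1:
        raise ValueError(f"invert_sequence needs a single bond class, got {classes}")
    ordered = sorted(targets, key=lambda t: t.residue)
    values = [t.d0 for t in ordered][::-1]
    return [
        RDCTarget(t.residue, t.bond_class, v, restrained=t.restrained,
                  provenance="artificial-inverted")
        for t, v in zip(ordered, values)
    ]
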