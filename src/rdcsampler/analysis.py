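"""Evaluation metrics and diagnostics.

RMSD family between calculated and target RDCs (all / restrained /
unrestrained subsets), deviation counts, cross-set RMSDs, theta/sin(theta)
orientation distributions with magic-angle peak detection, Kabsch backbone
superposition, and geometric hydrogen-bond detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from rdcsampler.core_rdc import RDCTarget
from rdcsampler.structure_io import Structure

__all__ = [
    "MetricsReport",
    "rmsd_metrics",
    "cross_rmsd",
    "ThetaDistribution",
    "theta_distribution",
    "helix_reference_vectors",
    "superpose_backbone",
    "detect_hbonds",
]

MAGIC_ANGLES_DEG = (math.degrees(math.acos(1.0 / math.sqrt(3.0))),
                    180.0 - math.degrees(math.acos(1.0 / math.sqrt(3.0))))
SIGNIFICANCE_HZ = 3.0  # deviations at or below this are considered insignificant


@dataclass
class MetricsReport:
    """RMSD family for one (calculated, target) pairing.

    rmsd over all targets, r_rmsd over the restrained subset, ur_rmsd over
    the unrestrained one (None for empty subsets); n_dev counts deviations
    strictly larger than 3 Hz, n_dev_sign counts opposite-sign pairs (a
    zero on either side matches both signs).
    """

    rmsd: float
    r_rmsd: Optional[float]
    ur_rmsd: Optional[float]
    n_dev: int
    n_dev_sign: int
    n: int
    n_restrained: int
    deviations: np.ndarray

    def as_dict(self) -> dict:
        return {
            "rmsd": self.rmsd,
            "r_rmsd": self.r_rmsd,
            "ur_rmsd": self.ur_rmsd,
            "n_dev": self.n_dev,
            "n_dev_sign": self.n_dev_sign,
            "n": self.n,
            "n_restrained": self.n_restrained,
        }


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.square(x))))


def rmsd_metrics(calc: Sequence[float],
                 targets: Sequence[RDCTarget]) -> MetricsReport:
    """Metrics between calculated RDCs and index-aligned targets."""
    calc = np.asarray(calc, dtype=float)
    if calc.size == 0:
        raise ValueError("empty RDC list")
    if calc.size != len(targets):
        raise ValueError("calc and targets must be index-aligned")
    d0 = np.array([t.d0 for t in targets])
    mask = np.array([t.restrained for t in targets], dtype=bool)
    dev = calc - d0
    n_dev = int(np.sum(np.abs(dev) > SIGNIFICANCE_HZ))
    n_sign = int(np.sum((calc * d0) < 0.0))
    return MetricsReport(
        rmsd=_rms(dev),
        r_rmsd=_rms(dev[mask]) if mask.any() else None,
        ur_rmsd=_rms(dev[~mask]) if (~mask).any() else None,
        n_dev=n_dev,
        n_dev_sign=n_sign,
        n=calc.size,
        n_restrained=int(mask.sum()),
        deviations=dev,
    )


def cross_rmsd(set_a: Sequence[float], set_b: Sequence[float]) -> float:
    """RMSD between two aligned sets of calculated RDCs (Hz)."""
    a = np.asarray(set_a, dtype=float)
    b = np.asarray(set_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty RDC list")
    return _rms(a - b)


@dataclass
class ThetaDistribution:
    """1/sin(theta)-weighted orientation histograms against reference vectors."""

    bin_edges_deg: np.ndarray
    densities: np.ndarray  # (n_refs, n_bins), each normalized to unit sum
    magic_angle_flag: bool
    per_ref_flags: np.ndarray


def theta_distribution(traj: np.ndarray, reference_vectors: np.ndarray,
                       bin_width_deg: float = 2.0,
                       peak_window_deg: float = 5.0,
                       peak_factor: float = 1.5) -> ThetaDistribution:
    """Distribution of the angle between sampled mfv directions and refs.

    Each sample is weighted by 1/sin(theta) (the isotropic density of theta
    is proportional to sin(theta), so a uniform rotational distribution
    gives a flat weighted histogram); samples with sin(theta) < 1e-6 are
    dropped.  The magic-angle flag raises when any bin within
    ``peak_window_deg`` of 54.74 or 125.26 degrees exceeds ``peak_factor``
    times the mean bin density.
    """
    traj = np.asarray(traj, dtype=float)
    if traj.size == 0:
        raise ValueError("empty orientation trajectory")
    refs = np.atleast_2d(np.asarray(reference_vectors, dtype=float))
    refs = refs / np.linalg.norm(refs, axis=1, keepdims=True)
    edges = np.arange(0.0, 180.0 + bin_width_deg, bin_width_deg)
    centers = 0.5 * (edges[:-1] + edges[1:])
    near_magic = np.zeros(centers.size, dtype=bool)
    for ma in MAGIC_ANGLES_DEG:
        near_magic |= np.abs(centers - ma) <= peak_window_deg
    densities = np.empty((refs.shape[0], centers.size))
    flags = np.zeros(refs.shape[0], dtype=bool)
    for i, ref in enumerate(refs):
        cos_t = np.clip(traj @ ref, -1.0, 1.0)
        theta = np.degrees(np.arccos(cos_t))
        sin_t = np.sin(np.radians(theta))
        keep = sin_t >= 1e-6
        hist, _ = np.histogram(theta[keep], bins=edges,
                               weights=1.0 / sin_t[keep])
        total = hist.sum()
        dens = hist / total if total > 0 else hist
        densities[i] = dens
        flags[i] = bool(np.any(dens[near_magic] > peak_factor * dens.mean()))
    return ThetaDistribution(edges, densities, bool(flags.any()), flags)


DEFAULT_HELIX_RANGES = ((4, 15), (24, 36), (89, 99))


def helix_reference_vectors(structure: Structure,
                            ranges=DEFAULT_HELIX_RANGES) -> np.ndarray:
    """Unit vectors joining the endpoint CA atoms of the given helices."""
    vecs = []
    for first, last in ranges:
        d = structure.residue(last)["CA"] - structure.residue(first)["CA"]
        vecs.append(d / np.linalg.norm(d))
    return np.array(vecs)


def superpose_backbone(struct_a: Structure, struct_b: Structure,
                       residue_range: Tuple[int, int] = (3, 126)):
    """Kabsch superposition of B onto A over backbone N, CA, C atoms.

    Returns ``(rotation, translation, rmsd_nm, per_residue)`` where the
    transform maps B coordinates onto A's frame and ``per_residue`` holds,
    for every residue present in both structures, the post-fit CA and N
    distances (the per-residue structural-difference profile).
    """
    lo, hi = residue_range
    sel = []
    missing = []
    for seq in range(lo, hi + 1):
        try:
            ra, rb = struct_a.residue(seq), struct_b.residue(seq)
        except KeyError:
            missing.append(seq)
            continue
        for atom in ("N", "CA", "C"):
            if atom not in ra or atom not in rb:
                missing.append(seq)
                break
        else:
            sel.append(seq)
    if missing:
        raise ValueError(f"missing backbone atoms for residues {missing}")
    pa = np.array([struct_a.residue(s)[a] for s in sel for a in ("N", "CA", "C")])
    pb = np.array([struct_b.residue(s)[a] for s in sel for a in ("N", "CA", "C")])
    ca_mean, cb_mean = pa.mean(axis=0), pb.mean(axis=0)
    rot, rssd = Rotation.align_vectors(pa - ca_mean, pb - cb_mean)
    q = rot.as_matrix()
    translation = ca_mean - q @ cb_mean
    fit_rmsd = float(rssd / math.sqrt(pa.shape[0]))
    per_residue = {}
    for res_a in struct_a.residues:
        try:
            res_b = struct_b.residue(res_a.seqid)
        except KeyError:
            continue
        entry = {}
        for atom in ("CA", "N"):
            if atom in res_a and atom in res_b:
                moved = q @ res_b[atom] + translation
                entry[atom] = float(np.linalg.norm(res_a[atom] - moved))
        per_residue[res_a.seqid] = entry
    return q, translation, fit_rmsd, per_residue


def detect_hbonds(structure: Structure,
                  max_ha_nm: float = 0.25,
                  min_angle_deg: float = 135.0) -> List[Tuple[int, int]]:
    """Backbone N-H...O=C hydrogen bonds by the geometric criterion.

    A bond requires a hydrogen-acceptor distance strictly below
    ``max_ha_nm`` and a donor-hydrogen-acceptor angle strictly above
    ``min_angle_deg``.  Returns (donor residue, acceptor residue) pairs.
    """
    bonds = []
    for res_d in structure.residues:
        if "H" not in res_d or "N" not in res_d:
            continue
        h, n = res_d["H"], res_d["N"]
        for res_a in structure.residues:
            if res_a.seqid == res_d.seqid or "O" not in res_a:
                continue
            o = res_a["O"]
            dist = float(np.linalg.norm(h - o))
            if dist >= max_ha_nm:
                continue
            u1 = (n - h) / np.linalg.norm(n - h)
            u2 = (o - h) / dist
            angle = math.degrees(math.acos(float(np.clip(u1 @ u2, -1.0, 1.0))))
            if angle > min_angle_deg:
                bonds.append((res_d.seqid, res_a.seqid))
    return bonds
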