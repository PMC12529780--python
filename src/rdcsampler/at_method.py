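"""Alignment-tensor (Saupe matrix) back-calculation of RDCs.

For a rigid structure, each RDC is linear in the five independent elements
of the symmetric traceless order matrix S::

    D_k = Dc_k R_k (u_k^T S u_k)
        = Dc_k R_k [ux^2-uz^2, uy^2-uz^2, 2 ux uy, 2 ux uz, 2 uy uz] . s

with s = (Sxx, Syy, Sxy, Sxz, Syz) and Szz = -Sxx - Syy.  Fitting s by
unweighted linear least squares over the restrained targets (the standard
SVD Saupe fit, no time-averaging) and evaluating the linear form for all
vectors gives the alignment-tensor prediction for every RDC, restrained or
not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from rdcsampler.core_rdc import BOND_CLASSES, RDCTarget
from rdcsampler.structure_io import RDCVector

__all__ = ["AlignmentTensor", "ATFitResult", "build_design_matrix",
           "fit_alignment_tensor", "predict_rdc"]

_SVD_RCOND = 1e-10


@dataclass
class AlignmentTensor:
    """Five independent components (Sxx, Syy, Sxy, Sxz, Syz)."""

    s: np.ndarray

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        if self.s.shape != (5,):
            raise ValueError("alignment tensor needs exactly 5 components")

    @property
    def matrix(self) -> np.ndarray:
        sxx, syy, sxy, sxz, syz = self.s
        return np.array([
            [sxx, sxy, sxz],
            [sxy, syy, syz],
            [sxz, syz, -sxx - syy],
        ])

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.matrix)

    def rotated(self, q: np.ndarray) -> "AlignmentTensor":
        m = q @ self.matrix @ q.T
        return AlignmentTensor(
            np.array([m[0, 0], m[1, 1], m[0, 1], m[0, 2], m[1, 2]])
        )


@dataclass
class ATFitResult:
    tensor: AlignmentTensor
    predicted: np.ndarray  # Hz, for all input vectors
    rank: int
    residual_rms: float  # Hz, over the restrained subset


def _scales(vectors: Sequence[RDCVector]) -> np.ndarray:
    """Dc*R in Hz per vector (rigid-bond radial factor of each class)."""
    return np.array([BOND_CLASSES[v.bond_class].dc_r_hz for v in vectors])


def build_design_matrix(vectors: Sequence[RDCVector]) -> np.ndarray:
    """N x 5 matrix A with A @ s = predicted RDCs in Hz."""
    u = np.array([v.u for v in vectors])
    ux, uy, uz = u[:, 0], u[:, 1], u[:, 2]
    basis = np.column_stack([
        ux ** 2 - uz ** 2,
        uy ** 2 - uz ** 2,
        2.0 * ux * uy,
        2.0 * ux * uz,
        2.0 * uy * uz,
    ])
    return _scales(vectors)[:, None] * basis


def fit_alignment_tensor(
    vectors: Sequence[RDCVector], targets: Sequence[RDCTarget]
) -> ATFitResult:
    """Least-squares Saupe fit over the restrained targets.

    Requires at least 5 restrained targets; a design matrix of rank < 5
    yields a warning and the minimum-norm solution.  Predictions are
    returned for all vectors.
    """
    if len(vectors) != len(targets):
        raise ValueError("vectors and targets must be index-aligned")
    mask = np.array([t.restrained for t in targets], dtype=bool)
    if mask.sum() < 5:
        raise ValueError(
            f"need at least 5 restrained targets to fit 5 tensor components, "
            f"got {int(mask.sum())}"
        )
    a_full = build_design_matrix(vectors)
    a = a_full[mask]
    d0 = np.array([t.d0 for t in targets])[mask]
    s, _, rank, _ = np.linalg.lstsq(a, d0, rcond=_SVD_RCOND)
    if rank < 5:
        warnings.warn(
            f"rank-deficient design matrix (rank {rank} < 5); "
            "minimum-norm solution returned"
        )
    tensor = AlignmentTensor(s)
    predicted = a_full @ s
    residual = float(np.sqrt(np.mean((a @ s - d0) ** 2)))
    return ATFitResult(tensor, predicted, int(rank), residual)


def predict_rdc(tensor: AlignmentTensor,
                vectors: Sequence[RDCVector]) -> np.ndarray:
    """Predicted RDCs D_k = Dc_k R_k u_k^T S u_k in Hz."""
    u = np.array([v.u for v in vectors])
    quad = np.einsum("ki,ij,kj->k", u, tensor.matrix, u)
    return _scales(vectors) * quad
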