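"""Anisotropic elastic-network normal-mode analysis on Cα traces.

Residue pairs closer than a cutoff in the reference structure are joined
by identical harmonic springs anchored at their reference distances:

    E(q) = (gamma / 2) * sum_{d_ij^0 < cutoff} (d_ij(q) - d_ij^0)^2

The Hessian of this potential at the reference is block-structured: the
off-diagonal 3x3 block for a contacting pair (i, j) is
``-gamma * (r_ij r_ij^T) / |r_ij|^2`` with ``r_ij`` the reference
inter-residue vector, and each diagonal block is minus the sum of its
row's off-diagonal blocks, which enforces translational invariance.
Diagonalizing the Hessian yields the normal modes; a connected,
non-collinear network has exactly six zero modes (rigid translations and
rotations).  The harmonic mean-square fluctuation of residue i is the
trace of the i-th 3x3 diagonal block of the Hessian pseudo-inverse,

    <dr_i^2> = c * sum_{k > 6} (1/lambda_k) |v_k,i|^2,

computed here from the nonzero modes.  The overall scale c (temperature,
force constant) cancels once profiles are normalized, so the defaults
``gamma = 1`` and ``c = 1`` are used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .exceptions import (
    DegenerateGeometryError,
    DisconnectedNetworkError,
    ZeroModeCountError,
)
from .profiles import FluctProfile
from .structio import CalphaStructure

__all__ = [
    "DEFAULT_CUTOFF",
    "ENMModel",
    "ENMModes",
    "build_hessian",
    "compute_modes",
    "enm_rmsf",
    "predict_profile",
]

DEFAULT_CUTOFF = 12.0  # Å, standard Cα anisotropic-network range
DEFAULT_GAMMA = 1.0
DEFAULT_TOL_ZERO = 1e-8  # relative to the largest eigenvalue


@dataclass
class ENMModel:
    """Elastic network specification: reference coordinates plus spring
    parameters.

    ``cutoff`` is the interaction distance threshold in Å and ``gamma`` the
    uniform spring force constant (arbitrary energy/Å² units; it cancels in
    normalized profiles).
    """

    coords: np.ndarray
    cutoff: float = DEFAULT_CUTOFF
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if len(self.coords) < 2:
            raise ValueError("an elastic network needs at least 2 residues")
        if self.cutoff <= 0 or self.gamma <= 0:
            raise ValueError("cutoff and gamma must be positive")

    @property
    def n_residues(self) -> int:
        return len(self.coords)


@dataclass
class ENMModes:
    """Eigendecomposition of an elastic-network Hessian.

    ``eigenvalues`` ascend; ``eigenvectors[:, k]`` is the orthonormal
    3N-dimensional mode k.  ``n_zero`` counts the near-zero (rigid-body)
    modes at the tolerance used during computation.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    n_zero: int
    residue_numbers: np.ndarray | None = field(default=None)

    @property
    def n_residues(self) -> int:
        return self.eigenvectors.shape[0] // 3


def build_hessian(model: ENMModel) -> np.ndarray:
    """Assemble the 3N x 3N Hessian of the elastic-network potential.

    Raises :class:`DegenerateGeometryError` if two residues coincide.
    """
    coords = model.coords
    n = model.n_residues
    diff = coords[:, None, :] - coords[None, :, :]  # r_i - r_j
    dist2 = np.sum(diff**2, axis=2)
    iu = np.triu_indices(n, k=1)
    if np.any(dist2[iu] == 0.0):
        raise DegenerateGeometryError("two residues occupy identical coordinates")
    contact = (dist2 < model.cutoff**2) & ~np.eye(n, dtype=bool)
    hessian = np.zeros((3 * n, 3 * n))
    ii, jj = np.nonzero(np.triu(contact, k=1))
    for i, j in zip(ii, jj):
        r = diff[i, j]
        block = -model.gamma * np.outer(r, r) / dist2[i, j]
        hessian[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] = block
        hessian[3 * j : 3 * j + 3, 3 * i : 3 * i + 3] = block
        hessian[3 * i : 3 * i + 3, 3 * i : 3 * i + 3] -= block
        hessian[3 * j : 3 * j + 3, 3 * j : 3 * j + 3] -= block
    return hessian


def compute_modes(
    hessian: np.ndarray,
    tol_zero: float = DEFAULT_TOL_ZERO,
    allow_extra_zero_modes: bool = False,
    residue_numbers: np.ndarray | None = None,
) -> ENMModes:
    """Diagonalize a symmetric Hessian and classify rigid-body modes.

    Modes with eigenvalue below ``tol_zero`` times the largest eigenvalue
    are flagged as zero modes.  A connected, non-collinear network must have
    exactly six; more indicate a disconnected network (error unless
    ``allow_extra_zero_modes``), fewer a numerical-tolerance problem.
    """
    hessian = np.asarray(hessian, dtype=float)
    if hessian.ndim != 2 or hessian.shape[0] != hessian.shape[1]:
        raise ValueError("hessian must be square")
    if np.max(np.abs(hessian - hessian.T)) > 1e-10 * max(
        1.0, np.max(np.abs(hessian))
    ):
        raise ValueError("hessian must be symmetric")
    eigvals, eigvecs = scipy.linalg.eigh(hessian)
    top = eigvals[-1]
    if top <= 0:
        raise DisconnectedNetworkError("network has no contacts (zero Hessian)")
    n_zero = int(np.sum(eigvals < tol_zero * top))
    if n_zero > 6 and not allow_extra_zero_modes:
        raise DisconnectedNetworkError(
            f"{n_zero} zero modes found (expected 6); the network is disconnected "
            "or collinear"
        )
    if n_zero < 6:
        raise ZeroModeCountError(
            f"only {n_zero} zero modes found (expected 6); tol_zero may be too tight"
        )
    return ENMModes(
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        n_zero=n_zero,
        residue_numbers=residue_numbers,
    )


def enm_rmsf(modes: ENMModes, scale: float = 1.0) -> FluctProfile:
    """Per-residue RMSF implied by the harmonic mode covariance.

    ``<dr_i^2> = scale * sum over nonzero modes of (1/lambda) |v_i|^2``;
    the profile is the square root.  ``scale`` is an arbitrary amplitude
    (it cancels under normalization) and defaults to 1.
    """
    n = modes.n_residues
    nz = slice(modes.n_zero, None)
    inv_l = 1.0 / modes.eigenvalues[nz]
    vecs = modes.eigenvectors[:, nz].reshape(n, 3, -1)  # (res, xyz, mode)
    msf = scale * np.einsum("rxm,m->r", vecs**2, inv_l)
    resnums = (
        modes.residue_numbers
        if modes.residue_numbers is not None
        else np.arange(1, n + 1)
    )
    return FluctProfile(
        protein_id="",
        residue_numbers=np.asarray(resnums),
        values=np.sqrt(msf),
        source="predicted",
    )


def predict_profile(
    structure: CalphaStructure,
    cutoff: float = DEFAULT_CUTOFF,
    gamma: float = DEFAULT_GAMMA,
    tol_zero: float = DEFAULT_TOL_ZERO,
) -> FluctProfile:
    """End-to-end elastic-network flexibility prediction for one structure."""
    model = ENMModel(coords=structure.coords, cutoff=cutoff, gamma=gamma)
    modes = compute_modes(
        build_hessian(model),
        tol_zero=tol_zero,
        residue_numbers=structure.residue_numbers,
    )
    profile = enm_rmsf(modes)
    profile.protein_id = structure.protein_id
    return profile
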