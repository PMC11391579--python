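"""Rigid-body superposition, iterative mean structures, and ensemble RMSF.

The experimental fluctuation profile of an NMR ensemble (and of any
simulated ensemble of snapshots) is obtained by superposing all models
onto a converged mean structure and measuring, per residue, the root mean
square deviation of the model positions from the mean:

    RMSF_i = sqrt( (1/M) sum_j |x_i(j) - <x_i>|^2 )

Superposition is the Kabsch least-squares alignment (SVD with the proper
rotation constraint); the mean structure is computed iteratively:
superpose on model 1, average, re-superpose on the average, re-average,
until two successive means agree to 1e-6 Å (in practice two iterations).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import DegenerateGeometryError, DimensionError, InsufficientDataError
from .profiles import FluctProfile
from .structio import CalphaStructure, Ensemble

__all__ = ["RigidTransform", "kabsch_superpose", "mean_structure", "ensemble_rmsf"]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("rotation determinant must be +1")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-9:
            raise ValueError("rotation must be orthogonal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an ``(n, 3)`` coordinate array."""
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns the proper rigid transform minimizing the RMSD of the
    transformed mobile coordinates to the reference, and that minimum RMSD
    in Å.  Reflections are excluded.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise DimensionError(
            f"coordinate shapes differ: {mobile.shape} vs {reference.shape}"
        )
    if mobile.ndim != 2 or mobile.shape[1] != 3 or len(mobile) < 3:
        raise DegenerateGeometryError("superposition needs at least 3 points in 3D")
    mob_mean = mobile.mean(axis=0)
    ref_mean = reference.mean(axis=0)
    P = mobile - mob_mean
    Q = reference - ref_mean
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref_mean - R @ mob_mean
    transform = RigidTransform(rotation=R, translation=t)
    moved = transform.apply(mobile)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return transform, rmsd


def _superpose_all(coords: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Superpose each model of an (M, n, 3) stack onto the reference."""
    out = np.empty_like(coords)
    for j in range(len(coords)):
        tf, _ = kabsch_superpose(coords[j], reference)
        out[j] = tf.apply(coords[j])
    return out


def mean_structure(
    ensemble: Ensemble, tol: float = 1e-6, max_iter: int = 10
) -> CalphaStructure:
    """Iteratively converged mean Cα structure of an ensemble.

    All models are superposed on model 1 and averaged; models are then
    re-superposed on the average and re-averaged, until the RMSD between
    successive means drops below ``tol`` Å or ``max_iter`` iterations have
    run.  With experimental ensembles the second mean is already at the
    fixed point.
    """
    first = ensemble.models[0]
    if ensemble.n_models == 1:
        return replace(first)
    coords = ensemble.coords
    aligned = _superpose_all(coords, first.coords)
    mean = aligned.mean(axis=0)
    for _ in range(max_iter):
        aligned = _superpose_all(coords, mean)
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    return CalphaStructure(
        protein_id=ensemble.protein_id,
        chain_id=first.chain_id,
        residue_numbers=first.residue_numbers.copy(),
        coords=mean,
        bfactors=None,
    )


def ensemble_rmsf(ensemble: Ensemble, source: str = "nmr") -> FluctProfile:
    """Per-residue RMSF of an ensemble about its converged mean structure.

    Each model is superposed on the mean before the fluctuation is
    measured; the average over models uses the ensemble size M as
    denominator (a population average over snapshots).  ``source`` tags the
    resulting profile (``"nmr"`` for experimental ensembles, ``"predicted"``
    for simulation snapshots).
    """
    if ensemble.n_models < 2:
        raise InsufficientDataError(
            f"{ensemble.protein_id}: RMSF needs at least 2 models"
        )
    mean = mean_structure(ensemble)
    aligned = _superpose_all(ensemble.coords, mean.coords)
    sq_dev = np.sum((aligned - mean.coords) ** 2, axis=2)  # (M, n)
    rmsf = np.sqrt(sq_dev.mean(axis=0))
    return FluctProfile(
        protein_id=ensemble.protein_id,
        residue_numbers=ensemble.residue_numbers.copy(),
        values=rmsf,
        source=source,
    )
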