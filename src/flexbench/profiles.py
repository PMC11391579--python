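"""Per-residue fluctuation profiles and the operations that prepare them
for comparison: the B-factor relation, terminal truncation, normalization
and replicate averaging.

A fluctuation profile assigns each residue a root-mean-square fluctuation
(RMSF).  Experimental profiles come either from the spread of an NMR
ensemble or from crystallographic B-factors through the isotropic
Debye-Waller relation

    B_i = (8 pi^2 / 3) * RMSF_i^2

Before predicted and experimental profiles are correlated, the highly
mobile chain termini are removed (they are nonspecific and would dominate
the correlation) and both profiles are normalized to a unit maximum so
that methods with different absolute fluctuation scales remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import (
    AlignmentError,
    MissingDataError,
    NormalizationError,
    TruncationDegenerateError,
)
from .structio import CalphaStructure

__all__ = [
    "FluctProfile",
    "TruncationRange",
    "bfactor_to_rmsf",
    "rmsf_to_bfactor",
    "xray_profile",
    "truncate_termini",
    "apply_truncation",
    "normalize_profile",
    "average_replicates",
]

_B_COEFF = 8.0 * np.pi**2 / 3.0  # B = _B_COEFF * RMSF^2


@dataclass
class FluctProfile:
    """Per-residue fluctuation values with provenance.

    ``values`` are in Å for raw profiles and unitless after normalization.
    ``source`` records where the profile came from: ``"nmr"`` (ensemble
    spread), ``"xray"`` (B-factors) or ``"predicted"``.
    """

    protein_id: str
    residue_numbers: np.ndarray
    values: np.ndarray
    source: str = "predicted"
    normalized: bool = False

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.residue_numbers):
            raise ValueError("values and residue_numbers length mismatch")
        if np.any(self.values < 0):
            raise ValueError("fluctuation values must be non-negative")
        if self.source not in ("nmr", "xray", "predicted"):
            raise ValueError(f"unknown profile source {self.source!r}")
        if self.normalized and len(self.values) and abs(self.values.max() - 1.0) > 1e-12:
            raise ValueError("normalized profile must have max exactly 1")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class TruncationRange:
    """Residues kept after terminal truncation.

    ``first_kept``/``last_kept`` are residue sequence numbers (inclusive);
    ``lnt``/``lct`` count the residues removed from the N- and C-terminus.
    """

    first_kept: int
    last_kept: int
    lnt: int
    lct: int

    def __post_init__(self) -> None:
        if self.first_kept > self.last_kept:
            raise ValueError("first_kept must not exceed last_kept")
        if self.lnt < 0 or self.lct < 0:
            raise ValueError("removed segment lengths must be non-negative")


def bfactor_to_rmsf(b):
    """RMSF (Å) from an isotropic B-factor (Å²): ``sqrt(3 B / 8 pi^2)``."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("B-factors must be non-negative")
    out = np.sqrt(b / _B_COEFF)
    return float(out) if out.ndim == 0 else out


def rmsf_to_bfactor(rmsf):
    """Inverse of :func:`bfactor_to_rmsf`: ``B = (8 pi^2 / 3) RMSF^2``."""
    rmsf = np.asarray(rmsf, dtype=float)
    if np.any(rmsf < 0):
        raise ValueError("RMSF must be non-negative")
    out = _B_COEFF * rmsf**2
    return float(out) if out.ndim == 0 else out


def xray_profile(structure: CalphaStructure) -> FluctProfile:
    """Experimental fluctuation profile of an X-ray structure.

    Applies the Debye-Waller relation element-wise to the Cα B-factor of
    every residue.
    """
    if structure.bfactors is None:
        raise MissingDataError(
            f"{structure.protein_id}: structure carries no B-factors"
        )
    return FluctProfile(
        protein_id=structure.protein_id,
        residue_numbers=structure.residue_numbers.copy(),
        values=bfactor_to_rmsf(structure.bfactors),
        source="xray",
    )


def truncate_termini(
    profile: FluctProfile,
    iterate: bool = False,
    threshold_sd: float = 1.0,
    ddof: int = 1,
) -> TruncationRange:
    """Determine the terminal residues to discard from a fluctuation profile.

    The mean ``m`` and standard deviation ``s`` of the profile are computed
    over the currently kept segment; residues are removed from the
    N-terminus inward while their value exceeds ``m + threshold_sd * s``
    (strictly), then likewise from the C-terminus.  Interior residues are
    never removed.  With ``iterate=True`` (the NMR convention) the pass is
    repeated on the kept segment until nothing more is removed or at most
    three residues remain; X-ray profiles use a single pass.

    ``ddof=1`` selects the sample standard deviation (n-1 denominator).

    Returns the :class:`TruncationRange`; raises
    :class:`TruncationDegenerateError` if every residue would be removed.
    """
    if len(profile) < 3:
        raise ValueError("truncation needs at least 3 residues")
    values = profile.values
    lo, hi = 0, len(values)  # kept half-open slice [lo, hi)
    while True:
        kept = values[lo:hi]
        m = kept.mean()
        s = kept.std(ddof=ddof) if len(kept) > ddof else 0.0
        thr = m + threshold_sd * s
        removed = 0
        while lo < hi and values[lo] > thr:
            lo += 1
            removed += 1
        while hi > lo and values[hi - 1] > thr:
            hi -= 1
            removed += 1
        if lo >= hi:
            raise TruncationDegenerateError(
                f"{profile.protein_id}: truncation removed the entire chain"
            )
        if not iterate or removed == 0 or hi - lo <= 3:
            break
    return TruncationRange(
        first_kept=int(profile.residue_numbers[lo]),
        last_kept=int(profile.residue_numbers[hi - 1]),
        lnt=lo,
        lct=len(values) - hi,
    )


def apply_truncation(profile: FluctProfile, rng: TruncationRange) -> FluctProfile:
    """Restrict a profile to the residues kept by a truncation range."""
    mask = (profile.residue_numbers >= rng.first_kept) & (
        profile.residue_numbers <= rng.last_kept
    )
    if not mask.any():
        raise AlignmentError(
            f"{profile.protein_id}: truncation range does not overlap the profile"
        )
    # removing the peak residue can drop the maximum below 1, so the
    # truncated profile is no longer normalized until renormalized
    return replace(
        profile,
        residue_numbers=profile.residue_numbers[mask],
        values=profile.values[mask],
        normalized=False,
    )


def normalize_profile(profile: FluctProfile) -> FluctProfile:
    """Divide a profile by its maximum so that the peak value is 1."""
    peak = profile.values.max() if len(profile) else 0.0
    if peak <= 0:
        raise NormalizationError(
            f"{profile.protein_id}: cannot normalize an all-zero profile"
        )
    return replace(profile, values=profile.values / peak, normalized=True)


def average_replicates(
    profiles: list[FluctProfile], normalize_first: bool = True
) -> FluctProfile:
    """Average replicate fluctuation profiles.

    With ``normalize_first=True`` each replicate is normalized to unit
    maximum before the element-wise mean is taken, and the mean is
    re-normalized; this keeps replicates with different absolute amplitudes
    on an equal footing.  All inputs must share the same residue numbering.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    ref = profiles[0]
    for p in profiles[1:]:
        if not np.array_equal(p.residue_numbers, ref.residue_numbers):
            raise AlignmentError(
                f"{ref.protein_id}: replicate profiles have mismatched residues"
            )
    if normalize_first:
        stack = np.stack([normalize_profile(p).values for p in profiles])
        mean = FluctProfile(
            protein_id=ref.protein_id,
            residue_numbers=ref.residue_numbers.copy(),
            values=stack.mean(axis=0),
            source=ref.source,
        )
        return normalize_profile(mean)
    stack = np.stack([p.values for p in profiles])
    return FluctProfile(
        protein_id=ref.protein_id,
        residue_numbers=ref.residue_numbers.copy(),
        values=stack.mean(axis=0),
        source=ref.source,
    )
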