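"""Reading and writing Cα traces from PDB text.

The whole pipeline operates on Cα coordinates only: the elastic-network
model, the ensemble RMSF and the B-factor conversion are all defined per
residue on the Cα atom.  This module extracts that reduced representation
from standard (possibly multi-model) PDB files and writes it back in a form
any PDB consumer accepts.

Parsing is delegated to :mod:`gemmi`; writing uses the fixed-column ATOM
record layout directly so the round-trip precision (3 decimals for
coordinates, 2 for B-factors) is explicit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .exceptions import (
    EnsembleConsistencyError,
    PDBParseError,
)

__all__ = ["CalphaStructure", "Ensemble", "read_calpha_ensemble", "write_ensemble_pdb"]


@dataclass
class CalphaStructure:
    """Ordered Cα trace of a single model.

    Parameters
    ----------
    protein_id
        Free-text label (PDB id, synthetic name, ...).
    chain_id
        One-character chain identifier.
    residue_numbers
        Strictly increasing PDB residue sequence numbers, shape ``(n,)``.
    coords
        Cα coordinates in Å, shape ``(n, 3)``.
    bfactors
        Per-residue isotropic B-factors in Å², shape ``(n,)``; ``None`` when
        the source carries no meaningful temperature factors (e.g. predicted
        models).
    """

    protein_id: str
    chain_id: str
    residue_numbers: np.ndarray
    coords: np.ndarray
    bfactors: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.bfactors is not None:
            self.bfactors = np.asarray(self.bfactors, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n, 3)")
        if len(self.residue_numbers) != len(self.coords):
            raise ValueError("residue_numbers and coords length mismatch")
        if self.bfactors is not None and len(self.bfactors) != len(self.coords):
            raise ValueError("bfactors and coords length mismatch")
        if np.any(np.diff(self.residue_numbers) <= 0):
            raise ValueError("residue_numbers must be strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_residues(self) -> int:
        return len(self.residue_numbers)

    def __len__(self) -> int:
        return self.n_residues


@dataclass
class Ensemble:
    """A batch of Cα models sharing one residue indexing.

    Represents an NMR ensemble, a set of simulation snapshots, or a replicate
    set of predicted models.  Every model must carry identical
    ``residue_numbers`` and ``chain_id``.
    """

    models: list[CalphaStructure] = field(default_factory=list)
    protein_id: str = ""

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("an Ensemble needs at least one model")
        ref = self.models[0]
        for m in self.models[1:]:
            if m.chain_id != ref.chain_id or not np.array_equal(
                m.residue_numbers, ref.residue_numbers
            ):
                raise EnsembleConsistencyError(
                    f"{self.protein_id}: models do not share an identical residue set"
                )

    @property
    def n_models(self) -> int:
        return len(self.models)

    @property
    def residue_numbers(self) -> np.ndarray:
        return self.models[0].residue_numbers

    @property
    def coords(self) -> np.ndarray:
        """All model coordinates stacked, shape ``(n_models, n_residues, 3)``."""
        return np.stack([m.coords for m in self.models])

    def __len__(self) -> int:
        return self.n_models


def _extract_ca(
    model: gemmi.Model, chain: str | None, protein_id: str
) -> CalphaStructure | None:
    """Pull the Cα trace of one gemmi model; None if the chain has no CA."""
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        resnums: list[int] = []
        coords: list[tuple[float, float, float]] = []
        bfs: list[float] = []
        for res in ch:
            if res.het_flag == "H":  # HETATM residues are not part of the trace
                continue
            if res.seqid.icode not in ("", " "):
                raise PDBParseError(
                    f"{protein_id}: insertion code {res.seqid.icode!r} at residue "
                    f"{res.seqid.num} is not supported; renumber the chain"
                )
            # altloc: keep the highest-occupancy CA, first wins on a tie
            best = None
            for atom in res:
                if atom.name != "CA" or atom.element != gemmi.Element("C"):
                    continue
                if best is None or atom.occ > best.occ:
                    best = atom
            if best is None:
                continue
            resnums.append(res.seqid.num)
            coords.append((best.pos.x, best.pos.y, best.pos.z))
            bfs.append(best.b_iso)
        if resnums:
            return CalphaStructure(
                protein_id=protein_id,
                chain_id=ch.name,
                residue_numbers=np.array(resnums),
                coords=np.array(coords),
                bfactors=np.array(bfs),
            )
        if chain is not None:
            break
    return None


def read_calpha_ensemble(
    pdb_text: str, chain: str | None = None, protein_id: str = ""
) -> Ensemble:
    """Parse PDB text into a Cα :class:`Ensemble`.

    One model is produced per MODEL/ENDMDL block; a file without MODEL
    records yields a single-model ensemble.  Only ATOM records with atom
    name ``CA`` are kept; alternate locations are resolved to the highest
    occupancy (first on a tie).  When ``chain`` is ``None`` the first chain
    containing Cα atoms is used.

    Raises
    ------
    PDBParseError
        If no Cα atoms are found on the requested chain.
    EnsembleConsistencyError
        If models disagree on the residue set.
    """
    structure = gemmi.read_pdb_string(pdb_text)
    models: list[CalphaStructure] = []
    resolved_chain = chain
    for gmodel in structure:
        cas = _extract_ca(gmodel, resolved_chain, protein_id)
        if cas is None:
            raise PDBParseError(
                f"{protein_id}: no CA atoms found"
                + (f" on chain {resolved_chain!r}" if resolved_chain else "")
            )
        if resolved_chain is None:
            resolved_chain = cas.chain_id  # lock onto the first chain seen
        models.append(cas)
    if not models:
        raise PDBParseError(f"{protein_id}: file contains no models")
    return Ensemble(models=models, protein_id=protein_id)


def _format_atom_line(
    serial: int, resnum: int, chain_id: str, xyz: np.ndarray, b: float
) -> str:
    # Fixed-column PDB ATOM record: coords %8.3f (cols 31-54), occ 55-60, B 61-66.
    return (
        f"ATOM  {serial:>5d}  CA  ALA {chain_id:1s}{resnum:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{b:6.2f}"
        f"           C  "
    )


def write_ensemble_pdb(ensemble: Ensemble) -> str:
    """Serialize an :class:`Ensemble` as multi-model PDB text.

    A single-model ensemble is written without MODEL/ENDMDL records.
    Coordinates are written at 3 decimals and B-factors at 2, the PDB
    fixed-width convention; absent B-factors are written as 0.00.
    """
    lines: list[str] = []
    multi = ensemble.n_models > 1
    for imodel, model in enumerate(ensemble.models, start=1):
        if multi:
            lines.append(f"MODEL     {imodel:>4d}")
        bfs = (
            model.bfactors
            if model.bfactors is not None
            else np.zeros(model.n_residues)
        )
        for serial, (resnum, xyz, b) in enumerate(
            zip(model.residue_numbers, model.coords, bfs), start=1
        ):
            lines.append(
                _format_atom_line(serial, int(resnum), model.chain_id, xyz, float(b))
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
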