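import numpy as np
import pytest

from flexbench.structio import CalphaStructure, Ensemble


def make_pdb_text(
    models: list[np.ndarray],
    bfactors: list[np.ndarray] | None = None,
    chain: str = "A",
    with_model_records: bool = True,
    resnums: list[int] | None = None,
) -> str:
    """Hand-roll PDB text for fixtures, independent of the package writer."""
    lines = []
    for im, coords in enumerate(models, start=1):
        if with_model_records:
            lines.append(f"MODEL     {im:>4d}")
        nums = resnums if resnums is not None else range(1, len(coords) + 1)
        for serial, (rn, xyz) in enumerate(zip(nums, coords), start=1):
            b = 0.0 if bfactors is None else float(bfactors[im - 1][serial - 1])
            lines.append(
                f"ATOM  {serial:>5d}  CA  GLY {chain}{rn:>4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00{b:6.2f}"
                f"           C  "
            )
        if with_model_records:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def random_coords(n: int, rng: np.random.Generator, scale: float = 10.0) -> np.ndarray:
    return rng.uniform(-scale, scale, size=(n, 3))


def structure_from(coords, bfactors=None, protein_id="test", chain="A"):
    coords = np.asarray(coords, dtype=float)
    return CalphaStructure(
        protein_id=protein_id,
        chain_id=chain,
        residue_numbers=np.arange(1, len(coords) + 1),
        coords=coords,
        bfactors=None if bfactors is None else np.asarray(bfactors, dtype=float),
    )


def ensemble_from(model_coords, protein_id="test"):
    return Ensemble(
        models=[structure_from(c, protein_id=protein_id) for c in model_coords],
        protein_id=protein_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
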