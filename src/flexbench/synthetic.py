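"""Synthetic inputs with known ground truth.

Every input the pipeline consumes can be generated here: idealized Cα
traces (helix, strand, mixed, self-avoiding random walk), multi-model
ensembles whose per-residue scatter follows a prescribed σ-profile,
X-ray-style single-model structures whose B-factor column encodes a
prescribed RMSF profile, and complete benchmark directories (experimental
file + replicate predicted ensembles per simulated method + truth table).

The σ-profiles emulate two robust features of real flexibility data: the
chain termini fluctuate several-fold more than the core (a multiplicative
ramp over the terminal residues), and the core itself is not flat — loops
are softer than secondary-structure elements (a smooth log-normal
modulation along the chain).  A simulated prediction method of fidelity f
samples its ensembles from ``f * σ_true + (1 - f) * σ_noise``, where
σ_noise is an independent random profile, so f = 1 reproduces the truth up
to sampling error and f = 0 is uninformative.

All generators draw from a single :class:`numpy.random.Generator` stream
per call and are bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .profiles import rmsf_to_bfactor
from .structio import CalphaStructure, Ensemble, write_ensemble_pdb

__all__ = [
    "SyntheticSpec",
    "BenchmarkFiles",
    "make_trace",
    "terminal_ramp",
    "make_sigma_profile",
    "make_ensemble",
    "make_xray_structure",
    "make_benchmark",
]

FOLDS = ("helix", "strand", "mixed", "random_walk")
CLASS_FOLD = {"alpha": "helix", "beta": "strand", "alpha_beta": "mixed"}

# canonical Cα helix geometry: 1.5 Å rise, 100 deg turn, 2.3 Å radius
_HELIX_RISE = 1.5
_HELIX_TURN = np.deg2rad(100.0)
_HELIX_RADIUS = 2.3
_CA_STEP = 3.8  # Å, virtual Cα-Cα bond
# beta fold: an antiparallel meander sheet of extended strands; a compact,
# non-planar arrangement (a single extended strand would be a quasi-1D
# mechanism under a central-force network)
_STRAND_RISE = 3.8  # fully extended step along the strand axis
_SHEET_SPACING = 4.6  # Å between adjacent strand axes
_SHEET_CORRUGATION = 1.5  # Å out-of-plane corrugation amplitude across strands
_SHEET_CORRUGATION_FREQ = 0.9  # rad per strand
_STRAND_LEN = 9  # residues per strand in the meander


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic protein and its ensembles."""

    n_residues: int = 60
    fold: str = "helix"
    sigma_core: float = 0.4  # Å, per-coordinate Gaussian scatter of the core
    terminal_boost: float = 3.0  # terminal/core fluctuation ratio
    terminal_length: int = 6  # residues per terminus under the ramp
    n_models: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 5:
            raise ValueError("need at least 5 residues")
        if self.sigma_core <= 0:
            raise ValueError("sigma_core must be positive")
        if self.terminal_boost < 1:
            raise ValueError("terminal_boost must be >= 1")
        if self.terminal_length >= self.n_residues / 2:
            raise ValueError("terminal_length must be < n_residues / 2")
        if self.fold not in FOLDS:
            raise ValueError(f"fold must be one of {FOLDS}")


def _helix_coords(n: int) -> np.ndarray:
    k = np.arange(n)
    return np.column_stack(
        [
            _HELIX_RADIUS * np.cos(k * _HELIX_TURN),
            _HELIX_RADIUS * np.sin(k * _HELIX_TURN),
            _HELIX_RISE * k,
        ]
    )


def _sheet_coords(n: int) -> np.ndarray:
    """Antiparallel beta-meander: strands along ±z, one turn residue between
    consecutive strands, and a sinusoidal corrugation across the sheet for
    non-planarity.  All consecutive Cα-Cα distances equal ``_CA_STEP``."""
    unit = _STRAND_LEN + 1  # strand residues + one turn residue
    n_strands = max(2, int(np.ceil((n + 1) / unit)))
    z_top = (_STRAND_LEN - 1) * _STRAND_RISE
    pts: list[np.ndarray] = []
    for k in range(n_strands):
        x = _SHEET_SPACING * k
        y = _SHEET_CORRUGATION * np.sin(_SHEET_CORRUGATION_FREQ * k)
        zs = np.arange(_STRAND_LEN) * _STRAND_RISE
        if k % 2:
            zs = zs[::-1]
        strand = [np.array([x, y, z]) for z in zs]
        if pts:
            prev = pts[-1]
            first = strand[0]
            dx, dy = first[0] - prev[0], first[1] - prev[1]
            h = np.sqrt(_CA_STEP**2 - (dx / 2) ** 2 - (dy / 2) ** 2)
            bulge = 1.0 if prev[2] > z_top / 2 else -1.0
            pts.append(
                np.array([prev[0] + dx / 2, prev[1] + dy / 2, prev[2] + bulge * h])
            )
        pts.extend(strand)
        if len(pts) >= n:
            break
    return np.array(pts[:n])


def _mixed_coords(n: int) -> np.ndarray:
    """Helix packed against a beta sheet.  The sheet is attached one bond
    beyond the helix end and runs back down alongside the helix (radially
    outward strands), so the two elements share contacts along their whole
    length and the assembly is rigid."""
    n1 = n // 2
    helix = _helix_coords(n1)
    sheet = _sheet_coords(n - n1)
    end = helix[-1]
    rho = np.array([end[0], end[1], 0.0])
    rho /= np.linalg.norm(rho)  # radial direction at the helix end
    down = np.array([0.0, 0.0, -1.0])
    tang = np.cross(down, rho)
    u = (rho + np.array([0.0, 0.0, 1.0])) / np.sqrt(2.0)
    origin = end + _CA_STEP * u
    local = sheet - sheet[0]
    placed = (
        origin
        + np.outer(local[:, 0], rho)
        + np.outer(local[:, 1], tang)
        + np.outer(local[:, 2], down)
    )
    return np.vstack([helix, placed])


def _random_walk_coords(n: int, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding walk with fixed 3.8 Å steps (3 Å exclusion)."""
    pts = [np.zeros(3)]
    while len(pts) < n:
        for _ in range(200):
            v = rng.normal(size=3)
            v *= _CA_STEP / np.linalg.norm(v)
            cand = pts[-1] + v
            prior = np.array(pts[:-1]) if len(pts) > 1 else None
            if prior is None or np.min(
                np.linalg.norm(prior - cand, axis=1)
            ) >= 3.0:
                pts.append(cand)
                break
        else:  # dead end: back up one step and retry
            pts.pop()
            if not pts:
                pts = [np.zeros(3)]
    return np.array(pts)


def make_trace(spec: SyntheticSpec, protein_id: str = "synthetic") -> CalphaStructure:
    """Idealized Cα trace for one synthetic protein.

    Consecutive Cα-Cα distances fall in [3.7, 3.9] Å for every fold;
    deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    if spec.fold == "helix":
        coords = _helix_coords(n)
    elif spec.fold == "strand":
        coords = _sheet_coords(n)
    elif spec.fold == "mixed":
        coords = _mixed_coords(n)
    else:
        coords = _random_walk_coords(n, rng)
    return CalphaStructure(
        protein_id=protein_id,
        chain_id="A",
        residue_numbers=np.arange(1, n + 1),
        coords=coords,
        bfactors=None,
    )


def terminal_ramp(
    n: int, terminal_boost: float, terminal_length: int
) -> np.ndarray:
    """Multiplicative terminal-flexibility factors.

    Equal to ``terminal_boost`` at the chain ends, decaying linearly to 1
    over ``terminal_length`` residues, and 1 in the core.
    """
    factors = np.ones(n)
    L = terminal_length
    if L > 0:
        ramp = terminal_boost - (terminal_boost - 1.0) * np.arange(L) / L
        factors[:L] = ramp
        factors[-L:] = ramp[::-1]
    return factors


def make_sigma_profile(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    roughness: float = 0.5,
    corr_length: int = 5,
) -> np.ndarray:
    """Per-residue σ-profile: boosted termini over a loop-like rough core.

    The core is ``sigma_core * exp(roughness * z)`` with ``z`` a smooth
    standardized Gaussian field of correlation length ``corr_length``
    residues; ``roughness = 0`` gives a flat core.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    core = np.full(n, spec.sigma_core)
    if roughness > 0:
        half = 3 * corr_length
        kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / corr_length) ** 2)
        padded = rng.normal(size=n + 2 * half)
        smooth = np.convolve(padded, kernel, mode="valid")
        smooth = (smooth - smooth.mean()) / smooth.std()
        core = core * np.exp(roughness * smooth)
    return core * terminal_ramp(n, spec.terminal_boost, spec.terminal_length)


def make_ensemble(
    reference: CalphaStructure,
    sigma_profile: np.ndarray,
    n_models: int,
    seed: int | np.random.Generator = 0,
) -> Ensemble:
    """Gaussian ensemble around a reference trace.

    Each model adds independent isotropic per-residue Gaussian noise with
    the given σ_i to the reference and is then subjected to a random global
    rigid motion (so downstream superposition is actually exercised).
    """
    sigma_profile = np.asarray(sigma_profile, dtype=float)
    if len(sigma_profile) != reference.n_residues:
        raise ValueError("sigma_profile length must match the reference")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    models = []
    for _ in range(n_models):
        noise = rng.normal(size=(reference.n_residues, 3)) * sigma_profile[:, None]
        coords = reference.coords + noise
        quat = rng.normal(size=4)
        R = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
        t = rng.uniform(-20.0, 20.0, size=3)
        models.append(
            CalphaStructure(
                protein_id=reference.protein_id,
                chain_id=reference.chain_id,
                residue_numbers=reference.residue_numbers.copy(),
                coords=coords @ R.T + t,
                bfactors=None,
            )
        )
    return Ensemble(models=models, protein_id=reference.protein_id)


def make_xray_structure(
    reference: CalphaStructure, rmsf_profile: np.ndarray
) -> CalphaStructure:
    """X-ray-style structure whose B-factor column encodes an RMSF profile
    through the Debye-Waller relation ``B = (8 pi^2 / 3) RMSF^2``."""
    rmsf_profile = np.asarray(rmsf_profile, dtype=float)
    if len(rmsf_profile) != reference.n_residues:
        raise ValueError("rmsf_profile length must match the reference")
    if np.any(rmsf_profile < 0):
        raise ValueError("RMSF profile must be non-negative")
    return CalphaStructure(
        protein_id=reference.protein_id,
        chain_id=reference.chain_id,
        residue_numbers=reference.residue_numbers.copy(),
        coords=reference.coords.copy(),
        bfactors=rmsf_to_bfactor(rmsf_profile),
    )


@dataclass
class BenchmarkFiles:
    """Locations of a generated synthetic benchmark."""

    out_dir: Path
    manifest_path: Path
    truth_path: Path


def _allocate(n: int, fractions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n items to labelled fractions."""
    total = sum(fractions.values())
    raw = {k: n * v / total for k, v in fractions.items()}
    counts = {k: int(np.floor(r)) for k, r in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def make_benchmark(
    n_proteins: int,
    out_dir: str | Path,
    seed: int = 0,
    class_mix: dict[str, float] | None = None,
    expt_mix: dict[str, float] | None = None,
    methods: dict[str, float] | None = None,
    n_models: int = 25,
    n_replicates: int = 3,
    length_range: tuple[int, int] = (40, 80),
    sigma_core: float = 0.4,
    terminal_boost: float = 3.0,
    terminal_length: int = 6,
    roughness: float = 0.5,
) -> BenchmarkFiles:
    """Generate a complete synthetic benchmark on disk.

    Per protein: a reference trace (fold chosen by secondary-structure
    class), an experimental input (multi-model NMR-style ensemble or
    single-model X-ray-style structure with encoded B-factors), and
    ``n_replicates`` predicted ensembles per simulated method, whose
    fidelity f in [0, 1] mixes the true σ-profile with an independent
    noise profile.  Writes all PDB files plus ``manifest.csv`` (pipeline
    input) and ``truth.csv`` (generating parameters) to ``out_dir``.
    """
    if n_proteins < 4:
        raise ValueError("a benchmark needs at least 4 proteins")
    class_mix = class_mix or {"alpha": 0.30, "beta": 0.21, "alpha_beta": 0.49}
    expt_mix = expt_mix or {"nmr": 0.5, "xray": 0.5}
    methods = methods or {"high_fidelity": 0.9, "low_fidelity": 0.3}
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    class_counts = _allocate(n_proteins, class_mix)
    expt_counts = _allocate(n_proteins, expt_mix)
    classes = [c for c in sorted(class_counts) for _ in range(class_counts[c])]
    expts = [e for e in sorted(expt_counts) for _ in range(expt_counts[e])]
    rng.shuffle(expts)  # decorrelate class and experiment assignment

    manifest_rows = []
    truth_rows = []
    for idx, (ss_class, expt) in enumerate(zip(classes, expts)):
        pid = f"syn{idx:03d}"
        n_res = int(rng.integers(length_range[0], length_range[1] + 1))
        spec = SyntheticSpec(
            n_residues=n_res,
            fold=CLASS_FOLD[ss_class],
            sigma_core=sigma_core,
            terminal_boost=terminal_boost,
            terminal_length=terminal_length,
            n_models=n_models,
            seed=int(rng.integers(2**31)),
        )
        reference = make_trace(spec, protein_id=pid)
        sigma_true = make_sigma_profile(spec, rng=rng, roughness=roughness)

        expt_path = out_dir / f"{pid}_expt.pdb"
        if expt == "nmr":
            ens = make_ensemble(reference, sigma_true, n_models, seed=rng)
            expt_path.write_text(write_ensemble_pdb(ens))
        else:
            xray = make_xray_structure(reference, np.sqrt(3.0) * sigma_true)
            expt_path.write_text(
                write_ensemble_pdb(Ensemble(models=[xray], protein_id=pid))
            )

        for method, fidelity in methods.items():
            noise = make_sigma_profile(spec, rng=rng, roughness=max(roughness, 0.3))
            sigma_method = fidelity * sigma_true + (1.0 - fidelity) * noise
            rep_paths = []
            for rep in range(1, n_replicates + 1):
                ens = make_ensemble(reference, sigma_method, n_models, seed=rng)
                path = out_dir / f"{pid}_{method}_rep{rep}.pdb"
                path.write_text(write_ensemble_pdb(ens))
                rep_paths.append(path.name)
            manifest_rows.append(
                {
                    "protein_id": pid,
                    "expt_method": expt,
                    "ss_class": ss_class,
                    "experimental_path": expt_path.name,
                    "method": method,
                    "predicted_paths": ";".join(rep_paths),
                }
            )
            truth_rows.append(
                {
                    "protein_id": pid,
                    "ss_class": ss_class,
                    "expt_method": expt,
                    "n_residues": n_res,
                    "method": method,
                    "fidelity": fidelity,
                    "sigma_true": ";".join(f"{s:.6g}" for s in sigma_true),
                }
            )

    manifest_path = out_dir / "manifest.csv"
    truth_path = out_dir / "truth.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False)
    return BenchmarkFiles(
        out_dir=out_dir, manifest_path=manifest_path, truth_path=truth_path
    )
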