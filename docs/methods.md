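# Methods

This note documents the models, conventions and numerical choices behind
`flexbench`, and what its synthetic validation does and does not
demonstrate about real data.

## Fluctuation profiles

**Ensemble RMSF.**  Given an ensemble of M Cα models (an NMR deposition
or simulation snapshots), all models are superposed on the first model
and averaged; models are then re-superposed on the average and
re-averaged until two successive means differ by less than 1e-6 Å RMSD
(at most 10 iterations — coherent ensembles converge in two or three).
The RMSF of residue i is the root mean square deviation of its position
from the converged mean, with every model superposed on that mean and M
(not M−1) in the denominator: the profile is a population average over
snapshots, not a sample estimate of a hypothetical larger ensemble.
Superposition is unweighted Kabsch (SVD with the proper-rotation
constraint); reflections are excluded.

Two intrinsic properties of this protocol matter when checking it
against generated data:

* *Fit absorption.*  Fitting 6 rigid degrees of freedom to 3N
  coordinates absorbs a fraction of order 6/(3N) of the fluctuation
  variance, unevenly — residues far from the centroid lose more.  For a
  30-residue chain the resulting downward bias in RMSF reaches ~9% at
  the termini; at N ≈ 100–150 it drops below ~2.5%.  The bias is
  scale-free in σ: it cannot be reduced by making fluctuations smaller.
* *Sampling noise.*  With M models the relative standard error of one
  residue's RMSF is 1/sqrt(6M) ≈ 1.3% at M = 1000.  The maximum error
  over 100+ residues therefore approaches 4% even for a perfect
  estimator, which is why the recovery checks average replicate
  ensembles before asserting a 5% per-residue bound.

**X-ray profiles.**  The isotropic Debye–Waller relation
B = (8π²/3)·RMSF² applied to the Cα B-factor of each residue.  No
rigid-body disorder correction is applied; the benchmark statistics are
relative comparisons between methods on the same structures, for which a
common monotone distortion of the experimental profile is immaterial.

**Terminal truncation.**  Over the kept segment the mean m and sample
standard deviation s (n−1 denominator, configurable) of the profile are
computed; residues are removed from the N-terminus inward while their
value strictly exceeds m + 1·s, then likewise from the C-terminus.
Interior residues are never removed.  NMR profiles iterate this pass on
the kept segment until nothing is removed or only three residues remain;
X-ray profiles use a single pass.  The threshold multiplier and the SD
convention are exposed in the API; the range is determined from the
experimental profile only and applied unchanged to every prediction
method for that protein, so all methods are scored on identical
residues.  With a strict inequality at +1 SD the minimum of the profile
always survives a pass, so complete removal is impossible under the
default settings; the degenerate-range guard exists for pathological
configurations (e.g. negative multipliers).

**Normalization and replicate averaging.**  Profiles are divided by
their maximum (RMSFN, peak = 1).  Both correlation coefficients are
invariant under positive rescaling of either profile, so the choice of
normalization constant cannot affect any benchmark statistic; it only
fixes the scale for plotting and averaging.  Replicate trajectories are
normalized first, averaged element-wise, and the mean re-normalized —
this keeps replicates with different absolute amplitudes on an equal
footing.  Averaging before normalizing is available as an option.

## The elastic-network predictor

The potential is harmonic in inter-residue distances: identical springs
of constant γ connect all Cα pairs within a cutoff, anchored at their
reference distances.  The Hessian at the reference is assembled from
3×3 blocks −γ r̂ r̂ᵀ per contact (r̂ the unit inter-residue vector), with
diagonal blocks closing each row to zero — translational invariance is
exact by construction.  A connected, non-collinear network has exactly
six zero modes; eigenvalues below 1e-8 of the largest are classified as
zero, more than six raise a disconnection error (overridable), fewer a
tolerance error.  The per-residue mean-square fluctuation is the mode
sum Σ λ⁻¹|v_i|² over non-rigid modes, equal to the trace of the
corresponding 3×3 diagonal block of the Hessian pseudo-inverse (the test
suite enforces this identity at 1e-8 relative).

Defaults: cutoff 12 Å (standard for Cα anisotropic networks; the value
is exposed because no single cutoff suits all coarse-grainings), γ = 1
and unit amplitude (both cancel after normalization, so only the shape
of the profile is ever compared).  Rigid-block projections, nonlinear
mode extrapolation and contact-energy-weighted springs are out of scope.

## Comparison statistics

Pearson's r_p uses the product-moment formula over shared residues;
Spearman's r_s uses the rank-difference shortcut 1 − 6Σd²/(n(n²−1))
when all ranks are distinct and the product-moment correlation of
average ranks otherwise (the two coincide without ties).  Skewness is
the population moment ratio g₁ = m₃/m₂^{3/2}; the normalization
convention only rescales values slightly and cannot change signs or
orderings.  Histograms use left-closed 0.1 bins on [−1, 1] with the
final bin closed; the cumulative distribution is the right-continuous
count of coefficients not exceeding x.

**ANOVA.**  Fixed-effects two-way ANOVA (prediction method ×
secondary-structure class) with interaction, run separately per
structure-determination method because NMR- and B-factor-derived
profiles measure physically different quantities.  Type II sums of
squares are computed by model comparison (each main effect against the
model containing the other; the interaction against the additive model)
with degrees of freedom from design-matrix ranks, so unbalanced class
sizes are handled without ambiguity; on balanced designs this reduces
exactly to the classical decomposition, and the implementation is
cross-checked against an independent general-linear-model route in the
test suite.  Null calibration at α = 0.05 is verified on 2000 simulated
null datasets.

**Pairwise tests.**  Student's t on per-protein coefficient differences,
paired by default because the same proteins are scored under every
method (an unpaired equal-variance/Welch fallback is available).  The
significance matrix reports, for each ordered method pair, the sign of
the mean difference (row minus column) and whether p < α, with r_p in
the upper triangle and r_s in the lower.  No multiple-testing correction
is applied across cells: the matrix reports raw per-pair calls.  An
identically zero difference vector is reported as t = 0, p = 1; a
nonzero constant difference has no within-pair variance and is an error.

## Synthetic data

The generator emulates the features of real flexibility data that the
pipeline must handle, with defaults chosen once as desk-scale analogs of
a ~100-protein benchmark:

* **Folds.**  Helix: canonical Cα geometry (rise 1.5 Å, turn 100°,
  radius 2.3 Å).  "Strand" class: an antiparallel β-meander —
  9-residue extended strands 4.6 Å apart with one turn residue between
  strands and a sinusoidal out-of-plane corrugation.  A single extended
  strand, or a perfectly planar sheet, is an exact mechanism under a
  central-force network (zero transverse stiffness), so compactness and
  non-planarity are structural requirements, not cosmetics.  Mixed:
  a helix with the meander packed back alongside it so the two elements
  share contacts along their length.  Random walk: self-avoiding 3.8 Å
  steps with a 3 Å exclusion.  All folds keep consecutive Cα–Cα
  distances in [3.7, 3.9] Å and yield exactly six zero modes for chains
  of 40–150 residues.
* **σ-profiles.**  Per-residue Gaussian scatter σ_i = core × ramp:
  the core is 0.4 Å modulated by a smooth log-normal field (correlation
  length 5 residues, roughness 0.5) standing in for loop/secondary-
  structure contrast; the ramp multiplies the terminal 6 residues up to
  3× at the chain ends, emulating the dominant terminal fluctuations the
  truncation stage must remove.
* **Ensembles.**  Models are the reference plus independent isotropic
  per-residue noise, each given a random global rigid motion so that
  superposition is genuinely exercised.  NMR-style ensembles and
  predicted replicates default to 25 models, 3 replicates per method.
* **Simulated methods.**  A method of fidelity f samples its ensembles
  from f·σ_true + (1−f)·σ_noise, with σ_noise an independent profile
  sharing the terminal ramp: f = 1 reproduces the truth up to sampling
  error, f = 0 is uninformative, and the default pair (0.9, 0.3) gives a
  separation that a 30-protein benchmark resolves decisively.
* **Benchmarks.**  Chain lengths uniform on 40–80 residues; class mix
  30% α / 21% β / 49% α+β; half NMR, half X-ray.  All generators draw
  from one seeded stream per call and are bit-reproducible.

What passing these tests shows: the pipeline's bookkeeping, geometry,
spectral computation and statistics are correct, calibrated and
deterministic, and the end-to-end chain recovers known ground truth.
What it does not show: anything about the physical accuracy of any
particular force field or elastic-network parameterization on real
proteins — synthetic ensembles are isotropic, harmonic and uncorrelated
between residues, whereas real fluctuations are anisotropic, correlated
along the chain and coupled to solvent and crystal environment.

## Numerical conventions

Coordinates are written to PDB fixed-width fields (3 decimals; round
trips are exact to 5e-4 Å) and B-factors to 2 decimals.  Residue
identity is (chain, residue number); insertion codes are rejected rather
than silently misaligned; alternate locations resolve to the highest
occupancy, first on ties; HETATM records are ignored.  Profiles are
matched by residue number, never by positional index.  Mean-structure
iteration stops at 1e-6 Å; zero-mode classification at 1e-8 relative;
batch CSV output is written at 6 significant digits so reruns are
byte-comparable.  Proteins whose evaluation fails (degenerate
truncation, constant profiles, disconnected networks) are excluded from
the batch with a logged reason rather than aborting the run.

## Validation problem sizes

The shipped checks use: 20 random-walk networks of 10–30 residues for
the pseudo-inverse identity; four replicate 1000-model ensembles on a
120-residue meander for fluctuation recovery (see the bias/noise
analysis above for why replicates are averaged); 2000 null datasets of
32 proteins × 4 methods for ANOVA calibration; and 30-protein synthetic
benchmarks for the self-consistency and method-separation checks.
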