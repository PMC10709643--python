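# Methods

## Equilibrium model

The only species considered are the free monomer M and the tetramer T
(`T ⇌ 4 M`); SEC of this system shows no dimers or trimers, and the package
deliberately does not implement intermediate-species models.  The
dissociation constant is stored dimensionless against a 1 M standard state,
numerically equal to the conventional value in M³.

Peak-area fractions are interpreted as monomer-equivalent **mass** fractions:
the A280 extinction per unit mass is the same for monomer and tetramer of one
chain, so `[M] = f·c` and `[T] = (1−f)·c/4` for total monomer-equivalent
concentration *c*.  This convention is what makes a 4:96 ratio at 300 µM give
K_D ≈ 2.9 × 10⁻¹⁶ M³.

Speciation at given (K, c) is the unique root of the strictly increasing
`g([M]) = [M] + 4[M]⁴/K − c` on (0, c], found by bracketed Brent iteration
(machine-precision rtol) with a short Newton polish; there is no dependence
on an initial guess.  When `4c⁴/K` underflows the solver returns the fully
dissociated state directly.

## Thermodynamic model

ΔG° is per mole of tetramer for the dissociation direction, matching
K = [M]⁴/[T]. With ΔC°p constant the enthalpy and entropy integrals close to
`ΔH° = ΔC°p(T − T_h)` and `ΔS° = ΔC°p ln(T/T_s)`, and
`ΔG°(T) = ΔC°p(1 + ln T_s)T − ΔC°p T ln T − ΔC°p T_h`, which satisfies
ΔG = ΔH − TΔS identically (property-tested on 1000 random parameter draws)
and is maximal at T = T_s when ΔC°p > 0.

The fit minimizes `Σ wᵢ(ΔGᵢ − model(Tᵢ))²` with wᵢ = 1/σᵢ² when
uncertainties are supplied.  Initialization is closed-form from the data:
T_s from the location of the ΔG° maximum, ΔC°p from the curvature of a
quadratic pre-fit through `ΔG″ = −ΔC°p/T` at mid-range, and T_h from
`ΔG°(T_s) = ΔC°p(T_s − T_h)`.  Bounds ΔC°p ∈ (0, 100] kcal/mol/K and
T_h, T_s ∈ [200, 400] K keep the parameters physically sensible and the
logarithms defined; convergence tolerances are 1e-12 with a 10 000-evaluation
cap, and non-convergence is reported as an explicit failure flag.

Units: energies kcal/mol, R = 1.9872 × 10⁻³ kcal/mol/K.  Temperatures are °C
at every user-facing boundary (CSV, config, CLI) and Kelvin internally.

Known inconsistency in the source numbers: the published ΔS° range
"−0.02–0.02 kcal/K/mol" cannot be reconstructed from ΔC°p = 0.78 and
T_s = 29 °C over 4–45 °C (the closed form gives −0.067 to +0.040), and the
variable-domain parameter triplet (0.84, 24 °C, −1 °C) yields negative ΔH°
at 4 °C unless T_h and T_s are interchanged.  The package computes the
closed forms faithfully and takes no side; only the enthalpy upper bound
(34 kcal/mol at 45 °C), which does reconstruct, is used as a check.

## SEC peak deconvolution

Chromatograms are decomposed into n Gaussians plus a jointly fitted *linear*
baseline (reduces to constant when the slope is ~0; robust to drift).
Default initialization is deterministic: local maxima of the trace after a
5-sample moving average, accepted tallest-first while suppressing any
candidate inside the half-maximum region of an already accepted peak (noise
on a broad peak otherwise spawns several spurious maxima on its crown);
widths start from the half-width at half-maximum.  Species assignment is by
elution order — the tetramer elutes first (≈13.1 mL), the monomer last
(≈16.4 mL) — so `f_mono` is the relative area of the latest-eluting peak.
Areas are `amplitude·σ·√(2π)`; trapezoidal integration on the native grid is
used only for validation.  Whether published area ratios were taken before
or after baseline subtraction is generally unstated; this implementation
always fits and reports the baseline.

Two-state CD unmixing solves `S = f·B_mono + (1−f)·B_tet` for the two basis
spectra per wavelength (2×2 solve); compositions closer than 0.05 in f are
rejected as singular.

## Kinetics

The mass-action ODE `d[T]/dt = k_on[M]⁴ − k_off[T]` (with [M] eliminated by
conservation) is integrated with adaptive LSODA at rtol 1e-9 and
atol 1e-12·c, and serves as the simulator and oracle.  The primary estimator
stays a bare exponential, `f(t) = f_eq + (f0 − f_eq)e^{−t/τ}` with f0, f_eq
constrained to [0, 1], because reported "rate constants" for such systems
rarely state a definition; both 1/τ and the linearized
`k_off = 1/(τ(1 + 16[M]_eq³/K))` are exposed and neither is asserted as the
published definition.  The linearization is quantitatively valid only for
perturbations of a few percent — the quartic association term makes even a
10% tetramer-fraction jump visibly nonlinear — and the tests check the 5%
agreement in that small-perturbation regime.

## Structure analysis

*Hydrogen bonds* are polar heavy-atom pairs (N, O, S; carbon excluded) under
a 3.5 Å distance cutoff, with no angle criterion, because distance-only
census is the most defensible reading when no hydrogen positions or angle
thresholds are given.  Pairs within one residue and water–water pairs are
excluded; waters are excluded from interface counts by default (flag to
include).  The full bond list is always returned so that counts under this
definition are auditable; counts are sensitive to the definition, and any
mismatch against published counts should be inspected via the list, not
hidden.  Symmetry mates are never generated — analysis is restricted to the
deposited asymmetric-unit chains.

*Selections* are `chain` or `chain:first-last`, inclusive, honoring Kabat
insertion codes (`A:27d-34`).  Alternate locations resolve to the highest
occupancy, first on tie.

*Kabsch superposition* uses the SVD closed form with the determinant
correction (proper rotations only); degenerate inputs (<3 points, collinear
sets) are rejected.  An independent seeded quaternion-search oracle backs the
tests.

*Swap detection*: for each residue, the interchain contact fraction is
(interchain heavy-atom contacts)/(all non-local contacts), where non-local
excludes sequence neighbors within ±2; after 3-residue median smoothing, the
swapped segment is the longest terminal run (≥5 residues, fraction > 0.5),
and the hinge is the stretch between that run and the nearest preceding run
of residues below 0.25.  Thresholds are package choices: 0.5 marks "packs
mostly against the partner chain", 0.25 marks "clearly packs against its own
chain", and the band in between is structurally ambiguous — exactly where a
hinge lives.  Finding no segment is a valid result, not an error.

*Framework RMSD* groups the Kabat framework regions as FR1+FR2+FR3 (before
the hinge) and FR4 (after it), Cα only; residues missing from either
structure are listed, never silently dropped.

*Assembly bookkeeping* is the plain difference `G(complex) − Σ G(components)`
for combining externally computed free energies (e.g. solvation-theory
outputs for a tetramer vs two dimers).

## Synthetic data

The generators emulate the study conditions at desk scale and carry their
ground truth: thermodynamic parameters (0.78 kcal/mol/K, T_h = 1 °C,
T_s = 29 °C), temperatures 4–45 °C, concentrations 3–300 µM, SEC peaks at
13.1/16.4 mL (σ = 0.35 mL), a 300 µM stock diluted 50-fold for kinetics,
and relaxation times anchored at 13.5 h (4 °C) and 0.3 h (45 °C).

Measurement noise on equilibrium ratios is applied as independent Gaussian
*relative* perturbations of the monomer and tetramer peak areas (default 3%
each), not as additive noise on the fraction: area errors are approximately
scale-proportional in practice, which makes the fraction uncertainty vanish
toward 0 and 1 and reproduces a K_D dispersion of roughly ±15% across
concentrations, the level such tables typically show.  Additive fraction
noise would instead imply errors of order 100% in K_D at the extreme
operating points.

Rate constants are calibrated so that an exponential fit of the *simulated*
50-fold dilution jump reproduces the anchor relaxation times (scalar
root-find on k_off at the two anchor temperatures, log-linear interpolation
in 1/T in between, k_on = k_off/K(T) by detailed balance).  Calibrating on
the linearized τ instead would miss the anchors by a factor ≈2.5, because
the dilution jump is far outside linear response.

Toy structures are built, not sampled: a two-chain β-ladder whose only
cross-chain polar contacts are five declared N–O pairs at exactly 2.9 Å; an
unswapped dimer (two separated compact folds, each tail docked on its own
core); and a swapped dimer in which the 6-residue C-terminal tails are
exchanged between the folds, so residues 25–30 of each chain contact only
the partner chain.  Geometry guarantees the declared truths under the
package's contact definitions.

A single root seed derives an independent stream per artifact (CRC-32 of the
artifact name mixed into the seed sequence), so adding a generator never
perturbs existing ones; fixed seed means bitwise-identical artifacts.

What the synthetic data does **not** emulate: detector artifacts (injection
spikes, pump pulsation), tailing/EMG peak shapes, column calibration,
realistic protein geometry beyond what the structure operations probe, and
temperature-dependent ΔC°p.  Passing recovery tests therefore demonstrates
correctness of the estimators under the stated noise model, not robustness
to every artifact of real chromatograms.

## Problem sizes and determinism

Default synthetic runs use 7 temperatures × 5 concentrations for the
thermodynamic fit, 25 time points per relaxation trace, 1601-point
chromatogram grids, and ≤100-replicate recovery studies; these sizes keep a
full pipeline run under a few seconds while leaving the estimators
statistically non-trivial.  All randomness flows from explicit integer
seeds; reruns with the same configuration are byte-identical in the numeric
report sections.

## Known limitations

* Hydrogen-bond counts depend on the N/O/S distance-only definition; no
  DSSP-style energetics or angle criteria.
* The exponential relaxation estimator is biased for large jumps (that bias
  is intrinsic to the estimator, and shared by the published analysis
  convention it mirrors).
* The thermodynamic fit assumes uncorrelated, homoscedastic ΔG° errors per
  temperature unless σ values are supplied.
* Dimer or higher-order intermediates, activity corrections, pressure
  dependence and temperature-dependent ΔC°p are out of scope.
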