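# Methods

## Photoselection model

For an isotropic, orientationally frozen ensemble excited by a linearly
polarized pump, the probability of exciting a molecule scales with
cos²θ between pump field and electronic tdm. For a vibrational probe
tdm at angle Φ to the electronic one this yields channel factors
f∥ = 1 + 2r and f⊥ = 1 − r with r = (3cos²Φ − 1)/5, hence the dichroic
ratio d = (1 + 2r)/(1 − r) ∈ [0.5, 3] and its inverse
Φ(d) = arccos √((2d − 1)/(d + 2)). The isotropic combination
(A∥ + 2A⊥)/3 recovers the orientation-free amplitude exactly. Because a
tdm has no observable sign, all angles are folded to [0, 90]°.
Assumptions: one-photon photoselection in the weak-excitation limit and
no rotational depolarization between pump and probe (appropriate for a
membrane-protein film/suspension on a ≤50 ps window); no depolarization
correction is applied. Measured ratios pushed outside [0.5, 3] by noise
are clamped to the boundary angle and flagged with a warning rather than
rejected, because boundary estimates are physically meaningful
(a parallel tdm genuinely sits at d = 3).

## Global decomposition

Both channels are fitted simultaneously with one band set. Each band
contributes S_k · g(ν̃) · h_k(t) scaled per channel by f_pol(Φ_k); the
channel difference enters *only* through Φ_k, so the dichroic relation
is a structural constraint, not a post-hoc ratio of independently
fitted amplitudes. Bleaches are IRF-smeared steps held constant; any
apparent bleach recovery must be explained by overlap with rising
bands, which is exactly how the canonical fixture reproduces the
apparent 1661 cm⁻¹ decay. All rising bands share a single τ.

Numerical choices:

- **Line shape**: Gaussian with unit peak height,
  g = exp(−4 ln2 ((ν̃−ν̃₀)/Δν̃)²). The line shape is a modelling choice
  (Lorentzian/Voigt would be drop-in alternatives); Gaussian is the
  simplest symmetric profile and matches the generator, keeping
  recovery tests line-shape-consistent.
- **IRF convolution**: analytic step⊗Gaussian
  (½ erfc(−Δt/√2σ)) and exponential-rise⊗Gaussian, with the decaying
  term evaluated through `erfcx` where the naive expression would
  overflow, so any τ/σ ratio is stable. σ = FWHM/(2√(2 ln 2)),
  FWHM = 0.35 ps by default.
- **Angle parameterization**: Φ is fitted as c = cos²Φ ∈ [0, 1], which
  removes the angular boundary pathology at 0°/90° (the cost is
  quadratic in c but quartic in Φ near a boundary) and lets the
  trust-region optimizer pin c cleanly at a bound; degrees are derived
  for reporting.
- **Bounds**: centers free within ±8 cm⁻¹ of the initial guess and
  widths within [4, 40] cm⁻¹ — loose physical limits that prevent
  overlapping bands from exchanging identities; amplitudes unbounded;
  τ ∈ [0.01, 10⁴] ps.
- **Optimizer**: bounded trust-region least squares (lmfit/`least_squares`)
  with uniform weights (no per-pixel noise model is assumed), ftol 1e−10,
  xtol 1e−8. Non-convergence is reported in the result, not raised.
- **Fit region**: wavenumbers inside the spectral window and delays
  ≥ t_min = 0.3 ps, keeping the coherent-artifact region around time
  zero out of the analysis.

## Exhaustive-search confidence intervals

The profile scan fixes the target parameter on a grid marching outward
from the optimum, re-optimizes all other free parameters at each point
(warm-started from the neighbouring solution), and compares the profiled
cost χ²(θ) with the best χ² through
F = (χ²(θ)/χ²_min − 1)(n_obs − n_free), thresholded at the
F(1, n_obs − n_free) quantile of erf(σ/√2) (≈ 0.9545 for 2σ). Endpoints
are interpolated on √F, which is exact for a locally quadratic cost.
Angle scans are clipped to [0, 90]°; reaching a physical bound while
still under the threshold yields a boundary-flagged one-sided interval
(the mechanism behind "0° (2σ: 0–30°)"-type results). Default grid
steps: 1.5° for angles, 4% of the estimate for τ; endpoints are stable
to well under one step against grid refinement.

## Synthetic data generator

The generator runs the identical forward model plus additive i.i.d.
Gaussian noise per (delay, wavenumber, channel) sample, seeded for
bit-reproducibility. The canonical fixture encodes the study
conditions: bands at 1661 (bleach, Φ=45°), 1668 (rise, Φ=41°), 1689
(bleach, Φ=29°) and 1703 cm⁻¹ (rise, Φ=0°), shared τ = 16 ps, IRF
0.35 ps, ν̃ ∈ [1655, 1750] cm⁻¹ at 2 cm⁻¹, 30 log-spaced delays from
0.3 to 50 ps. Quantities not fixed by the study are fixture choices
made once: FWHM 12 cm⁻¹ (typical mid-IR protein bandwidth), isotropic
amplitudes −1.0/+0.5/−0.45/+0.35 mOD (strong amide I bleach, weaker
carboxyl features), and noise sd = 2% of the largest amplitude
(0.02 mOD). Recovery experiments start fits from jittered guesses:
multiplicative U(0.9, 1.1) on τ, widths and amplitudes, ±3 cm⁻¹ on
centers, ±4.5° on angles folded to [0, 90].

What passing recovery tests show — and what they do not: the generator
shares the fit's functional form, so recovery demonstrates correctness
and calibration of the inference (estimator bias, interval coverage),
not robustness to model misspecification. Real surfaces add baseline
drift, correlated detector noise, chirp, solvent background and
non-Gaussian line shapes that are deliberately out of scope here.
Because the synthetic noise level and delay sampling are declared
choices rather than measured ones, the synthetic-replicate confidence
intervals are narrower than the published experimental ones; recovery
criteria therefore target the point values and interval *behaviour*
(coverage, boundary flags), not the published interval widths.

## Structure-based tdm directions

Carboxyl C=O: unit vector between the named carbonyl carbon and oxygen
(the user names the oxygen — OE1/OE2, OD1/OD2 — since which one is the
C=O depends on proton placement). Amide I of residue i: ê_CO of residue
i rotated by θ toward N(i+1) within the N–C–O plane, implemented as
cos θ·ê_CO + sin θ·p̂ with p̂ the unit component of (N−C) orthogonal to
ê_CO; θ defaults to 10° (D₂O) and 20° is the H₂O value. Excitonic
coupling between neighbouring amide I oscillators is neglected by
design. Relative angles use |v₁·v₂|, so all results are invariant to
tdm sign and to rigid motion of the structure. PDB parsing (gemmi)
keeps the first model and the highest-occupancy alternate location
(first on ties); insertion codes are part of the residue key.

The idealized α-helix generator (φ = −57°, ψ = −47°, standard bond
geometry via natural-extension placement; carbonyl O on the
CA–C/C–N(i+1) bisector) provides an exact geometric oracle: its screw
symmetry forces all amide I angles to a common value against the true
helix axis, which is recovered from chord second-differences rather
than a principal-axis fit (biased for non-integer turn counts).
Published model-structure reference angles for specific residues (47°
backbone and 28° carboxyl for the counterion glutamate) depend on an
undeposited homology model and are documented as reference values only,
not reproduced.

## Problem sizes and determinism

Recovery experiments use 50 replicates (point estimates) and 100
replicates (interval coverage) of the 30×48×2-point fixture; a single
global fit takes ~30 ms, a τ profile ~100 ms, so the full suites run in
seconds. Every stochastic path takes an explicit integer seed; the
acceptance script derives all replicate seeds from its single `--seed`
argument.

## Known limitations

- One surface at a time: joint fitting of datasets with different
  spectral resolution is not supported (each run is analysed
  independently).
- No chirp, baseline or solvent-background corrections; data are
  assumed preprocessed.
- The bleach model excludes genuine bleach recovery by construction; a
  system with true ground-state repopulation on the observation window
  needs an extended kinetics class.
- Amide I tdm estimation is a rigid-geometry heuristic; no normal-mode
  or coupling calculation is attempted.
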