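# polir

Analysis tools for **polarization-resolved femtosecond visible-pump /
mid-IR-probe spectroscopy** of photoreceptor proteins. The package is
aimed at time-resolved spectroscopists who need to (i) decompose
two-channel transient absorption surfaces ΔA(ν̃, t) into overlapping
vibrational bands with shared kinetics, (ii) convert per-band dichroic
ratios into transition-dipole-moment (tdm) angles with honest
uncertainty intervals, and (iii) compare those measured angles with tdm
directions estimated from a protein structure.

## The model

A linearly polarized pump photoselects chromophores whose electronic tdm
is aligned with its field. The absorbance change probed parallel and
perpendicular to the pump encodes the angle Φ between the electronic tdm
and each vibrational tdm through the dichroic ratio *d* = A∥/A⊥:

    Φ(d) = arccos √((2d − 1)/(d + 2)),   d ∈ [0.5, 3]

with the magic angle Φ = 54.74° at *d* = 1 and the isotropic signal
(A∥ + 2A⊥)/3 free of orientational information.

The global decomposition models both polarization channels
simultaneously as a sum of Gaussian bands:

    ΔA_pol(ν̃, t) = Σ_k f_pol(Φ_k) · S_k · g(ν̃; ν̃_k, Δν̃_k) · h_k(t)

where S_k is the isotropic amplitude, f∥ = 1 + 2r, f⊥ = 1 − r with
r = (3cos²Φ_k − 1)/5, bleach kinetics h_k are an IRF-smeared step held
constant in time, and all product bands rise with **one shared**
exponential time constant τ (convolved with a ~350 fs Gaussian
instrument response). Channel amplitudes are *derived* from (S_k, Φ_k),
never fitted independently, so the dichroic-ratio relation is a hard
constraint of the fit. Confidence intervals come from an
exhaustive-search profile: each parameter is stepped over a grid, all
others re-optimized, and the interval bounded by an F test at the chosen
sigma level — which naturally produces one-sided, boundary-flagged
intervals such as "0° (2σ: 0–30°)" for near-parallel bands.

The structural module estimates vibrational tdm directions from PDB
coordinates: carboxyl C=O tdms along the bond, amide I tdms rotated by
~10° (20° in H₂O) from the C=O direction toward the peptide nitrogen
within the N–C–O plane, and relative angles (folded to [0, 90]°) against
an electronic tdm axis such as the retinal polyene chain.

A forward simulator generates surfaces with exactly the statistical
structure the fit assumes; its canonical fixture emulates the CaChR1
amide-I/carboxyl region (bleaches at 1661/1689 cm⁻¹, product bands at
1668/1703 cm⁻¹, shared 16 ps rise, angles 45°/29°/41°/0°).

## Worked example

```python
import numpy as np
from polir import decomposition as dc, synthetic
from polir.spectra import SpectralWindow

surface = synthetic.cachr1_fixture(noise_sd=0.02, seed=1)
bands, kin = synthetic.perturbed(
    synthetic.cachr1_bands(), synthetic.cachr1_kinetics(), np.random.default_rng(99)
)
spec = dc.ModelSpec(bands=bands, kin=kin, fit_window=SpectralWindow(1655, 1750))
fit = dc.fit_global(surface, spec)
print(f"tau = {fit.tau:.2f} ps")
print(dc.report_angles(fit).round(3).to_string(index=False))
```

prints

```
tau = 16.17 ps
           label  center_cm1  fwhm_cm1  s_iso_mOD  phi_deg  dichroic_ratio kinetics  tau_ps
  amide I bleach    1660.985    12.038     -0.998   44.919           1.336 constant     NaN
 amide I product    1668.057    11.991      0.499   40.714           1.508 exp_rise  16.169
 carboxyl bleach    1689.029    12.087     -0.447   28.683           2.064 constant     NaN
carboxyl product    1702.966    12.152      0.353    0.001           3.000 exp_rise  16.169
```

The fit was started from jittered guesses yet recovers the generating
shared rise constant (16 ps) and the four tdm angles (45/41/29/0°); the
0° band's dichroic ratio of 3.0 marks a vibrational tdm parallel to the
electronic one. `exhaustive_ci` then yields, e.g., τ = 16.07 ps
(2σ: 15.48–16.70 ps) and a lower-boundary-flagged angle interval
0–10.4° for the 1703 cm⁻¹ band on this replicate.

More narrative walk-throughs live in `examples/` (photoselection math,
simulate-and-fit, confidence intervals, structure-based tdm angles), and
the same pipeline is scriptable from the shell via the `polir` command
(`simulate`, `fit`, `ci`, `structure-angles`, `check-recovery`).

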