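"""Forward simulator for polarization-resolved transient mid-IR surfaces.

Generates surfaces with exactly the statistical structure the global
decomposition assumes: Gaussian bands (unit peak height), bleaches that
are constant in time after an instrument-response-smeared step, product
bands rising with a single shared exponential, channel amplitudes set by
photoselection, and additive i.i.d. Gaussian noise.

The canonical fixture emulates the measured CaChR1 amide-I/carboxyl
region: two constant bleaches at 1661 and 1689 cm⁻¹ and two positive
bands at 1668 and 1703 cm⁻¹ rising with a shared 16 ps constant, with
tdm angles 45°, 29°, 41° and 0° and a 350 fs Gaussian IRF.  Band widths
and amplitudes are fixture choices (12 cm⁻¹ FWHM; plateau amplitudes
−1.0, −0.45, +0.5, +0.35 mOD) — plausible mid-IR protein values, not
measured ones.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import erfc, erfcx

from . import photoselection
from .spectra import TransientSurface

__all__ = [
    "Band",
    "KineticModel",
    "NoiseSpec",
    "KINETICS",
    "gaussian_band",
    "kinetic_trace",
    "simulate",
    "cachr1_bands",
    "cachr1_kinetics",
    "cachr1_fixture",
    "DEFAULT_NOISE_SD",
]

KINETICS = ("constant", "exp_rise")

#: 2% of the largest fixture |s_iso| (1.0 mOD), in mOD.
DEFAULT_NOISE_SD = 0.02


@dataclass
class Band:
    """One spectral component of the decomposition model.

    center/fwhm in cm⁻¹; ``s_iso`` is the signed isotropic plateau
    amplitude in mOD (negative for bleaches); ``phi`` the tdm angle in
    degrees in [0, 90]; ``kinetics`` either ``"constant"`` (IRF-smeared
    step, flat thereafter) or ``"exp_rise"`` (shared-τ exponential rise).
    """

    center: float
    fwhm: float
    s_iso: float
    phi: float
    kinetics: str
    label: str = ""

    def __post_init__(self):
        if not self.fwhm > 0:
            raise ValueError(f"fwhm must be > 0, got {self.fwhm}")
        if not (0.0 <= self.phi <= 90.0):
            raise ValueError(f"phi must be in [0, 90] degrees, got {self.phi}")
        if self.kinetics not in KINETICS:
            raise ValueError(f"kinetics must be one of {KINETICS}, got {self.kinetics!r}")


@dataclass
class KineticModel:
    """Shared kinetics: rise constant τ (ps), Gaussian IRF FWHM (ps), time zero."""

    tau: float
    irf_fwhm: float = 0.35
    t0: float = 0.0

    def __post_init__(self):
        if not self.tau > 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if self.irf_fwhm < 0:
            raise ValueError(f"irf_fwhm must be >= 0, got {self.irf_fwhm}")


@dataclass
class NoiseSpec:
    """Additive i.i.d. Gaussian noise per (delay, wavenumber, polarization) sample."""

    sd: float
    seed: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError(f"noise sd must be >= 0, got {self.sd}")


def gaussian_band(wavenumbers, center: float, fwhm: float) -> np.ndarray:
    """Gaussian line shape normalized to unit peak height."""
    x = np.asarray(wavenumbers, dtype=float)
    return np.exp(-4.0 * np.log(2.0) * ((x - center) / fwhm) ** 2)


def kinetic_trace(kinetics: str, tau: float, irf_fwhm: float, t0: float, delays) -> np.ndarray:
    """Amplitude fraction in [0, 1] vs delay for one kinetics class.

    ``constant``: Heaviside step convolved with the Gaussian IRF,
    analytically ``0.5 erfc(−Δt / (√2 σ))`` with σ = FWHM / (2√(2 ln 2)).

    ``exp_rise``: ``H(t)(1 − exp(−Δt/τ))`` convolved with the same IRF,
    using the standard analytic exponential⊗Gaussian expression.  The
    decaying part is evaluated through ``erfcx`` where the plain form
    would overflow, so the result is stable for any τ/σ ratio.
    """
    if kinetics not in KINETICS:
        raise ValueError(f"unknown kinetics {kinetics!r}")
    if kinetics == "exp_rise" and not tau > 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    t = np.asarray(delays, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("delays must be finite")
    dt = t - t0
    sigma = irf_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    if sigma == 0.0:
        step = (dt >= 0).astype(float)
        if kinetics == "constant":
            return step
        return step * -np.expm1(-np.clip(dt, 0.0, None) / tau)

    step = 0.5 * erfc(-dt / (np.sqrt(2.0) * sigma))
    if kinetics == "constant":
        return step
    # exp(sigma^2/(2 tau^2) - dt/tau) * erfc(a) with a = (sigma/tau - dt/sigma)/sqrt(2)
    a = (sigma / tau - dt / sigma) / np.sqrt(2.0)
    decay = np.empty_like(dt)
    pos = a > 0.0
    # erfc(a) = erfcx(a) exp(-a^2); combined exponent collapses to -dt^2/(2 sigma^2)
    decay[pos] = 0.5 * erfcx(a[pos]) * np.exp(-(dt[pos] ** 2) / (2.0 * sigma**2))
    expo = sigma**2 / (2.0 * tau**2) - dt[~pos] / tau
    decay[~pos] = 0.5 * np.exp(expo) * erfc(a[~pos])
    return np.clip(step - decay, 0.0, 1.0)


def simulate(
    bands,
    kin: KineticModel,
    wavenumbers,
    delays,
    noise: NoiseSpec | None = None,
    meta: dict | None = None,
) -> TransientSurface:
    """Run the four-factor forward model on explicit axes.

    dA_pol(t, ν) = Σ_k polfactor(Φ_k, pol) · s_iso,k · gauss(ν; c_k, w_k)
    · trace_k(t) + ε, with ε ~ N(0, sd²) i.i.d. per sample and channel.
    A fixed seed makes the output bit-reproducible.
    """
    wn = np.asarray(wavenumbers, dtype=float)
    t = np.asarray(delays, dtype=float)
    n_t, n_w = t.size, wn.size
    dA_par = np.zeros((n_t, n_w))
    dA_perp = np.zeros((n_t, n_w))
    for band in bands:
        if not isinstance(band, Band):
            raise TypeError(f"expected Band, got {type(band).__name__}")
        shape = gaussian_band(wn, band.center, band.fwhm)
        trace = kinetic_trace(band.kinetics, kin.tau, kin.irf_fwhm, kin.t0, t)
        f_par, f_perp = photoselection.polarized_amplitudes(1.0, band.phi)
        surf = band.s_iso * np.outer(trace, shape)
        dA_par += f_par * surf
        dA_perp += f_perp * surf
    if noise is not None and noise.sd > 0:
        rng = np.random.default_rng(noise.seed)
        dA_par = dA_par + rng.normal(0.0, noise.sd, size=dA_par.shape)
        dA_perp = dA_perp + rng.normal(0.0, noise.sd, size=dA_perp.shape)
    return TransientSurface(wn, t, dA_par, dA_perp, dict(meta or {}))


def cachr1_bands() -> list:
    """The canonical CaChR1 amide-I/carboxyl band set (fresh copies)."""
    return [
        Band(1661.0, 12.0, -1.00, 45.0, "constant", label="amide I bleach"),
        Band(1668.0, 12.0, +0.50, 41.0, "exp_rise", label="amide I product"),
        Band(1689.0, 12.0, -0.45, 29.0, "constant", label="carboxyl bleach"),
        Band(1703.0, 12.0, +0.35, 0.0, "exp_rise", label="carboxyl product"),
    ]


def cachr1_kinetics() -> KineticModel:
    """Shared 16 ps rise with 350 fs IRF, time zero at 0 ps."""
    return KineticModel(tau=16.0, irf_fwhm=0.35, t0=0.0)


def cachr1_fixture(noise_sd: float = DEFAULT_NOISE_SD, seed: int = 0) -> TransientSurface:
    """Synthetic stand-in for the measured CaChR1 protein-band surfaces.

    Four-band set on ν ∈ [1655, 1750] cm⁻¹ (2 cm⁻¹ step) with 30
    log-spaced delays from 0.3 to 50 ps.  The early-delay cutoff keeps
    the coherent-artifact region out of the simulated data, mirroring
    the analysis window.
    """
    wn = np.arange(1655.0, 1750.0 + 1e-9, 2.0)
    delays = np.geomspace(0.3, 50.0, 30)
    noise = NoiseSpec(sd=noise_sd, seed=seed) if noise_sd > 0 else None
    return simulate(
        cachr1_bands(),
        cachr1_kinetics(),
        wn,
        delays,
        noise=noise,
        meta={"fixture": "cachr1", "noise_sd_mOD": noise_sd, "seed": seed},
    )


def perturbed(bands, kin: KineticModel, rng: np.random.Generator, frac: float = 0.1):
    """Jitter a band set and kinetics for fit-recovery starts.

    τ, FWHM and amplitudes get multiplicative U(1−frac, 1+frac); centers
    an additive ±3 cm⁻¹; angles an additive ±(frac·45°) folded to [0, 90].
    Returns (bands, kin) copies; inputs are untouched.
    """
    out = []
    for b in bands:
        phi = abs(b.phi + rng.uniform(-45.0 * frac, 45.0 * frac))
        phi = min(phi, 180.0 - phi) if phi > 90.0 else phi
        out.append(
            replace(
                b,
                center=b.center + rng.uniform(-3.0, 3.0),
                fwhm=b.fwhm * rng.uniform(1 - frac, 1 + frac),
                s_iso=b.s_iso * rng.uniform(1 - frac, 1 + frac),
                phi=phi,
            )
        )
    kin2 = replace(kin, tau=kin.tau * rng.uniform(1 - frac, 1 + frac))
    return out, kin2
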