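"""Global polarization-coupled band decomposition with shared rise kinetics.

Both polarization channels are fitted simultaneously with one set of band
parameters: each band carries an isotropic amplitude ``s_iso`` and a tdm
angle Φ, and the channel amplitudes are *derived* through the
photoselection factors (1+2r) and (1−r) — never fitted independently.
This embeds the dichroic-ratio relation as a hard constraint, so the two
channels are explained by a single decomposition.  Bleaching bands are
strictly constant in time (an IRF-smeared step); positive product bands
rise with a single shared exponential time constant τ.

Φ is fitted internally as c = cos²Φ ∈ [0, 1] to avoid angular boundary
pathologies and reported in degrees.  Confidence intervals come from an
exhaustive (profile) search: the target parameter is stepped over a grid,
all other free parameters are re-optimized at each step, and the interval
is the region where the F statistic comparing the profiled to the best
cost stays below the chosen sigma level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy.special import erf
from scipy.stats import f as f_dist

from . import photoselection
from .spectra import SpectralWindow, TransientSurface
from .synthetic import Band, KineticModel, gaussian_band, kinetic_trace

__all__ = [
    "BandTemplate",
    "ModelSpec",
    "FitResult",
    "ConfidenceInterval",
    "ProfileError",
    "fit_global",
    "exhaustive_ci",
    "report_angles",
]


class ProfileError(ValueError):
    """Requested profile parameter is fixed or unknown."""


@dataclass
class BandTemplate(Band):
    """A :class:`~polir.synthetic.Band` with fit metadata.

    ``vary_*`` flags free or fix each parameter; centers float within
    ``center_slack`` cm⁻¹ of the initial guess and widths within
    ``(fwhm_lo, fwhm_hi)`` — loose physical bounds that keep overlapping
    bands from swapping identities during optimization.
    """

    vary_center: bool = True
    vary_fwhm: bool = True
    vary_s_iso: bool = True
    vary_phi: bool = True
    center_slack: float = 8.0
    fwhm_lo: float = 4.0
    fwhm_hi: float = 40.0

    @classmethod
    def from_band(cls, band: Band, **kwargs) -> "BandTemplate":
        return cls(
            center=band.center,
            fwhm=band.fwhm,
            s_iso=band.s_iso,
            phi=band.phi,
            kinetics=band.kinetics,
            label=band.label,
            **kwargs,
        )


def _as_template(b) -> BandTemplate:
    return b if isinstance(b, BandTemplate) else BandTemplate.from_band(b)


@dataclass
class ModelSpec:
    """Model definition for :func:`fit_global`.

    ``bands`` may be plain :class:`Band` objects (all parameters free with
    default bounds) or :class:`BandTemplate`.  ``kin`` carries the initial
    shared τ plus the fixed IRF width and time zero.  Only data with
    wavenumber inside ``fit_window`` and delay ≥ ``t_min`` enters the fit;
    the default ``t_min`` keeps the coherent-artifact region out.
    """

    bands: list
    kin: KineticModel
    fit_window: SpectralWindow
    t_min: float = 0.3
    vary_tau: bool = True
    tau_bounds: tuple = (0.01, 1e4)

    def __post_init__(self):
        if not self.bands:
            raise ValueError("ModelSpec needs at least one band")
        self.bands = [_as_template(b) for b in self.bands]
        if not (self.tau_bounds[0] < self.kin.tau < self.tau_bounds[1]):
            raise ValueError("tau bounds must contain the initial tau")


@dataclass
class ConfidenceInterval:
    """Profile (exhaustive-search) interval for one parameter."""

    parameter: str
    sigma: float
    lo: float
    hi: float
    best: float
    lo_at_bound: bool = False
    hi_at_bound: bool = False

    def covers(self, value: float) -> bool:
        return self.lo <= value <= self.hi


@dataclass
class FitResult:
    """Optimized band set, shared τ, diagnostics, and residuals.

    ``at_bound`` maps user-facing parameter names (``tau``, ``b{i}_phi``,
    ...) to True where the optimizer finished on a bound — e.g. an angle
    pinned at 0° shows up as ``b{i}_phi: True``.
    """

    bands: list
    tau: float
    stderr: dict
    residual_par: np.ndarray
    residual_perp: np.ndarray
    cost: float
    n_obs: int
    n_free: int
    success: bool
    message: str
    at_bound: dict = field(default_factory=dict)
    _problem: object = field(default=None, repr=False, compare=False)
    _params: object = field(default=None, repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "tau_ps": self.tau,
            "cost": self.cost,
            "n_obs": self.n_obs,
            "n_free": self.n_free,
            "success": self.success,
            "message": self.message,
            "at_bound": {k: bool(v) for k, v in self.at_bound.items()},
            "stderr": {k: (None if v is None or not np.isfinite(v) else float(v))
                       for k, v in self.stderr.items()},
            "bands": [
                {
                    "label": b.label,
                    "center_cm1": b.center,
                    "fwhm_cm1": b.fwhm,
                    "s_iso_mOD": b.s_iso,
                    "phi_deg": b.phi,
                    "kinetics": b.kinetics,
                }
                for b in self.bands
            ],
        }


def _phi_to_c(phi_deg: float) -> float:
    return math.cos(math.radians(phi_deg)) ** 2


def _c_to_phi(c: float) -> float:
    return math.degrees(math.acos(math.sqrt(min(max(c, 0.0), 1.0))))


class _Problem:
    """Masked data, parameter construction and residual evaluation."""

    def __init__(self, surface: TransientSurface, spec: ModelSpec):
        self.spec = spec
        wmask = spec.fit_window.mask(surface.wavenumbers)
        tmask = surface.delays >= spec.t_min
        if not wmask.any():
            raise ValueError("fit window contains no wavenumber samples")
        if not tmask.any():
            raise ValueError(f"no delays >= t_min = {spec.t_min} ps")
        self.wn = surface.wavenumbers[wmask]
        self.t = surface.delays[tmask]
        self.data_par = surface.dA_par[np.ix_(tmask, wmask)]
        self.data_perp = surface.dA_perp[np.ix_(tmask, wmask)]
        self.n_obs = 2 * self.data_par.size
        # the step trace has no free parameter; evaluate once
        self.step_trace = kinetic_trace(
            "constant", 1.0, spec.kin.irf_fwhm, spec.kin.t0, self.t
        )

    def make_params(self) -> lmfit.Parameters:
        spec = self.spec
        params = lmfit.Parameters()
        for i, b in enumerate(spec.bands):
            params.add(
                f"b{i}_center",
                value=b.center,
                vary=b.vary_center,
                min=b.center - b.center_slack,
                max=b.center + b.center_slack,
            )
            params.add(
                f"b{i}_fwhm", value=b.fwhm, vary=b.vary_fwhm, min=b.fwhm_lo, max=b.fwhm_hi
            )
            params.add(f"b{i}_siso", value=b.s_iso, vary=b.vary_s_iso)
            params.add(f"b{i}_c", value=_phi_to_c(b.phi), vary=b.vary_phi, min=0.0, max=1.0)
        any_rise = any(b.kinetics == "exp_rise" for b in spec.bands)
        params.add(
            "tau",
            value=spec.kin.tau,
            vary=spec.vary_tau and any_rise,
            min=spec.tau_bounds[0],
            max=spec.tau_bounds[1],
        )
        return params

    def model(self, params) -> tuple:
        spec = self.spec
        tau = params["tau"].value
        rise_trace = None
        dA_par = np.zeros_like(self.data_par)
        dA_perp = np.zeros_like(self.data_perp)
        for i, b in enumerate(spec.bands):
            shape = gaussian_band(self.wn, params[f"b{i}_center"].value, params[f"b{i}_fwhm"].value)
            if b.kinetics == "constant":
                trace = self.step_trace
            else:
                if rise_trace is None:
                    rise_trace = kinetic_trace(
                        "exp_rise", tau, spec.kin.irf_fwhm, spec.kin.t0, self.t
                    )
                trace = rise_trace
            c = params[f"b{i}_c"].value
            r = (3.0 * c - 1.0) / 5.0
            surf = params[f"b{i}_siso"].value * np.outer(trace, shape)
            dA_par += (1.0 + 2.0 * r) * surf
            dA_perp += (1.0 - r) * surf
        return dA_par, dA_perp

    def residual(self, params) -> np.ndarray:
        m_par, m_perp = self.model(params)
        return np.concatenate(
            [(m_par - self.data_par).ravel(), (m_perp - self.data_perp).ravel()]
        )

    def minimize(self, params) -> lmfit.minimizer.MinimizerResult:
        return lmfit.minimize(
            self.residual,
            params,
            method="least_squares",
            ftol=1e-10,
            xtol=1e-8,
            gtol=1e-10,
        )


def _near_bound(par) -> bool:
    if not par.vary:
        return False
    span = (par.max - par.min) if np.isfinite(par.max) and np.isfinite(par.min) else 1.0
    tol = 1e-6 * max(abs(span), 1.0)
    return (np.isfinite(par.min) and abs(par.value - par.min) < tol) or (
        np.isfinite(par.max) and abs(par.value - par.max) < tol
    )


def fit_global(surface: TransientSurface, spec: ModelSpec) -> FitResult:
    """Least-squares fit of the polarization-coupled band model.

    Minimizes the sum of squared residuals over both channels, all delays
    ≥ ``spec.t_min`` and wavenumbers inside ``spec.fit_window`` with
    uniform weights, using bounded trust-region least squares.
    Non-convergence is reported through ``FitResult.success`` rather than
    raised; a window with fewer observations than free parameters raises
    ``ValueError``.
    """
    problem = _Problem(surface, spec)
    params = problem.make_params()
    n_free = sum(1 for p in params.values() if p.vary)
    if problem.n_obs <= n_free:
        raise ValueError(
            f"degenerate fit: {problem.n_obs} observations for {n_free} free parameters"
        )
    result = problem.minimize(params)

    bands = []
    stderr: dict = {}
    at_bound: dict = {}
    p = result.params
    for i, b in enumerate(spec.bands):
        c = p[f"b{i}_c"].value
        phi = _c_to_phi(c)
        bands.append(
            Band(
                center=p[f"b{i}_center"].value,
                fwhm=p[f"b{i}_fwhm"].value,
                s_iso=p[f"b{i}_siso"].value,
                phi=phi,
                kinetics=b.kinetics,
                label=b.label,
            )
        )
        for short, name in (
            ("center", f"b{i}_center"),
            ("fwhm", f"b{i}_fwhm"),
            ("siso", f"b{i}_siso"),
        ):
            stderr[f"b{i}_{short}"] = p[name].stderr
            at_bound[f"b{i}_{short}"] = _near_bound(p[name])
        c_err = p[f"b{i}_c"].stderr
        if c_err is not None and 0.0 < c < 1.0:
            # delta method: dPhi/dc = -1 / (2 sqrt(c (1 - c))) rad
            stderr[f"b{i}_phi"] = math.degrees(c_err / (2.0 * math.sqrt(c * (1.0 - c))))
        else:
            stderr[f"b{i}_phi"] = None
        at_bound[f"b{i}_phi"] = _near_bound(p[f"b{i}_c"])
    stderr["tau"] = p["tau"].stderr
    at_bound["tau"] = _near_bound(p["tau"])

    m_par, m_perp = problem.model(result.params)
    return FitResult(
        bands=bands,
        tau=p["tau"].value,
        stderr=stderr,
        residual_par=m_par - problem.data_par,
        residual_perp=m_perp - problem.data_perp,
        cost=float(result.chisqr),
        n_obs=problem.n_obs,
        n_free=result.nvarys,
        success=bool(result.success),
        message=str(result.message),
        at_bound=at_bound,
        _problem=problem,
        _params=result.params,
    )


def _resolve_parameter(spec: ModelSpec, fit: FitResult, name: str):
    """Map a user-facing name to (internal lmfit name, to/from transforms, scan bounds)."""
    if name == "tau":
        return "tau", (lambda v: v), (lambda v: v), spec.tau_bounds
    for i in range(len(spec.bands)):
        if name == f"b{i}_phi":
            return f"b{i}_c", _phi_to_c, _c_to_phi, (0.0, 90.0)
        for short, internal in (
            ("center", f"b{i}_center"),
            ("fwhm", f"b{i}_fwhm"),
            ("siso", f"b{i}_siso"),
        ):
            if name == f"b{i}_{short}":
                return internal, (lambda v: v), (lambda v: v), None
    raise ProfileError(f"unknown parameter {name!r}")


_DEFAULT_STEPS = {"phi": 1.5, "center": 0.4, "fwhm": 0.5}


def _default_step(name: str, best: float) -> float:
    kind = name.rsplit("_", 1)[-1]
    if kind in _DEFAULT_STEPS:
        return _DEFAULT_STEPS[kind]
    if kind == "siso":
        return max(0.02 * abs(best), 1e-4)
    return max(0.04 * abs(best), 1e-3)  # tau


def exhaustive_ci(
    surface: TransientSurface,
    spec: ModelSpec,
    fit: FitResult,
    parameter: str,
    level_sigma: float = 2.0,
    step: float | None = None,
    max_steps: int = 200,
) -> ConfidenceInterval:
    """Exhaustive-search (profile) confidence interval for one parameter.

    The parameter is fixed on a grid marching outward from the best-fit
    value in steps of ``step`` (a per-kind default if None); at each grid
    point every other free parameter is re-optimized (warm-started from
    the neighbouring solution) and the profiled cost is compared to the
    best cost with an F test at the ``level_sigma`` probability level
    with (1, n_obs − n_free) degrees of freedom.  The interval endpoint
    is interpolated at the F-threshold crossing.  Angle scans are clipped
    to [0, 90]°; an endpoint that reaches a physical bound while still
    inside the threshold is reported at the bound with the corresponding
    boundary flag set — reproducing boundary intervals such as 0–30°.

    Parameter names: ``tau``, ``b{i}_phi``, ``b{i}_center``, ``b{i}_fwhm``,
    ``b{i}_siso`` with ``i`` the band index in ``spec.bands``.
    """
    internal, to_internal, from_internal, scan_bounds = _resolve_parameter(spec, fit, parameter)
    problem = fit._problem if fit._problem is not None else _Problem(surface, spec)
    best_params = fit._params
    if best_params is None or not best_params[internal].vary:
        raise ProfileError(f"parameter {parameter!r} is fixed; cannot profile")

    best_val = from_internal(best_params[internal].value)
    best_cost = fit.cost
    dof = fit.n_obs - fit.n_free
    prob = erf(level_sigma / math.sqrt(2.0))
    fcrit = f_dist.ppf(prob, 1, dof)
    if step is None:
        step = _default_step(parameter, best_val)
    if scan_bounds is None:
        par = best_params[internal]
        scan_bounds = (par.min, par.max)

    def profile_cost(value_user: float, warm: lmfit.Parameters) -> tuple:
        pars = warm.copy()
        pars[internal].set(value=to_internal(value_user), vary=False)
        res = problem.minimize(pars)
        return float(res.chisqr), res.params

    def fstat(cost: float) -> float:
        return max(0.0, (cost - best_cost) / best_cost * dof)

    endpoints = {}
    flags = {}
    for direction, side in ((-1.0, "lo"), (+1.0, "hi")):
        warm = best_params.copy()
        prev_val, prev_f = best_val, 0.0
        endpoint, at_bound = None, False
        for k in range(1, max_steps + 1):
            val = best_val + direction * k * step
            clipped = min(max(val, scan_bounds[0]), scan_bounds[1])
            hit_bound = clipped != val
            cost_k, warm = profile_cost(clipped, warm)
            f_k = fstat(cost_k)
            if f_k >= fcrit:
                # interpolate on sqrt(F): exact for a locally quadratic cost,
                # where F grows as the squared parameter displacement
                if f_k > prev_f:
                    frac = (math.sqrt(fcrit) - math.sqrt(prev_f)) / (
                        math.sqrt(f_k) - math.sqrt(prev_f)
                    )
                else:
                    frac = 1.0
                endpoint = prev_val + frac * (clipped - prev_val)
                break
            prev_val, prev_f = clipped, f_k
            if hit_bound:
                endpoint, at_bound = clipped, True
                break
        if endpoint is None:  # ran out of steps inside the threshold
            endpoint, at_bound = prev_val, True
        endpoints[side] = endpoint
        flags[side] = at_bound

    return ConfidenceInterval(
        parameter=parameter,
        sigma=level_sigma,
        lo=min(endpoints["lo"], endpoints["hi"]),
        hi=max(endpoints["lo"], endpoints["hi"]),
        best=best_val,
        lo_at_bound=flags["lo"],
        hi_at_bound=flags["hi"],
    )


def report_angles(fit: FitResult) -> pd.DataFrame:
    """Per-band summary table, sorted by band center.

    Columns: label, center, FWHM, isotropic amplitude, tdm angle Φ, the
    dichroic ratio it implies, kinetics class, and τ for rising bands.
    """
    rows = []
    for b in sorted(fit.bands, key=lambda b: b.center):
        rows.append(
            {
                "label": b.label,
                "center_cm1": b.center,
                "fwhm_cm1": b.fwhm,
                "s_iso_mOD": b.s_iso,
                "phi_deg": b.phi,
                "dichroic_ratio": photoselection.dichroic_from_angle(b.phi),
                "kinetics": b.kinetics,
                "tau_ps": fit.tau if b.kinetics == "exp_rise" else np.nan,
            }
        )
    return pd.DataFrame(rows)
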