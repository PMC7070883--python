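"""Data model and text I/O for polarization-resolved transient absorption surfaces.

A :class:`TransientSurface` holds two ΔA matrices — pump-parallel and
pump-perpendicular probe polarization — on a shared (delay, wavenumber)
grid.  Units follow mid-IR pump–probe convention: wavenumbers in cm⁻¹,
delays in ps, ΔA in milli-OD.

The one on-disk format is a tidy CSV with columns
``wavenumber_cm1, delay_ps, polarization, dA_mOD`` (``polarization`` is
``par`` or ``perp``) and optional ``# key=value`` header lines carrying
metadata.  The grid must be rectangular: every (wavenumber, delay) pair
present in both polarizations.  Sparse or ragged data is rejected rather
than interpolated.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TransientSurface",
    "SpectralWindow",
    "TimeWindow",
    "SurfaceFormatError",
    "read_surface",
    "write_surface",
    "isotropic_surface",
    "average_window",
]

_COLUMNS = ["wavenumber_cm1", "delay_ps", "polarization", "dA_mOD"]


class SurfaceFormatError(ValueError):
    """The on-disk table violates the tidy two-polarization contract."""


@dataclass(frozen=True)
class SpectralWindow:
    """Half-open-free inclusive wavenumber window [lo, hi] in cm⁻¹."""

    lo: float
    hi: float

    def __post_init__(self):
        if not (np.isfinite(self.lo) and np.isfinite(self.hi) and self.lo < self.hi):
            raise ValueError(f"require lo < hi, got [{self.lo}, {self.hi}]")

    def mask(self, wavenumbers: np.ndarray) -> np.ndarray:
        return (wavenumbers >= self.lo) & (wavenumbers <= self.hi)


@dataclass(frozen=True)
class TimeWindow:
    """Inclusive delay window [lo, hi] in ps."""

    lo: float
    hi: float

    def __post_init__(self):
        if not (np.isfinite(self.lo) and np.isfinite(self.hi) and self.lo < self.hi):
            raise ValueError(f"require lo < hi, got [{self.lo}, {self.hi}]")

    def mask(self, delays: np.ndarray) -> np.ndarray:
        return (delays >= self.lo) & (delays <= self.hi)


@dataclass
class TransientSurface:
    """Two polarization-resolved ΔA matrices on shared axes.

    Attributes
    ----------
    wavenumbers : ndarray, shape (n_wn,)
        Probe wavenumbers in cm⁻¹, strictly monotonic on input; stored
        ascending (matrices are reordered alongside the axes).
    delays : ndarray, shape (n_t,)
        Pump–probe delays in ps, same canonicalization.
    dA_par, dA_perp : ndarray, shape (n_t, n_wn)
        Absorbance change in mOD for parallel / perpendicular probing.
    meta : dict
        Free-form metadata (e.g. spectral resolution, excitation wavelength).
    """

    wavenumbers: np.ndarray
    delays: np.ndarray
    dA_par: np.ndarray
    dA_perp: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.delays = np.asarray(self.delays, dtype=float)
        self.dA_par = np.asarray(self.dA_par, dtype=float)
        self.dA_perp = np.asarray(self.dA_perp, dtype=float)
        if self.wavenumbers.ndim != 1 or self.delays.ndim != 1:
            raise ValueError("axes must be 1-D")
        shape = (self.delays.size, self.wavenumbers.size)
        if self.dA_par.shape != shape or self.dA_perp.shape != shape:
            raise ValueError(
                f"matrix shapes {self.dA_par.shape}/{self.dA_perp.shape} "
                f"do not match (n_delays, n_wavenumbers) = {shape}"
            )
        for name, ax in (("wavenumbers", self.wavenumbers), ("delays", self.delays)):
            if not np.all(np.isfinite(ax)):
                raise ValueError(f"{name} contain non-finite values")
            d = np.diff(ax)
            if ax.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"{name} must be strictly monotonic")
        # canonicalize to ascending axes so fits are orientation-invariant
        if self.wavenumbers.size > 1 and self.wavenumbers[0] > self.wavenumbers[-1]:
            self.wavenumbers = self.wavenumbers[::-1].copy()
            self.dA_par = self.dA_par[:, ::-1].copy()
            self.dA_perp = self.dA_perp[:, ::-1].copy()
        if self.delays.size > 1 and self.delays[0] > self.delays[-1]:
            self.delays = self.delays[::-1].copy()
            self.dA_par = self.dA_par[::-1].copy()
            self.dA_perp = self.dA_perp[::-1].copy()
        if not (np.all(np.isfinite(self.dA_par)) and np.all(np.isfinite(self.dA_perp))):
            raise ValueError("ΔA matrices contain non-finite values")

    @property
    def shape(self) -> tuple:
        return self.dA_par.shape

    def isotropic(self) -> np.ndarray:
        """Magic-angle surface (dA_par + 2 dA_perp) / 3, same shape."""
        return (self.dA_par + 2.0 * self.dA_perp) / 3.0

    def __eq__(self, other) -> bool:
        if not isinstance(other, TransientSurface):
            return NotImplemented
        return (
            np.array_equal(self.wavenumbers, other.wavenumbers)
            and np.array_equal(self.delays, other.delays)
            and np.array_equal(self.dA_par, other.dA_par)
            and np.array_equal(self.dA_perp, other.dA_perp)
            and self.meta == other.meta
        )


def isotropic_surface(surface: TransientSurface) -> np.ndarray:
    """Elementwise isotropic signal (dA_par + 2 dA_perp)/3."""
    return surface.isotropic()


def average_window(surface: TransientSurface, tw: TimeWindow) -> tuple:
    """Unweighted mean spectra over delays with ``tw.lo <= t <= tw.hi``.

    Returns ``(spectrum_par, spectrum_perp)``, each of shape (n_wn,).
    Raises ``ValueError`` if no delay sample falls inside the window.
    """
    m = tw.mask(surface.delays)
    if not np.any(m):
        raise ValueError(
            f"time window [{tw.lo}, {tw.hi}] ps contains no delay samples"
        )
    return surface.dA_par[m].mean(axis=0), surface.dA_perp[m].mean(axis=0)


def write_surface(surface: TransientSurface, path) -> None:
    """Write the tidy CSV dialect, sorted by (delay, wavenumber, polarization).

    Values are formatted with 12 significant digits so a read/write round
    trip is lossless at that precision.  Metadata is emitted as
    ``# key=value`` header lines.
    """
    buf = io.StringIO()
    for key, value in surface.meta.items():
        buf.write(f"# {key}={value}\n")
    buf.write(",".join(_COLUMNS) + "\n")
    for i, t in enumerate(surface.delays):
        for j, w in enumerate(surface.wavenumbers):
            for pol, mat in (("par", surface.dA_par), ("perp", surface.dA_perp)):
                buf.write(f"{w:.12g},{t:.12g},{pol},{mat[i, j]:.12g}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_surface(path) -> TransientSurface:
    """Read the tidy CSV dialect into a validated :class:`TransientSurface`.

    Raises :class:`SurfaceFormatError` on a missing polarization channel,
    a ragged (non-rectangular) grid, or duplicate
    (wavenumber, delay, polarization) triplets, naming the offending rows.
    """
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = []
    for line in lines:
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
        elif line.strip():
            data_lines.append(line)
    if not data_lines:
        raise SurfaceFormatError(f"{path}: no data rows")
    df = pd.read_csv(io.StringIO("".join(data_lines)))
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise SurfaceFormatError(f"{path}: missing columns {missing}")
    bad_pol = set(df["polarization"].unique()) - {"par", "perp"}
    if bad_pol:
        raise SurfaceFormatError(f"{path}: unknown polarization labels {sorted(bad_pol)}")

    dup = df.duplicated(subset=["wavenumber_cm1", "delay_ps", "polarization"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()[:5]
        raise SurfaceFormatError(
            f"{path}: duplicate (wavenumber, delay, polarization) triplets at rows {rows}"
        )

    wn = np.sort(df["wavenumber_cm1"].unique())
    t = np.sort(df["delay_ps"].unique())
    mats = {}
    for pol in ("par", "perp"):
        sub = df[df["polarization"] == pol]
        if len(sub) != wn.size * t.size:
            example = sub.head(1).to_dict("records")
            raise SurfaceFormatError(
                f"{path}: channel '{pol}' has {len(sub)} rows, expected "
                f"{wn.size * t.size} for a rectangular grid "
                f"({t.size} delays x {wn.size} wavenumbers); near {example}"
            )
        pivot = sub.pivot(index="delay_ps", columns="wavenumber_cm1", values="dA_mOD")
        pivot = pivot.reindex(index=t, columns=wn)
        if pivot.isna().any().any():
            ii, jj = np.argwhere(pivot.isna().to_numpy())[0]
            raise SurfaceFormatError(
                f"{path}: channel '{pol}' missing sample at "
                f"delay={t[ii]} ps, wavenumber={wn[jj]} cm-1"
            )
        mats[pol] = pivot.to_numpy()
    try:
        return TransientSurface(wn, t, mats["par"], mats["perp"], meta)
    except ValueError as exc:
        raise SurfaceFormatError(f"{path}: {exc}") from exc
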