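"""Photoselection relations between transition-dipole angles and dichroic ratios.

A linearly polarized pump pulse preferentially excites molecules whose
electronic transition dipole moment (tdm) is aligned with the pump
polarization.  For an isotropic, orientationally frozen sample the induced
absorbance change probed parallel (:math:`A_\\parallel`) and perpendicular
(:math:`A_\\perp`) to the pump then encodes the angle :math:`\\Phi` between
the electronic tdm and the probed vibrational tdm through the dichroic
ratio :math:`d = A_\\parallel / A_\\perp`:

.. math::

    \\Phi(d) = \\arccos\\sqrt{\\frac{2d - 1}{d + 2}}

with the physically accessible range :math:`d \\in [0.5, 3]`
(:math:`\\Phi = 90°` and :math:`0°` respectively) and the magic angle
:math:`\\Phi \\approx 54.7356°` at :math:`d = 1`.

All public functions take and return angles in degrees, folded to
``[0, 90]`` because the sign of a tdm is not observable.  Internally the
math is in radians.  Functions are numpy-vectorized: scalars in, scalar
out; arrays in, arrays out.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "MAGIC_ANGLE_DEG",
    "D_MIN",
    "D_MAX",
    "OutOfRangeDichroicWarning",
    "order_parameter",
    "angle_from_dichroic",
    "dichroic_from_angle",
    "polarized_amplitudes",
    "isotropic_amplitude",
]

#: Magic angle in degrees, arccos(1/sqrt(3)).
MAGIC_ANGLE_DEG: float = float(np.degrees(np.arccos(1.0 / np.sqrt(3.0))))

#: Physical bounds of the dichroic ratio for a one-photon photoselected sample.
D_MIN: float = 0.5
D_MAX: float = 3.0


class OutOfRangeDichroicWarning(UserWarning):
    """A dichroic ratio outside [0.5, 3] was clamped to the physical boundary.

    Such values arise only from noise; the boundary estimate (0° or 90°)
    is returned and this warning acts as the boundary flag.
    """


def _check_phi(phi_deg) -> np.ndarray:
    phi = np.asarray(phi_deg, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise ValueError("angle must be finite")
    if np.any(phi < 0.0) or np.any(phi > 90.0):
        raise ValueError(f"angle must lie in [0, 90] degrees, got {phi_deg!r}")
    return phi


def order_parameter(phi_deg) -> np.ndarray | float:
    """Photoselection anisotropy factor r = (3 cos²Φ − 1) / 5.

    r spans [−1/5, 2/5] for Φ in [90°, 0°] and vanishes at the magic angle.
    """
    phi = _check_phi(phi_deg)
    c2 = np.cos(np.radians(phi)) ** 2
    r = (3.0 * c2 - 1.0) / 5.0
    return float(r) if np.isscalar(phi_deg) else r


def angle_from_dichroic(d) -> np.ndarray | float:
    """Invert the dichroic ratio to the tdm angle Φ in degrees.

    Parameters
    ----------
    d : float or array-like
        Dichroic ratio A_par / A_perp, strictly positive and finite.

    Returns
    -------
    float or ndarray
        Φ = arccos √((2d − 1)/(d + 2)) in degrees, in [0, 90].

    Notes
    -----
    Noise can push a measured ratio outside the physical range [0.5, 3];
    the arccos argument is then clamped to [0, 1], the boundary angle
    (90° or 0°) is returned, and :class:`OutOfRangeDichroicWarning` is
    emitted as the boundary flag.
    """
    darr = np.asarray(d, dtype=float)
    if not np.all(np.isfinite(darr)) or np.any(darr <= 0.0):
        raise ValueError(f"dichroic ratio must be finite and > 0, got {d!r}")
    arg = (2.0 * darr - 1.0) / (darr + 2.0)
    if np.any(arg < 0.0) or np.any(arg > 1.0):
        warnings.warn(
            "dichroic ratio outside the physical range [0.5, 3]; "
            "angle clamped to the [0, 90] degree boundary",
            OutOfRangeDichroicWarning,
            stacklevel=2,
        )
        arg = np.clip(arg, 0.0, 1.0)
    phi = np.degrees(np.arccos(np.sqrt(arg)))
    return float(phi) if np.isscalar(d) else phi


def dichroic_from_angle(phi_deg) -> np.ndarray | float:
    """Dichroic ratio d = (1 + 2r)/(1 − r) implied by a tdm angle (degrees).

    Exact inverse of :func:`angle_from_dichroic`; strictly decreasing from
    3 at Φ=0° to 0.5 at Φ=90°.
    """
    r = np.asarray(order_parameter(phi_deg))
    d = (1.0 + 2.0 * r) / (1.0 - r)
    return float(d) if np.isscalar(phi_deg) else d


def polarized_amplitudes(s_iso, phi_deg) -> tuple:
    """Split an isotropic amplitude into (parallel, perpendicular) channels.

    ``a_par = s_iso (1 + 2r)``, ``a_perp = s_iso (1 − r)`` with
    r = (3cos²Φ − 1)/5, so that ``a_par / a_perp`` equals
    :func:`dichroic_from_angle` and ``(a_par + 2 a_perp)/3`` recovers
    ``s_iso``.  The sign of ``s_iso`` (negative for bleaches) is preserved.
    """
    r = np.asarray(order_parameter(phi_deg))
    s = np.asarray(s_iso, dtype=float)
    a_par = s * (1.0 + 2.0 * r)
    a_perp = s * (1.0 - r)
    if np.isscalar(s_iso) and np.isscalar(phi_deg):
        return float(a_par), float(a_perp)
    return a_par, a_perp


def isotropic_amplitude(a_par, a_perp) -> np.ndarray | float:
    """Magic-angle (orientation-free) amplitude (a_par + 2 a_perp) / 3."""
    out = (np.asarray(a_par, dtype=float) + 2.0 * np.asarray(a_perp, dtype=float)) / 3.0
    if np.isscalar(a_par) and np.isscalar(a_perp):
        return float(out)
    return out
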