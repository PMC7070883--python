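"""Dichroic ratios and transition-dipole angles.

A polarized pump photoselects molecules aligned with its field; probing
parallel vs perpendicular then measures the angle between the electronic
transition dipole and the probed vibrational one through d = A_par/A_perp.
"""

from polir import photoselection as ps

print("dichroic ratio -> tdm angle (Eq. inversion):")
for d in (3.0, 2.0, 1.0, 0.7, 0.5):
    print(f"  d = {d:4.2f}  ->  phi = {ps.angle_from_dichroic(d):7.3f} deg")
# d = 3 means the vibrational tdm is parallel to the electronic one,
# d = 0.5 perpendicular, and d = 1 the 'magic angle' where orientation
# information vanishes.

print(f"\nmagic angle: {ps.MAGIC_ANGLE_DEG:.4f} deg")

s_iso = -1.0  # a bleaching band with -1 mOD isotropic amplitude
for phi in (0.0, 29.0, 45.0, 90.0):
    a_par, a_perp = ps.polarized_amplitudes(s_iso, phi)
    print(
        f"phi = {phi:4.1f} deg: A_par = {a_par:+.3f} mOD, A_perp = {a_perp:+.3f} mOD,"
        f" isotropic check = {ps.isotropic_amplitude(a_par, a_perp):+.3f} mOD"
    )
# The isotropic combination (A_par + 2 A_perp)/3 always returns the
# orientation-free amplitude, whatever the angle.
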