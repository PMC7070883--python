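"""Vibrational tdm directions from coordinates and angles to a probe axis.

A carboxyl C=O stretch has its tdm along the bond; a backbone amide I tdm
is the C=O direction tilted ~10 degrees (in D2O) toward the peptide
nitrogen inside the N-C-O plane.  On an idealized alpha-helix every
peptide plane is related by the helical screw, so all amide I angles to
the helix axis coincide - the geometric sanity check used here.
"""

from polir import structure as st

helix = st.ideal_helix_structure(n_res=14)
axis = st.helix_axis(helix)

groups = [
    {"kind": "amide", "chain": "A", "resnum": i, "label": f"amide I res {i}"}
    for i in range(3, 12)
]
table = st.angle_table(helix, axis, groups)
print(table[["label", "angle_deg"]].round(3).to_string(index=False))
print(
    f"\nspread: {table['angle_deg'].max() - table['angle_deg'].min():.2e} deg "
    "(identical by screw symmetry)"
)
# With a real electronic tdm axis (e.g. the retinal polyene chain via
# electronic_axis), the same table ranks which carbonyl groups match a
# measured polarization angle.

zero = st.relative_angle(
    st.amide_i_tdm(helix, "A", 5, rotation_deg=0.0),
    st.bond_tdm(helix, "A", 5, "C", "O"),
)
print(f"amide tdm at 0 deg rotation vs C=O bond: {zero:.2e} deg (identical)")
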