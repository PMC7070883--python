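"""Vibrational transition-dipole directions from protein coordinates.

Two field-standard heuristics are implemented.  A carboxylic-acid C=O
stretch has its tdm along the C=O bond.  The backbone amide I mode
couples to C–N stretching and N–H bending, which rotates its tdm by
about 10° (20° in H₂O) away from the C=O bond, inside the N–C–O plane
and toward the nitrogen; the default of 10° is the D₂O value.  The
peptide nitrogen is taken from residue i+1 — the N of the
C(i)=O(i)···N(i+1) peptide unit.

Relative angles between tdms are folded to [0, 90]° because tdm signs
are arbitrary.  Both heuristics neglect excitonic coupling between
neighbouring amide I oscillators.

PDB files are parsed with gemmi: first model only, and for alternate
locations the highest-occupancy conformer (first wins on ties).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd

from .photoselection import _check_phi  # angle-range validation reuse

__all__ = [
    "Atom",
    "Structure",
    "TdmVector",
    "StructureError",
    "GroupResolutionError",
    "load_structure",
    "save_pdb",
    "bond_tdm",
    "amide_i_tdm",
    "relative_angle",
    "electronic_axis",
    "axis_from_vector",
    "angle_table",
    "ideal_helix_structure",
]


class StructureError(ValueError):
    """Parsing or atom-lookup failure."""


class GroupResolutionError(StructureError):
    """One or more angle-table groups could not be resolved."""

    def __init__(self, failures: list):
        self.failures = failures
        super().__init__("unresolvable groups: " + "; ".join(failures))


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    resname: str
    chain: str
    resnum: int
    icode: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class Structure:
    """Flat atom list with (chain, resnum, icode, atom-name) lookup."""

    atoms: list
    name: str = ""
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for a in self.atoms:
            if not all(math.isfinite(v) for v in (a.x, a.y, a.z)):
                raise StructureError(f"non-finite coordinates for atom {a.name}")
            self._index.setdefault((a.chain, a.resnum, a.icode), {})[a.name] = a

    def atom(self, chain: str, resnum: int, name: str, icode: str = "") -> Atom:
        res = self._index.get((chain, resnum, icode))
        if res is None:
            raise StructureError(f"no residue {chain}/{resnum}{icode or ''}")
        if name not in res:
            raise StructureError(
                f"residue {chain}/{resnum} has no atom {name!r} "
                f"(has {sorted(res)})"
            )
        return res[name]

    def residue_ids(self) -> list:
        return sorted(self._index.keys())


@dataclass(frozen=True)
class TdmVector:
    """Unit transition-dipole direction anchored at a group's carbonyl carbon."""

    vector: np.ndarray
    anchor: np.ndarray
    label: str = ""

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=float)
        n = np.linalg.norm(v)
        if not np.isfinite(n) or abs(n - 1.0) > 1e-9:
            raise ValueError(f"tdm vector must be unit norm, |v| = {n}")
        object.__setattr__(self, "vector", v)
        object.__setattr__(self, "anchor", np.asarray(self.anchor, dtype=float))


def load_structure(path) -> Structure:
    """Parse a PDB file: first model, highest-occupancy altloc per atom."""
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, FileNotFoundError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]
    best: dict = {}
    order: list = []
    for chain in model:
        for res in chain:
            for atom in res:
                key = (chain.name, res.seqid.num, res.seqid.icode.strip(), atom.name)
                rec = Atom(
                    serial=atom.serial,
                    name=atom.name,
                    resname=res.name,
                    chain=chain.name,
                    resnum=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    x=atom.pos.x,
                    y=atom.pos.y,
                    z=atom.pos.z,
                    occupancy=atom.occ,
                    altloc=atom.altloc.strip("\x00").strip(),
                )
                if key not in best:
                    best[key] = rec
                    order.append(key)
                elif rec.occupancy > best[key].occupancy:  # ties keep the first altloc
                    best[key] = rec
    atoms = [best[k] for k in order]
    if not atoms:
        raise StructureError(f"{path}: no ATOM records")
    return Structure(atoms, name=str(path))


def save_pdb(structure: Structure, path) -> None:
    """Write minimal ATOM records (enough for round trips and fixtures)."""
    with open(path, "w") as fh:
        for i, a in enumerate(structure.atoms, start=1):
            element = a.name.strip()[0]
            fh.write(
                f"ATOM  {i:5d} {a.name:<4s}{a.resname:>3s} {a.chain:1s}"
                f"{a.resnum:4d}{a.icode or ' ':1s}   "
                f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {element:>2s}\n"
            )
        fh.write("END\n")


def _unit(v: np.ndarray, context: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-6:
        raise StructureError(f"degenerate geometry: {context}")
    return v / n


def bond_tdm(
    structure: Structure,
    chain: str,
    resnum: int,
    atom_from: str,
    atom_to: str,
    icode: str = "",
    label: str = "",
) -> TdmVector:
    """Unit vector along a bond, e.g. a carboxyl C=O (tdm along the bond)."""
    a = structure.atom(chain, resnum, atom_from, icode)
    b = structure.atom(chain, resnum, atom_to, icode)
    v = _unit(b.pos - a.pos, f"atoms {atom_from} and {atom_to} coincide")
    return TdmVector(v, a.pos, label or f"{chain}/{resnum} {atom_from}->{atom_to}")


def amide_i_tdm(
    structure: Structure,
    chain: str,
    resnum: int,
    rotation_deg: float = 10.0,
    icode: str = "",
    label: str = "",
) -> TdmVector:
    """Amide I tdm of residue ``resnum``: C=O tilted toward the peptide N.

    Uses backbone C, O of residue i and N of residue i+1.  The returned
    unit vector is cos(θ)·ê_CO + sin(θ)·p̂ where p̂ is the component of
    (N − C) orthogonal to ê_CO — i.e. the C=O direction rotated by θ
    within the N–C–O plane toward the nitrogen.  θ defaults to 10° (the
    D₂O value); use 20° for H₂O samples.
    """
    _check_phi(rotation_deg)
    c = structure.atom(chain, resnum, "C", icode)
    o = structure.atom(chain, resnum, "O", icode)
    n = structure.atom(chain, resnum + 1, "N")
    e_co = _unit(o.pos - c.pos, "C and O coincide")
    cn = n.pos - c.pos
    perp = cn - np.dot(cn, e_co) * e_co
    if np.linalg.norm(perp) < 1e-6:
        raise StructureError(
            f"N, C, O of {chain}/{resnum} are collinear; amide plane undefined"
        )
    p = perp / np.linalg.norm(perp)
    theta = math.radians(rotation_deg)
    v = math.cos(theta) * e_co + math.sin(theta) * p
    return TdmVector(v / np.linalg.norm(v), c.pos, label or f"{chain}/{resnum} amide I")


def relative_angle(v1: TdmVector, v2: TdmVector) -> float:
    """Angle between two tdm directions in degrees, folded to [0, 90]."""
    dot = abs(float(np.dot(v1.vector, v2.vector)))
    return math.degrees(math.acos(min(dot, 1.0)))


def electronic_axis(
    structure: Structure,
    chain: str,
    resnum: int,
    atom_from: str,
    atom_to: str,
    icode: str = "",
    label: str = "electronic tdm",
) -> TdmVector:
    """Electronic tdm proxy: the axis between two named chromophore atoms.

    Stands in for a computed excited-state tdm (e.g. along the retinal
    polyene chain between its terminal carbons).
    """
    return bond_tdm(structure, chain, resnum, atom_from, atom_to, icode, label)


def axis_from_vector(v, label: str = "electronic tdm") -> TdmVector:
    """Electronic tdm from a raw 3-vector supplied in config; normalized."""
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {arr.shape}")
    return TdmVector(_unit(arr, "zero electronic tdm vector"), np.zeros(3), label)


def angle_table(structure: Structure, axis: TdmVector, groups: list) -> pd.DataFrame:
    """Relative tdm angles for a list of group specs.

    Each group is a mapping with ``kind`` (``"amide"`` or ``"bond"``),
    ``chain``, ``resnum``, optional ``label``/``icode``; bond groups add
    ``atom_from``/``atom_to`` (e.g. CD→OE2 for a Glu carboxyl) and amide
    groups may override ``rotation_deg``.  All failures are collected and
    raised together as :class:`GroupResolutionError`.
    """
    rows = []
    failures = []
    for g in groups:
        try:
            kind = g["kind"]
            if kind == "amide":
                tdm = amide_i_tdm(
                    structure,
                    g["chain"],
                    g["resnum"],
                    rotation_deg=g.get("rotation_deg", 10.0),
                    icode=g.get("icode", ""),
                    label=g.get("label", ""),
                )
            elif kind == "bond":
                tdm = bond_tdm(
                    structure,
                    g["chain"],
                    g["resnum"],
                    g["atom_from"],
                    g["atom_to"],
                    icode=g.get("icode", ""),
                    label=g.get("label", ""),
                )
            else:
                raise StructureError(f"unknown group kind {kind!r}")
        except (StructureError, KeyError) as exc:
            failures.append(f"{g.get('label') or g}: {exc}")
            continue
        rows.append(
            {
                "label": tdm.label,
                "kind": kind,
                "chain": g["chain"],
                "resnum": g["resnum"],
                "vx": tdm.vector[0],
                "vy": tdm.vector[1],
                "vz": tdm.vector[2],
                "angle_deg": relative_angle(tdm, axis),
            }
        )
    if failures:
        raise GroupResolutionError(failures)
    columns = ["label", "kind", "chain", "resnum", "vx", "vy", "vz", "angle_deg"]
    return pd.DataFrame(rows, columns=columns)


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom D from chain A-B-C."""
    angle = math.radians(angle_deg)
    torsion = math.radians(torsion_deg)
    bc = _unit(c - b, "NeRF bc")
    n = _unit(np.cross(b - a, bc), "NeRF plane")
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def ideal_helix_structure(n_res: int = 12, chain: str = "A") -> Structure:
    """Idealized poly-alanine-like α-helix backbone (synthetic fixture).

    Built from standard internal coordinates (φ = −57°, ψ = −47°,
    ω = 180°) with the NeRF algorithm; atoms N, CA, C per residue plus a
    carbonyl O on the C(i)–N(i+1) bisector.  In a geometrically ideal
    helix all peptide planes are related by the helical screw, so amide I
    tdms make one common angle with the helix axis — the geometry oracle
    for orientation analyses.
    """
    if n_res < 2:
        raise ValueError("need at least 2 residues")
    b_n_ca, b_ca_c, b_c_n, b_c_o = 1.458, 1.525, 1.329, 1.231
    ang_n_ca_c, ang_ca_c_n, ang_c_n_ca = 111.2, 116.2, 121.7
    phi, psi, omega = -57.0, -47.0, 180.0

    # seed the first three backbone atoms, then extend with NeRF
    coords = [np.array([0.0, 0.0, 0.0]), np.array([b_n_ca, 0.0, 0.0])]
    ang = math.radians(ang_n_ca_c)
    coords.append(
        coords[1]
        + b_ca_c * np.array([-math.cos(ang), math.sin(ang), 0.0])
    )
    kinds = ["N", "CA", "C"]
    # build one extra residue so the last kept residue has its peptide N
    for _ in range(n_res):
        a, b, c = coords[-3], coords[-2], coords[-1]
        coords.append(_place_atom(a, b, c, b_c_n, ang_ca_c_n, psi))
        coords.append(_place_atom(b, c, coords[-1], b_n_ca, ang_c_n_ca, omega))
        coords.append(_place_atom(c, coords[-2], coords[-1], b_ca_c, ang_n_ca_c, phi))
        kinds += ["N", "CA", "C"]

    atoms = []
    serial = 0
    n_built = len(coords) // 3
    for i in range(n_built):
        res_atoms = {k: coords[3 * i + j] for j, k in enumerate(("N", "CA", "C"))}
        if i + 1 < n_built:
            n_next = coords[3 * (i + 1)]
            c_pos = res_atoms["C"]
            bis = _unit(
                _unit(c_pos - res_atoms["CA"], "O dir") + _unit(c_pos - n_next, "O dir"),
                "O bisector",
            )
            res_atoms["O"] = c_pos + b_c_o * bis
        for name in ("N", "CA", "C", "O"):
            if name not in res_atoms:
                continue
            serial += 1
            x, y, z = res_atoms[name]
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    resname="ALA",
                    chain=chain,
                    resnum=i + 1,
                    icode="",
                    x=float(x),
                    y=float(y),
                    z=float(z),
                )
            )
    kept = [a for a in atoms if a.resnum <= n_res + 1]
    return Structure(kept, name=f"ideal_helix_{n_res}")


def helix_axis(structure: Structure, chain: str = "A") -> TdmVector:
    """Screw axis of a helical CA trace.

    Successive chord differences ``w_i = CA(i+2) − 2·CA(i+1) + CA(i)`` are
    perpendicular to the screw axis, so the cross product of neighbouring
    ``w_i`` recovers the axis exactly for ideal geometry (a principal-axis
    fit is biased when the helix spans a non-integer number of turns).
    """
    ca = np.array(
        [a.pos for a in structure.atoms if a.name == "CA" and a.chain == chain]
    )
    if len(ca) < 4:
        raise StructureError("need >= 4 CA atoms for a helix axis")
    w = np.diff(ca, n=2, axis=0)
    crosses = np.cross(w[:-1], w[1:])
    rise = ca[-1] - ca[0]
    crosses[np.einsum("ij,j->i", crosses, rise) < 0] *= -1.0
    return TdmVector(_unit(crosses.sum(axis=0), "helix axis"), ca.mean(axis=0), "helix axis")
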