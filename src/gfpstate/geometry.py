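"""Chromophore-environment geometry: distances, χ1 torsions, rotamer wells,
hydrogen-bond strength bins and the Gln222 amide-orientation call.

Hydrogen bonds are assigned from donor–acceptor heavy-atom distance alone —
the crystal structures carry no hydrogens, so no angular criterion is
applied (a documented limitation).  The strength bins follow the standard
crystallographic convention: 2.5 ≤ d ≤ 3.0 Å normal, 3.0 < d ≤ 3.5 Å weak,
d > 3.5 Å no bond, d < 2.5 Å flagged as a clash; a distance of exactly
3.0 Å or 3.5 Å is resolved toward the stronger class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .structure_io import Atom, SiteLookupError, StructureModel, find_bridging_water, resolve_site

__all__ = [
    "HBondStrengthScheme",
    "GeometryReport",
    "GeometryError",
    "distance",
    "dihedral",
    "chi1",
    "classify_rotamer",
    "classify_hbond",
    "gln222_orientation",
    "measure",
]


class GeometryError(ValueError):
    """Degenerate geometry (e.g. collinear points in a torsion)."""


@dataclass(frozen=True)
class HBondStrengthScheme:
    """Distance bins for donor–acceptor heavy-atom hydrogen-bond strength (Å)."""

    clash_below: float = 2.5
    normal_max: float = 3.0
    weak_max: float = 3.5

    def __post_init__(self) -> None:
        if not (self.clash_below < self.normal_max < self.weak_max):
            raise ValueError("strength bins must be ordered clash < normal < weak")


DEFAULT_SCHEME = HBondStrengthScheme()


@dataclass
class GeometryReport:
    """The named measurements for one structure.

    ``d_his`` is Nδ1(His148)···Oη(chromophore); ``d_203`` is the distal
    position-203 atom (Oγ1 for Thr, Cγ2 for Val/Ile) to Oη; ``d_wat3`` the
    chromophore-Oη···bridging-water distance (absent when no bridging water
    is found); ``d_val_cz`` the Val203 Cγ1···Cζ van der Waals contact
    (present only for Val).  Distances in Å, angles in degrees.
    """

    structure_id: str
    d_his: float
    d_203: float
    pos203_residue: str
    pos203_distal_atom: str
    chi1_203: float
    rotamer_203: str
    gln222_orientation: str
    d_wat3: Optional[float] = None
    d_val_cz: Optional[float] = None
    hbond_list: list = field(default_factory=list)
    sigma_his: Optional[float] = None
    sigma_203: Optional[float] = None
    sigma_wat3: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def distance(a: Atom, b: Atom) -> float:
    """Euclidean distance between two atoms in Å."""
    return float(np.linalg.norm(a.position - b.position))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1–p2–p3–p4 in degrees, IUPAC convention.

    The angle lies in (−180, 180]; positive means clockwise rotation of the
    far bond when viewed from p2 toward p3.  Raises :class:`GeometryError`
    when three consecutive points are collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or b2n < 1e-10:
        raise GeometryError("collinear or coincident points in dihedral")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / b2n)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


_CHI1_GAMMA = {"THR": "OG1", "VAL": "CG1", "ILE": "CG1", "SER": "OG",
               "GLN": "CG", "GLU": "CG", "HIS": "CG"}


def chi1(model: StructureModel, residue_number: int) -> float:
    """First side-chain torsion N–CA–CB–γ of the numbered residue (degrees)."""
    atoms = model.residue_atoms(residue_number)
    if not atoms:
        raise SiteLookupError(f"no residue {residue_number}")
    resname = atoms[0].residue_name
    gamma = _CHI1_GAMMA.get(resname)
    if gamma is None:
        raise SiteLookupError(f"chi1 undefined for residue type {resname}")
    pts = []
    for name in ("N", "CA", "CB", gamma):
        hit = [a for a in atoms if a.atom_name == name]
        if not hit:
            raise SiteLookupError(
                f"residue {resname}{residue_number} lacks atom {name} for chi1")
        pts.append(min(hit, key=lambda a: (-a.occupancy, a.altloc)).position)
    return dihedral(*pts)


def classify_rotamer(chi1_deg: float) -> str:
    """Rotamer well for a χ1 angle in (−180, 180].

    gauche− for χ1 ∈ [−120, 0), gauche+ for [0, 120), trans otherwise — a
    full partition with inclusive lower edges.
    """
    if not (-180.0 < chi1_deg <= 180.0):
        raise ValueError(f"chi1 {chi1_deg} outside (-180, 180]")
    if -120.0 <= chi1_deg < 0.0:
        return "gauche-"
    if 0.0 <= chi1_deg < 120.0:
        return "gauche+"
    return "trans"


def classify_hbond(d: float, scheme: HBondStrengthScheme = DEFAULT_SCHEME) -> str:
    """Strength class of a donor–acceptor heavy-atom distance (Å)."""
    if d <= 0:
        raise ValueError(f"non-positive distance {d}")
    if d < scheme.clash_below:
        return "clash"
    if d <= scheme.normal_max:
        return "normal"
    if d <= scheme.weak_max:
        return "weak"
    return "none"


def gln222_orientation(model: StructureModel, tie_threshold: float = 0.2) -> str:
    """Which Gln222 amide atom faces the Ser65 hydroxyl.

    Compares d(Oε1, Oγ-65) with d(Nε2, Oγ-65); the closer atom defines the
    orientation.  Differences below ``tie_threshold`` (Å) — conservative for
    1.2–1.5 Å-resolution data — give ``"undetermined"``.  Wild-type Glu222
    is handled by the same geometry with Oε1/Oε2.
    """
    atoms = model.residue_atoms(222)
    if not atoms:
        raise SiteLookupError("no residue 222")
    resname = atoms[0].residue_name
    if resname == "GLN":
        a1, a2, lab1, lab2 = "OE1", "NE2", "OE1->Ser65", "NE2->Ser65"
    elif resname == "GLU":
        a1, a2, lab1, lab2 = "OE1", "OE2", "OE1->Ser65", "OE2->Ser65"
    else:
        raise SiteLookupError(f"residue 222 is {resname}, expected GLN or GLU")
    og65 = resolve_site(model, "chromophore.hydroxyl")
    d1 = distance(resolve_site(model, f"pos222.{a1}"), og65)
    d2 = distance(resolve_site(model, f"pos222.{a2}"), og65)
    if abs(d1 - d2) < tie_threshold:
        return "undetermined"
    return lab1 if d1 < d2 else lab2


def _hbond_entry(site_a: str, atom_a: Atom, site_b: str, atom_b: Atom,
                 scheme: HBondStrengthScheme) -> Optional[dict]:
    d = distance(atom_a, atom_b)
    cls = classify_hbond(d, scheme)
    if cls == "none":
        return None
    return {"donor": site_a, "acceptor": site_b, "distance": round(d, 4),
            "strength": cls}


def measure(model: StructureModel, scheme: HBondStrengthScheme = DEFAULT_SCHEME,
            water_cutoff: float = 3.5) -> GeometryReport:
    """Full geometry report for one structure.

    Requires His148, a residue at position 203 and a chromophore to be
    resolvable; the bridging water (Wat3, operationally the water within
    ``water_cutoff`` of both chromophore-Oη and Ser205-Oγ minimising the
    summed distance) and the Val-specific Cγ1···Cζ contact are optional.
    """
    oh = resolve_site(model, "chromophore.OH")
    nd1 = resolve_site(model, "His148.ND1")
    distal = resolve_site(model, "pos203.distal")
    pos203 = model.residue_atoms(203)[0].residue_name

    d_his = distance(nd1, oh)
    d_203 = distance(distal, oh)
    chi = chi1(model, 203)

    d_val_cz = None
    if pos203 == "VAL":
        cz = resolve_site(model, "chromophore.CZ")
        cg1 = resolve_site(model, "pos203.CG1")
        d_val_cz = distance(cg1, cz)

    d_wat3 = None
    wat3 = None
    try:
        wat3 = find_bridging_water(
            model, ("chromophore.OH", "Ser205.OG"), cutoff=water_cutoff)
    except SiteLookupError:
        pass
    if wat3 is not None:
        d_wat3 = distance(wat3, oh)

    try:
        orientation = gln222_orientation(model)
    except SiteLookupError:
        orientation = "undetermined"

    hbonds = []
    e = _hbond_entry("His148.ND1", nd1, "CRO.OH", oh, scheme)
    if e:
        hbonds.append(e)
    if distal.element in ("O", "N"):
        e = _hbond_entry(f"pos203.{distal.atom_name}", distal, "CRO.OH", oh, scheme)
        if e:
            hbonds.append(e)
    if wat3 is not None:
        e = _hbond_entry("Wat3.O", wat3, "CRO.OH", oh, scheme)
        if e:
            hbonds.append(e)
        try:
            og205 = resolve_site(model, "Ser205.OG")
            e = _hbond_entry("Wat3.O", wat3, "Ser205.OG", og205, scheme)
            if e:
                hbonds.append(e)
        except SiteLookupError:
            pass

    return GeometryReport(
        structure_id=model.structure_id,
        d_his=d_his,
        d_203=d_203,
        pos203_residue=pos203,
        pos203_distal_atom=distal.atom_name,
        chi1_203=chi,
        rotamer_203=classify_rotamer(chi),
        gln222_orientation=orientation,
        d_wat3=d_wat3,
        d_val_cz=d_val_cz,
        hbond_list=hbonds,
    )
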