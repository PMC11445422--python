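"""Synthetic fixtures: GFP-like structure clusters, titration datasets and
small atom sets for RDG tests — every input the pipeline needs, generated
in code with no downloads.

Structure fixtures contain only the residues the measurements touch (the
chromophore, His148, the position-203 residue, Ser205, Gln222 and the
bridging water), not the full β-barrel.  Atoms are placed by explicit
construction — the chromophore phenolate oxygen Oη sits at the origin and
each partner is set along a prescribed direction at the prescribed
distance, with side-chain torsions built by natural-extension (NeRF)
placement — so realized geometry matches the preset exactly rather than by
optimisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .rdg import DensityModel
from .structure_io import Atom, StructureModel, write_pdb
from .titration import TitrationDataset, hh_fraction

__all__ = [
    "StructurePreset", "TitrationPreset", "ConstructionError",
    "STRUCTURE_PRESETS", "DEFAULT_TITRATION_PRESET", "TITRATION_PRESETS",
    "build_structure", "build_titration", "build_density_fixture",
    "random_structure_preset", "place_atom",
]


class ConstructionError(ValueError):
    """A preset's geometric constraints cannot be realised."""


@dataclass(frozen=True)
class StructurePreset:
    """Prescribed geometry for one synthetic structure."""

    name: str
    d_his: float                     # Nδ1(His148)···Oη, Å
    pos203_residue: str              # THR / VAL / ILE
    d_203: float                     # distal 203 atom···Oη, Å
    chi1_203: float = -60.0          # degrees
    gln222_orientation: str = "NE2->Ser65"   # which amide atom faces Oγ-65
    include_wat3: bool = True
    d_wat3: float = 2.7              # Oη···water O, Å
    dpi: float = 0.07                # Å
    b_profile: str = "uniform"       # uniform | ramp

    def __post_init__(self) -> None:
        for label, d in (("d_his", self.d_his), ("d_203", self.d_203),
                         ("d_wat3", self.d_wat3)):
            if not (2.0 < d < 6.0):
                raise ConstructionError(f"{label}={d} outside the feasible (2, 6) Å")
        if not (-180.0 < self.chi1_203 <= 180.0):
            raise ConstructionError(f"chi1_203={self.chi1_203} outside (-180, 180]")
        if self.pos203_residue not in ("THR", "VAL", "ILE"):
            raise ConstructionError(f"unsupported residue {self.pos203_residue} at 203")
        if self.b_profile not in ("uniform", "ramp"):
            raise ConstructionError(f"unknown b_profile {self.b_profile}")


#: the five exemplar presets: an I-state structure, two A-state structures
#: and two B-state structures, with the His148 distances at the printed
#: exemplar values (2.85 Å normal-strength, 3.24 Å weak)
STRUCTURE_PRESETS: Dict[str, StructurePreset] = {
    "I_like": StructurePreset(
        name="I_like", d_his=2.85, pos203_residue="VAL", d_203=3.6,
        chi1_203=-60.0, gln222_orientation="NE2->Ser65"),
    "A_like_low_pH": StructurePreset(
        name="A_like_low_pH", d_his=3.24, pos203_residue="VAL", d_203=3.6,
        chi1_203=-60.0, gln222_orientation="OE1->Ser65"),
    "A_like_wt": StructurePreset(
        name="A_like_wt", d_his=3.30, pos203_residue="THR", d_203=3.4,
        chi1_203=-60.0, gln222_orientation="OE1->Ser65"),
    "B_like_S65T": StructurePreset(
        name="B_like_S65T", d_his=2.80, pos203_residue="THR", d_203=2.8,
        chi1_203=60.0, gln222_orientation="NE2->Ser65"),
    "B_like_E222Q": StructurePreset(
        name="B_like_E222Q", d_his=2.90, pos203_residue="THR", d_203=2.7,
        chi1_203=60.0, gln222_orientation="NE2->Ser65"),
}


@dataclass(frozen=True)
class TitrationPreset:
    """Two-state titration with Henderson–Hasselbalch structure and
    replicate noise."""

    name: str
    pka_true: float = 6.0
    noise_sd: float = 0.02
    ph_grid: Tuple[float, ...] = tuple(np.round(np.linspace(4.0, 8.5, 10), 3))
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


DEFAULT_TITRATION_PRESET = TitrationPreset(name="T203V_E222Q")
TITRATION_PRESETS = {"T203V_E222Q": DEFAULT_TITRATION_PRESET}


# ---------------------------------------------------------------------------
# geometric construction

def place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d with |cd| = bond, ∠(b,c,d) = angle and torsion(a,b,c,d)
    = torsion (IUPAC sign), by natural-extension reference-frame placement."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_hat)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ConstructionError("collinear reference atoms in place_atom")
    n_hat = n / nn
    m_hat = np.cross(n_hat, bc_hat)
    frame = np.column_stack([bc_hat, m_hat, n_hat])
    return c + frame @ local


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _rotation_between(v1, v2) -> np.ndarray:
    """Rotation matrix taking unit vector v1 onto unit vector v2 (Rodrigues)."""
    v1, v2 = _unit(v1), _unit(v2)
    cross = np.cross(v1, v2)
    dot = float(np.dot(v1, v2))
    if np.linalg.norm(cross) < 1e-12:
        if dot > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        perp = _unit(np.cross(v1, [1.0, 0.0, 0.0]) if abs(v1[0]) < 0.9
                     else np.cross(v1, [0.0, 1.0, 0.0]))
        return 2.0 * np.outer(perp, perp) - np.eye(3)
    k = cross
    kmat = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + kmat + kmat @ kmat * (1.0 / (1.0 + dot))


def _rig(atoms: Dict[str, np.ndarray], anchor: str, target: np.ndarray,
         away: np.ndarray, body_ref: str) -> Dict[str, np.ndarray]:
    """Rigidly move a local residue template so ``anchor`` lands on ``target``
    with the anchor→``body_ref`` direction along ``away`` (pointing out of the
    measured cluster).  Rigid motion preserves all internal geometry."""
    anchor_pos = atoms[anchor]
    rot = _rotation_between(atoms[body_ref] - anchor_pos, away)
    return {name: rot @ (p - anchor_pos) + target for name, p in atoms.items()}


# fixed, well-separated directions from the chromophore Oη (unit vectors)
_DIR_HIS = _unit([0.15, 0.95, 0.27])
_DIR_203 = _unit([0.30, -0.80, 0.52])
_DIR_WAT = _unit([-0.20, 0.40, -0.89])


def _his148_template() -> Dict[str, np.ndarray]:
    # imidazole ring + backbone stub, idealised local coordinates (Å)
    return {
        "N":   np.array([-3.00, 2.20, 0.00]),
        "CA":  np.array([-2.40, 1.00, 0.55]),
        "CB":  np.array([-1.10, 0.70, -0.18]),
        "CG":  np.array([-0.55, -0.62, 0.10]),
        "ND1": np.array([0.00, 0.00, 0.00]),
        "CD2": np.array([-0.85, -1.93, 0.25]),
        "CE1": np.array([0.55, -1.20, 0.20]),
        "NE2": np.array([0.05, -2.32, 0.35]),
    }


def _pos203_template(resname: str, chi1: float) -> Tuple[Dict[str, np.ndarray], str]:
    """Backbone + side chain with the requested χ1; returns (atoms, distal name)."""
    atoms = {
        "N": np.array([0.0, 0.0, 0.0]),
        "CA": np.array([1.458, 0.0, 0.0]),
        "C": np.array([2.00, 1.20, 0.75]),
        "O": np.array([1.40, 2.26, 0.85]),
    }
    ang = math.radians(180.0 - 110.5)
    atoms["CB"] = atoms["CA"] + 1.53 * np.array([math.cos(ang), math.sin(ang), 0.0])
    n, ca, cb = atoms["N"], atoms["CA"], atoms["CB"]
    if resname == "THR":
        atoms["OG1"] = place_atom(n, ca, cb, 1.43, 109.5, chi1)
        atoms["CG2"] = place_atom(n, ca, cb, 1.53, 110.5, chi1 - 120.0)
        distal = "OG1"
    elif resname == "VAL":
        atoms["CG1"] = place_atom(n, ca, cb, 1.53, 110.5, chi1)
        atoms["CG2"] = place_atom(n, ca, cb, 1.53, 110.5, chi1 + 120.0)
        distal = "CG2"
    else:  # ILE: chi1 defined on CG1
        atoms["CG1"] = place_atom(n, ca, cb, 1.53, 110.5, chi1)
        atoms["CG2"] = place_atom(n, ca, cb, 1.53, 110.5, chi1 + 120.0)
        atoms["CD1"] = place_atom(ca, cb, atoms["CG1"], 1.53, 113.0, 170.0)
        distal = "CG2"
    return atoms, distal


def _ser205_template() -> Dict[str, np.ndarray]:
    atoms = {
        "N": np.array([0.0, 0.0, 0.0]),
        "CA": np.array([1.458, 0.0, 0.0]),
    }
    ang = math.radians(180.0 - 110.5)
    atoms["CB"] = atoms["CA"] + 1.53 * np.array([math.cos(ang), math.sin(ang), 0.0])
    atoms["OG"] = place_atom(atoms["N"], atoms["CA"], atoms["CB"], 1.43, 110.5, -65.0)
    return atoms


def _chromophore_atoms() -> Dict[str, np.ndarray]:
    """Minimal chromophore (CRO): phenolate Oη at the origin, ring carbon
    Cζ, imidazolinone O2/N2 and the Thr65-derived hydroxyl Oγ1."""
    return {
        "OH": np.array([0.0, 0.0, 0.0]),
        "CZ": np.array([-1.36, 0.0, 0.0]),
        "CE1": np.array([-2.08, 1.18, 0.05]),
        "CE2": np.array([-2.06, -1.19, -0.05]),
        "O2": np.array([-6.80, 1.45, 0.40]),
        "N2": np.array([-5.95, -0.62, 0.30]),
        "OG1": np.array([-7.40, 0.20, 1.60]),
        "CB2": np.array([-4.30, 0.45, 0.10]),
    }


def _gln222_atoms(og65: np.ndarray, orientation: str) -> Dict[str, np.ndarray]:
    """Place the Gln222 amide so the requested atom is 2.7 Å from Oγ-65 and
    the other 3.3 Å, with a planar amide of standard internal geometry."""
    u4 = _unit([-0.45, -0.30, 0.84])
    t = _unit(np.cross(u4, [0.0, 0.0, 1.0]))
    near = og65 + 2.7 * u4
    # far atom 2.25 Å from the near one and 3.3 Å from Oγ-65
    cos_th = (3.3 ** 2 - 2.7 ** 2 - 2.25 ** 2) / (2 * 2.7 * 2.25)
    th = math.acos(max(-1.0, min(1.0, cos_th)))
    w = math.cos(th) * u4 + math.sin(th) * t
    far = near + 2.25 * w
    ab = _unit(far - near)
    x = (1.23 ** 2 - 1.33 ** 2 + 2.25 ** 2) / (2 * 2.25)
    h = math.sqrt(max(1.23 ** 2 - x ** 2, 0.0))
    perp = _unit(np.cross(ab, u4))
    cd = near + x * ab + h * perp
    out = _unit(cd - og65)
    cg = cd + 1.52 * out
    cb = cg + 1.53 * _unit(out + 0.3 * perp)
    ca = cb + 1.53 * _unit(out - 0.2 * t)
    n = ca + 1.46 * out
    if orientation == "OE1->Ser65":
        oe1, ne2 = near, far
    elif orientation == "NE2->Ser65":
        ne2, oe1 = near, far
    else:
        raise ConstructionError(f"unknown gln222_orientation {orientation!r}")
    return {"N": n, "CA": ca, "CB": cb, "CG": cg, "CD": cd,
            "OE1": oe1, "NE2": ne2}


def build_structure(preset: StructurePreset, seed: int = 0,
                    out_path=None) -> StructureModel:
    """Realise a preset as a :class:`StructureModel` (optionally written as
    a PDB file with a DPI remark).  Construction is deterministic: the same
    preset and seed give byte-identical PDB output."""
    placed: List[Tuple[int, str, str, np.ndarray]] = []  # resnum, resname, atom, pos

    cro = _chromophore_atoms()
    for name, pos in cro.items():
        placed.append((66, "CRO", name, pos))

    his = _rig(_his148_template(), "ND1", preset.d_his * _DIR_HIS,
               away=_DIR_HIS, body_ref="CB")
    for name, pos in his.items():
        placed.append((148, "HIS", name, pos))

    local203, distal = _pos203_template(preset.pos203_residue, preset.chi1_203)
    res203 = _rig(local203, distal, preset.d_203 * _DIR_203,
                  away=_DIR_203, body_ref="CB")
    for name, pos in res203.items():
        placed.append((203, preset.pos203_residue, name, pos))

    wat_pos = None
    if preset.include_wat3:
        wat_pos = preset.d_wat3 * _DIR_WAT
        og205_target = wat_pos + 2.7 * _DIR_WAT
    else:
        og205_target = 6.0 * _DIR_WAT
    ser205 = _rig(_ser205_template(), "OG", og205_target,
                  away=_DIR_WAT, body_ref="CB")
    for name, pos in ser205.items():
        placed.append((205, "SER", name, pos))

    gln = _gln222_atoms(cro["OG1"], preset.gln222_orientation)
    for name, pos in gln.items():
        placed.append((222, "GLN", name, pos))

    if wat_pos is not None:
        placed.append((401, "HOH", "O", wat_pos))

    atoms: List[Atom] = []
    for i, (resnum, resname, atname, pos) in enumerate(placed):
        b = 20.0 if preset.b_profile == "uniform" else 10.0 + 1.0 * i
        element = atname[0] if atname[0] in ("N", "O", "C", "S") else "C"
        atoms.append(Atom(
            chain_id="A", residue_number=resnum, residue_name=resname,
            atom_name=atname, altloc="", occupancy=1.0, b_factor=b,
            position=pos, element=element))

    model = StructureModel(structure_id=preset.name, atoms=atoms, dpi=preset.dpi)
    if out_path is not None:
        write_pdb(model, out_path)
    return model


def random_structure_preset(rng: np.random.Generator) -> StructurePreset:
    """Draw a feasible random preset (for round-trip self-consistency tests)."""
    resname = rng.choice(["THR", "VAL", "ILE"])
    return StructurePreset(
        name=f"random_{rng.integers(1_000_000)}",
        d_his=float(rng.uniform(2.5, 4.0)),
        pos203_residue=str(resname),
        d_203=float(rng.uniform(2.5, 4.2)),
        chi1_203=float(rng.uniform(-179.0, 180.0)),
        gln222_orientation=str(rng.choice(["OE1->Ser65", "NE2->Ser65"])),
        include_wat3=bool(rng.random() < 0.8),
        d_wat3=float(rng.uniform(2.5, 3.4)),
        dpi=float(rng.uniform(0.05, 0.10)),
        b_profile=str(rng.choice(["uniform", "ramp"])),
    )


def build_titration(preset: TitrationPreset = DEFAULT_TITRATION_PRESET,
                    seed: int = 0) -> TitrationDataset:
    """Two-state fractions on the preset pH grid with replicate Gaussian
    noise, clipped to [0, 1]; reproducible for a fixed seed."""
    rng = np.random.default_rng(seed)
    ph, frac, sd, rep = [], [], [], []
    for r in range(preset.replicates):
        for p in preset.ph_grid:
            f = hh_fraction(p, preset.pka_true)
            if preset.noise_sd > 0:
                f = float(np.clip(f + rng.normal(0.0, preset.noise_sd), 0.0, 1.0))
            ph.append(p)
            frac.append(f)
            sd.append(max(preset.noise_sd, 1e-6))
            rep.append(r)
    return TitrationDataset(ph=np.array(ph), fraction=np.array(frac),
                            sd=np.array(sd), replicate_id=np.array(rep))


def build_density_fixture(kind: str) -> DensityModel:
    """Small atom sets with documented exact geometry for RDG tests.

    * ``single_atom`` — one H at the origin;
    * ``vdw_pair`` — two Ne atoms at 3.1 Å (van der Waals contact);
    * ``hbond_triplet`` — N–H···O with H on the N–O axis 1.0 Å from N and
      the heavy atoms 2.85 Å apart (the exemplar hydrogen-bond length).
    """
    if kind == "single_atom":
        return DensityModel(elements=["H"], positions=np.array([[0.0, 0.0, 0.0]]))
    if kind == "vdw_pair":
        return DensityModel(elements=["NE", "NE"],
                            positions=np.array([[0.0, 0.0, 0.0], [3.1, 0.0, 0.0]]))
    if kind == "hbond_triplet":
        return DensityModel(
            elements=["N", "H", "O"],
            positions=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                                [2.85, 0.0, 0.0]]))
    raise ValueError(f"unknown fixture kind {kind!r} "
                     "(single_atom / vdw_pair / hbond_triplet)")
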