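"""Reading protein structures into a uniform atom model.

PDB and mmCIF files are parsed with :mod:`gemmi`; every ATOM/HETATM record is
retained with its altloc, occupancy and B-factor.  On top of the flat atom
list a small semantic-site vocabulary maps keys such as ``"His148.ND1"``,
``"CRO.OH"`` or ``"pos203.distal"`` to concrete atoms, resolving the
Greek-letter names used in the structural-biology literature (Nδ1, Oη, Cζ …)
to PDB component atom codes and applying a deterministic altloc policy
(highest occupancy, ties broken by altloc letter).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "StructureModel",
    "SiteVocabulary",
    "StructureParseError",
    "SiteLookupError",
    "read_structure",
    "write_pdb",
    "resolve_site",
    "find_bridging_water",
]

#: residue codes accepted as the (Ser65/Thr65)-Tyr66-Gly67 chromophore
DEFAULT_CHROMOPHORE_CODES = frozenset({"CRO", "GYS", "CR2", "CSY"})

#: residue names recognised as water
WATER_CODES = frozenset({"HOH", "WAT"})

#: Greek-letter atom labels -> PDB component atom codes
GREEK_TO_PDB = {
    "Nδ1": "ND1", "Nd1": "ND1",
    "Nε2": "NE2", "Ne2": "NE2",
    "Oη": "OH", "Oh": "OH",
    "Cζ": "CZ", "Cz": "CZ",
    "Oγ": "OG", "Og": "OG",
    "Oγ1": "OG1", "Og1": "OG1",
    "Cγ1": "CG1", "Cg1": "CG1",
    "Cγ2": "CG2", "Cg2": "CG2",
    "Oε1": "OE1", "Oe1": "OE1",
    "Oε2": "OE2", "Oe2": "OE2",
    "Cβ": "CB", "Cb": "CB",
    "O2": "O2",
    "N2": "N2",
}


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be read or has an unknown format."""


class SiteLookupError(KeyError):
    """Raised when a semantic site key cannot be resolved to a single atom."""


@dataclass(frozen=True)
class Atom:
    """One crystallographic atom record.

    Coordinates are in Å as deposited (right-handed, no symmetry expansion);
    ``b_factor`` in Å²; ``occupancy`` a fraction in [0, 1].
    """

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    altloc: str
    occupancy: float
    b_factor: float
    position: np.ndarray
    element: str

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        object.__setattr__(self, "position", pos)
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.b_factor < 0:
            raise ValueError(f"negative B-factor {self.b_factor}")
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"position must be a finite 3-vector, got {pos!r}")

    @property
    def is_water(self) -> bool:
        return self.residue_name in WATER_CODES

    def __repr__(self) -> str:  # compact: chain/residue/atom/altloc
        alt = f"[{self.altloc}]" if self.altloc else ""
        return (f"Atom({self.chain_id}/{self.residue_name}{self.residue_number}"
                f"/{self.atom_name}{alt})")


@dataclass(frozen=True)
class SiteVocabulary:
    """Maps the literature's Greek atom labels to PDB codes and names the
    residue codes accepted as the chromophore."""

    chromophore_codes: frozenset = DEFAULT_CHROMOPHORE_CODES
    greek_to_pdb: Mapping[str, str] = field(default_factory=lambda: dict(GREEK_TO_PDB))

    def atom_code(self, label: str) -> str:
        return self.greek_to_pdb.get(label, label.upper())


DEFAULT_VOCABULARY = SiteVocabulary()


@dataclass
class StructureModel:
    """A parsed structure: ordered atoms plus refinement metadata.

    ``dpi`` is the diffraction-precision index (average coordinate error, Å)
    from refinement; it is an input, never computed here.  ``b_average`` is
    the occupancy-weighted mean B-factor over all atoms.
    """

    structure_id: str
    atoms: list
    dpi: Optional[float] = None
    vocabulary: SiteVocabulary = field(default_factory=SiteVocabulary)

    @property
    def b_average(self) -> float:
        w = np.array([a.occupancy for a in self.atoms])
        b = np.array([a.b_factor for a in self.atoms])
        if w.sum() <= 0:
            raise ValueError("cannot average B over zero total occupancy")
        return float((w * b).sum() / w.sum())

    def residues(self) -> dict:
        """Group atoms as {(chain, resnum, resname): [Atom, ...]} preserving order."""
        out: dict = {}
        for a in self.atoms:
            out.setdefault((a.chain_id, a.residue_number, a.residue_name), []).append(a)
        return out

    def residue_atoms(self, residue_number: int,
                      residue_name: Optional[str] = None) -> list:
        hits = [a for a in self.atoms
                if a.residue_number == residue_number and not a.is_water
                and (residue_name is None or a.residue_name == residue_name)]
        return hits

    def waters(self) -> list:
        return [a for a in self.atoms if a.is_water and a.element == "O"]


def _strip(name: str) -> str:
    return name.strip()


def read_structure(path, format: str = "auto",
                   dpi: Optional[float] = None,
                   vocabulary: Optional[SiteVocabulary] = None) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    path
        Coordinate file.  ``format`` may be ``"pdb"``, ``"mmcif"`` or
        ``"auto"`` (extension-based).
    dpi
        Diffraction-precision index in Å.  If not given, a ``REMARK   3
        ... DPI`` line in a PDB file is honoured when present.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"no such file: {path}")
    fmt = format.lower()
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix in (".pdb", ".ent"):
            fmt = "pdb"
        elif suffix in (".cif", ".mmcif"):
            fmt = "mmcif"
        else:
            raise StructureParseError(
                f"cannot infer format from extension {suffix!r}; pass format=")
    if fmt not in ("pdb", "mmcif"):
        raise StructureParseError(f"unknown format {format!r} (use pdb/mmcif/auto)")

    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"failed to parse {path} as {fmt}: {exc}") from exc

    atoms: list = []
    model = st[0]
    for chain in model:
        for res in chain:
            if res.seqid.icode not in ("", " "):
                raise StructureParseError(
                    f"insertion code {res.seqid.icode!r} at residue "
                    f"{res.seqid.num} not supported")
            for at in res:
                atoms.append(Atom(
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    residue_name=_strip(res.name),
                    atom_name=_strip(at.name),
                    altloc=at.altloc if at.altloc != "\0" else "",
                    occupancy=min(max(at.occ, 0.0), 1.0),
                    b_factor=at.b_iso,
                    position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    element=at.element.name,
                ))
    if not atoms:
        raise StructureParseError(f"{path}: no atom records found")

    if dpi is None and fmt == "pdb":
        dpi = _dpi_from_remarks(path)

    structure_id = st.name.strip() if st.name.strip() else path.stem
    return StructureModel(structure_id=structure_id, atoms=atoms, dpi=dpi,
                          vocabulary=vocabulary or SiteVocabulary())


_DPI_RE = re.compile(r"REMARK\s+3\s+DPI\s*\(?A?\)?\s*[:=]\s*([0-9.]+)")


def _dpi_from_remarks(path: Path) -> Optional[float]:
    with open(path) as fh:
        for line in fh:
            m = _DPI_RE.match(line)
            if m:
                return float(m.group(1))
            if line.startswith("ATOM") or line.startswith("HETATM"):
                break
    return None


def write_pdb(model: StructureModel, path) -> None:
    """Write the model as a fixed-column PDB file (with a DPI remark)."""
    st = gemmi.Structure()
    st.name = model.structure_id
    md = gemmi.Model("1")
    chains: dict = {}
    for a in model.atoms:
        ch = chains.get(a.chain_id)
        if ch is None:
            ch = gemmi.Chain(a.chain_id)
            chains[a.chain_id] = ch
        # append to existing residue when the last one matches
        res = None
        if len(ch) and ch[-1].seqid.num == a.residue_number and ch[-1].name == a.residue_name:
            res = ch[-1]
        else:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, " ")
            res.het_flag = "H" if a.is_water or a.residue_name in DEFAULT_CHROMOPHORE_CODES else "A"
            ch.add_residue(res)
            res = ch[-1]
        at = gemmi.Atom()
        at.name = a.atom_name
        at.altloc = a.altloc if a.altloc else "\0"
        at.occ = a.occupancy
        at.b_iso = a.b_factor
        at.pos = gemmi.Position(*a.position)
        at.element = gemmi.Element(a.element)
        res.add_atom(at)
    for ch in chains.values():
        md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    body = st.make_pdb_string()
    header = ""
    if model.dpi is not None:
        header = f"REMARK   3   DPI (A) : {model.dpi:.4f}\n"
    Path(path).write_text(header + body)


# ---------------------------------------------------------------------------
# semantic site resolution

_RES_KEY_RE = re.compile(r"^([A-Za-z]{2,3})(\d+)$")
_POS_KEY_RE = re.compile(r"^pos(\d+)$")

_THREE_LETTER = {
    "HIS": "HIS", "THR": "THR", "VAL": "VAL", "ILE": "ILE", "SER": "SER",
    "GLN": "GLN", "GLU": "GLU", "ASN": "ASN", "ARG": "ARG", "GLY": "GLY",
    "TYR": "TYR", "ALA": "ALA", "LEU": "LEU", "CRO": "CRO", "GYS": "GYS",
    "CR2": "CR2", "CSY": "CSY", "HOH": "HOH", "WAT": "WAT",
}


def _select_altloc(candidates: Sequence[Atom]) -> Atom:
    """Highest-occupancy conformer; ties broken by altloc letter order."""
    return min(candidates, key=lambda a: (-a.occupancy, a.altloc))


def resolve_site(model: StructureModel, key: str) -> Atom:
    """Resolve a semantic site key to exactly one atom.

    Supported key shapes (case-insensitive residue part):

    * ``"His148.ND1"`` / ``"His148.Nδ1"`` — residue by name+number, atom by
      PDB code or Greek label;
    * ``"CRO.OH"`` / ``"chromophore.OH"`` — the chromophore residue (any
      code in the vocabulary's ``chromophore_codes``);
    * ``"pos203.distal"`` — the distance-defining distal atom at a numbered
      position: OG1 for Thr, OG for Ser, CG2 for Val/Ile;
    * ``"pos222.OE1"`` — numbered position, explicit atom.

    Altlocs are resolved to the highest-occupancy conformer (ties by letter).
    """
    voc = model.vocabulary
    try:
        res_part, atom_part = key.split(".", 1)
    except ValueError:
        raise SiteLookupError(f"malformed site key {key!r} (expected RES.ATOM)")

    # pick candidate residue atoms
    if res_part.lower() in ("chromophore", "cro") or res_part.upper() in voc.chromophore_codes:
        pool = [a for a in model.atoms if a.residue_name in voc.chromophore_codes]
        if not pool:
            raise SiteLookupError(
                f"no chromophore residue (codes {sorted(voc.chromophore_codes)}) in "
                f"{model.structure_id}")
    else:
        m = _POS_KEY_RE.match(res_part.lower())
        if m:
            resnum = int(m.group(1))
            pool = model.residue_atoms(resnum)
        else:
            m = _RES_KEY_RE.match(res_part)
            if not m:
                raise SiteLookupError(f"cannot parse residue part of key {key!r}")
            resname = _THREE_LETTER.get(m.group(1).upper(), m.group(1).upper())
            resnum = int(m.group(2))
            pool = model.residue_atoms(resnum, resname)
        if not pool:
            raise SiteLookupError(
                f"no residue {res_part} in {model.structure_id}")

    if atom_part == "distal":
        resname = pool[0].residue_name
        distal = {"THR": "OG1", "SER": "OG", "VAL": "CG2", "ILE": "CG2"}.get(resname)
        if distal is None:
            raise SiteLookupError(
                f"'distal' undefined for residue type {resname} (key {key!r})")
        atom_code = distal
    elif atom_part == "hydroxyl":
        # the position-65 hydroxyl inside the chromophore: OG1 (Thr65) or OG (Ser65)
        names = {a.atom_name for a in pool}
        atom_code = "OG1" if "OG1" in names else "OG"
    else:
        atom_code = voc.atom_code(atom_part)

    hits = [a for a in pool if a.atom_name == atom_code]
    if not hits:
        have = sorted({a.atom_name for a in pool})
        raise SiteLookupError(
            f"atom {atom_code} not found for key {key!r}; candidates: {have}")
    return _select_altloc(hits)


def find_bridging_water(model: StructureModel, partners: Iterable[str],
                        cutoff: float = 3.5) -> Optional[Atom]:
    """Water oxygen bridging two sites, or ``None``.

    Returns the water O minimising the sum of distances to both partner
    atoms, provided each distance is ≤ ``cutoff`` (Å).  Absence of a
    bridging water is a valid result, not an error.  The choice is invariant
    under atom-record reordering (ties broken by coordinates).
    """
    pa, pb = [resolve_site(model, k) for k in partners]
    best = None
    best_key = None
    for w in model.waters():
        d1 = float(np.linalg.norm(w.position - pa.position))
        d2 = float(np.linalg.norm(w.position - pb.position))
        if d1 <= cutoff and d2 <= cutoff:
            key = (d1 + d2, tuple(np.round(w.position, 6)))
            if best_key is None or key < best_key:
                best, best_key = w, key
    return best
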