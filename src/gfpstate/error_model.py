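"""Coordinate-error propagation from the diffraction precision index (DPI).

The DPI from crystallographic refinement is an average coordinate error
σ_avg (Å).  Per-atom errors scale with the atomic displacement parameter,
σ_i = σ_avg·√(B_i/B_avg), and a distance between atoms i and j carries the
quadrature sum σ_l = √(σ_i² + σ_j²).  The DPI itself is an input taken from
refinement statistics, never computed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Tuple

from .geometry import GeometryReport
from .structure_io import Atom, StructureModel, resolve_site

__all__ = ["ErrorModel", "MissingDPIError", "atom_sigma", "distance_sigma",
           "build_error_model", "annotate_errors"]


class MissingDPIError(ValueError):
    """The structure has no DPI; supply one (config ``dpi:`` or ``--dpi``)."""


def atom_sigma(dpi: float, b_i: float, b_average: float) -> float:
    """Per-atom coordinate error σ_i = DPI·√(B_i/B_avg) in Å."""
    if dpi < 0 or b_i < 0:
        raise ValueError("dpi and B must be non-negative")
    if b_average <= 0:
        raise ValueError(f"b_average must be positive, got {b_average}")
    return dpi * math.sqrt(b_i / b_average)


def distance_sigma(sigma_i: float, sigma_j: float) -> float:
    """Distance error σ_l = √(σ_i² + σ_j²) in Å."""
    if sigma_i < 0 or sigma_j < 0:
        raise ValueError("sigmas must be non-negative")
    return math.hypot(sigma_i, sigma_j)


@dataclass
class ErrorModel:
    """DPI-derived per-atom and per-distance uncertainties for one structure."""

    sigma_average: float
    b_average: float
    per_atom_sigma: Dict[Tuple[str, int, str, str], float] = field(default_factory=dict)

    def sigma_for(self, atom: Atom) -> float:
        key = (atom.chain_id, atom.residue_number, atom.atom_name, atom.altloc)
        if key not in self.per_atom_sigma:
            self.per_atom_sigma[key] = atom_sigma(
                self.sigma_average, atom.b_factor, self.b_average)
        return self.per_atom_sigma[key]

    def sigma_distance(self, a: Atom, b: Atom) -> float:
        return distance_sigma(self.sigma_for(a), self.sigma_for(b))


def build_error_model(model: StructureModel) -> ErrorModel:
    if model.dpi is None:
        raise MissingDPIError(
            f"structure {model.structure_id} has no DPI; supply one via "
            "read_structure(dpi=...), a REMARK 3 DPI line, or --dpi")
    return ErrorModel(sigma_average=model.dpi, b_average=model.b_average)


def annotate_errors(model: StructureModel, report: GeometryReport) -> GeometryReport:
    """Attach σ_l to every reported distance, from the two atoms' B-factors.

    Mutates and returns ``report``.  For atoms with altlocs the B of the
    selected (highest-occupancy) conformer is used, consistent with the
    altloc policy of the structure reader.
    """
    em = build_error_model(model)
    oh = resolve_site(model, "chromophore.OH")
    nd1 = resolve_site(model, "His148.ND1")
    distal = resolve_site(model, "pos203.distal")
    report.sigma_his = em.sigma_distance(nd1, oh)
    report.sigma_203 = em.sigma_distance(distal, oh)
    if report.d_wat3 is not None:
        from .structure_io import find_bridging_water
        wat3 = find_bridging_water(model, ("chromophore.OH", "Ser205.OG"))
        if wat3 is not None:
            report.sigma_wat3 = em.sigma_distance(wat3, oh)
    return report
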