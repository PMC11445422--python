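"""Reduced-density-gradient (NCI) analysis on a promolecular density.

Non-covalent interactions show up as regions where the reduced density
gradient

    s(r) = |∇ρ| / (2 (3π²)^(1/3) ρ^(4/3))

drops toward zero at low density.  The sign of the second eigenvalue λ2 of
the density Hessian separates attraction (λ2 < 0, e.g. hydrogen bonds) from
steric repulsion (λ2 > 0), with |sign(λ2)ρ| near zero marking weak van der
Waals contact.

The density here is promolecular: a sum of unrelaxed, spherically symmetric
atomic densities.  Each atomic density is built in code from single-zeta
Slater-type-orbital shells with Slater's-rules exponents, giving radial
terms of the form c·r^p·e^(−r/ζ) (atomic units) whose gradient and Hessian
are assembled analytically — no DFT or ab initio density is involved, which
preserves the qualitative attraction/weak/repulsion classification the NCI
method is used for.  Hydrogen positions must be supplied by the caller (the
synthetic-fixture builder places them at ideal bond lengths).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = ["DensityModel", "RDGField", "ParameterError", "GridTooLargeError",
           "slater_terms", "promolecular_density", "reduced_gradient",
           "signed_density", "nci_scan", "write_cube", "BOHR_PER_ANGSTROM"]

BOHR_PER_ANGSTROM = 1.0 / 0.529177210903

#: Slater's-rules shells per element: (principal n, electrons, orbital exponent)
_SLATER_SHELLS: Dict[str, List[Tuple[int, int, float]]] = {
    "H":  [(1, 1, 1.00)],
    "C":  [(1, 2, 5.70), (2, 4, 1.625)],
    "N":  [(1, 2, 6.70), (2, 5, 1.95)],
    "O":  [(1, 2, 7.70), (2, 6, 2.275)],
    "NE": [(1, 2, 9.70), (2, 8, 2.925)],
    "S":  [(1, 2, 15.70), (2, 8, 5.925), (3, 6, 1.8167)],
}

_ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "NE": 10, "S": 16}


class ParameterError(KeyError):
    """No radial density parameters for the requested element."""


class GridTooLargeError(ValueError):
    """The requested NCI grid exceeds the configured cell-count guard."""


def slater_terms(element: str) -> List[Tuple[float, int, float]]:
    """Radial density terms (c, p, ζ) for an element: ρ(r) = Σ c·r^p·e^(−r/ζ).

    Derived from normalised single-zeta STO shells: a shell with principal
    number n, N_e electrons and orbital exponent z contributes
    N_e·(2z)^(2n+1)/((2n)!·4π) · r^(2n−2) · e^(−2zr).
    """
    shells = _SLATER_SHELLS.get(element.upper())
    if shells is None:
        raise ParameterError(
            f"no density parameters for element {element!r}; "
            f"available: {sorted(_SLATER_SHELLS)}")
    terms = []
    for n, ne, z in shells:
        c = ne * (2 * z) ** (2 * n + 1) / (math.factorial(2 * n) * 4 * math.pi)
        terms.append((c, 2 * n - 2, 1.0 / (2 * z)))
    return terms


@dataclass
class DensityModel:
    """Atoms (element, position in Å) plus per-element radial terms.

    ``params`` may override or extend the built-in Slater table with terms
    (c, p, ζ): ρ_elem(r) = Σ c·r^p·e^(−r/ζ), r in bohr, density in e/a0³.
    """

    elements: List[str]
    positions: np.ndarray  # (n_atoms, 3), Å
    params: Dict[str, List[Tuple[float, int, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape != (len(self.elements), 3):
            raise ValueError("positions must be (n_atoms, 3) matching elements")
        for e in self.elements:
            self.terms_for(e)  # fail early on unknown elements

    def terms_for(self, element: str) -> List[Tuple[float, int, float]]:
        key = element.upper()
        if key in self.params:
            return self.params[key]
        return slater_terms(key)

    @property
    def positions_bohr(self) -> np.ndarray:
        return self.positions * BOHR_PER_ANGSTROM


def _radial_parts(r: np.ndarray, terms) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """f(r), f'(r), f''(r) for ρ_elem(r) = Σ c·r^p·e^(−r/ζ)."""
    f = np.zeros_like(r)
    f1 = np.zeros_like(r)
    f2 = np.zeros_like(r)
    for c, p, zeta in terms:
        a = 1.0 / zeta
        e = c * np.exp(-a * r)
        if p == 0:
            f += e
            f1 += -a * e
            f2 += a * a * e
        else:
            rp = r ** p
            f += e * rp
            f1 += e * rp * (p / r - a)
            f2 += e * rp * ((p / r - a) ** 2 - p / r ** 2)
    return f, f1, f2


def promolecular_density(model: DensityModel, points):
    """Density, gradient and Hessian of the promolecular ρ at given points.

    ``points`` in Å, shape (3,) or (n, 3).  Returns ``(rho, grad, hess)`` in
    atomic units (gradient per bohr, Hessian per bohr²), with leading
    dimension matching the input.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float)) * BOHR_PER_ANGSTROM
    single = np.asarray(points).ndim == 1
    n = pts.shape[0]
    rho = np.zeros(n)
    grad = np.zeros((n, 3))
    hess = np.zeros((n, 3, 3))
    eye = np.eye(3)
    # canonical accumulation order: the field is bit-identical under any
    # permutation of the atom list
    order = sorted(range(len(model.elements)),
                   key=lambda i: (model.elements[i], *model.positions[i]))
    for elem, center in ((model.elements[i], model.positions_bohr[i])
                         for i in order):
        d = pts - center
        r = np.linalg.norm(d, axis=1)
        r = np.maximum(r, 1e-12)  # nuclear-position guard
        u = d / r[:, None]
        f, f1, f2 = _radial_parts(r, model.terms_for(elem))
        rho += f
        grad += f1[:, None] * u
        uuT = u[:, :, None] * u[:, None, :]
        hess += (f2 - f1 / r)[:, None, None] * uuT + (f1 / r)[:, None, None] * eye
    if single:
        return float(rho[0]), grad[0], hess[0]
    return rho, grad, hess


_RDG_CONST = 2.0 * (3.0 * math.pi ** 2) ** (1.0 / 3.0)


def reduced_gradient(rho, gradient_norm):
    """s = |∇ρ| / (2(3π²)^(1/3) ρ^(4/3)); requires ρ > 0."""
    rho_arr = np.asarray(rho, dtype=float)
    if np.any(rho_arr <= 0):
        raise ValueError("reduced gradient undefined for rho <= 0")
    s = np.asarray(gradient_norm, dtype=float) / (_RDG_CONST * rho_arr ** (4.0 / 3.0))
    return float(s) if s.ndim == 0 else s


def signed_density(hessian, rho, sym_tol: float = 1e-8):
    """sign(λ2)·ρ with λ1 ≤ λ2 ≤ λ3 the Hessian eigenvalues; sign(0) = +1."""
    h = np.asarray(hessian, dtype=float)
    if np.max(np.abs(h - np.swapaxes(h, -1, -2))) > sym_tol:
        raise ValueError("Hessian not symmetric within tolerance")
    lam = np.linalg.eigvalsh(h)
    lam2 = lam[..., 1]
    sign = np.where(lam2 < 0, -1.0, 1.0)
    out = sign * np.asarray(rho, dtype=float)
    return float(out) if out.ndim == 0 else out


@dataclass
class RDGField:
    """Gridded ρ, s and sign(λ2)ρ values (atomic units) on a regular lattice."""

    origin_bohr: np.ndarray        # grid origin, bohr
    spacing_bohr: float
    shape: Tuple[int, int, int]
    rho: np.ndarray                # (nx, ny, nz), e/a0^3
    s: np.ndarray                  # dimensionless
    signed_rho: np.ndarray         # e/a0^3, |signed_rho| == rho

    def axis_points(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin_bohr[axis] + self.spacing_bohr * np.arange(n)


def nci_scan(model: DensityModel,
             region: Optional[Tuple[Sequence[float], Sequence[float]]] = None,
             spacing: float = 0.15,
             s_iso: float = 0.4,
             rho_cutoff: float = 0.05,
             rho_floor: float = 2e-5,
             attract_threshold: float = 0.01,
             padding: float = 2.0,
             max_points: int = 4_000_000):
    """Evaluate the RDG field on a grid and summarise low-s interaction clusters.

    Parameters
    ----------
    region
        ((xmin, ymin, zmin), (xmax, ymax, zmax)) in Å; default is the atom
        bounding box padded by ``padding`` Å.
    spacing
        Grid step in bohr (default 0.15).
    s_iso, rho_cutoff, rho_floor
        A grid point belongs to an interaction region when s ≤ ``s_iso``
        and ``rho_floor`` < ρ < ``rho_cutoff`` (the upper cutoff excludes
        covalent regions, the floor the vacuum tail).
    attract_threshold
        |sign(λ2)ρ| boundary (a.u.) between weak contact and
        attraction/repulsion.

    Returns ``(field, summary)``; the summary lists connected clusters with
    their class (attraction / weak / repulsion), the nearest atom pair and
    the sign(λ2)ρ value at the cluster's minimum-s point.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if region is None:
        lo = model.positions.min(axis=0) - padding
        hi = model.positions.max(axis=0) + padding
    else:
        lo = np.asarray(region[0], dtype=float)
        hi = np.asarray(region[1], dtype=float)
    if np.any(hi <= lo):
        raise ValueError("empty region")
    lo_b = lo * BOHR_PER_ANGSTROM
    hi_b = hi * BOHR_PER_ANGSTROM
    # anchor the lattice on the atom centroid so that the symmetry planes of
    # symmetric fixtures (where |grad rho| and hence s vanish) fall exactly
    # on grid planes instead of between them
    canon = sorted(range(len(model.elements)),
                   key=lambda i: (model.elements[i], *model.positions[i]))
    center = model.positions_bohr[canon].mean(axis=0)
    axes = []
    for i in range(3):
        k0 = int(np.ceil((lo_b[i] - center[i]) / spacing))
        k1 = int(np.floor((hi_b[i] - center[i]) / spacing))
        if k1 < k0:
            raise ValueError("region smaller than one grid step")
        axes.append(center[i] + spacing * np.arange(k0, k1 + 1))
    lo_b = np.array([ax[0] for ax in axes])
    shape = tuple(len(ax) for ax in axes)
    ncell = shape[0] * shape[1] * shape[2]
    if ncell > max_points:
        raise GridTooLargeError(
            f"grid of {ncell} points exceeds max_points={max_points}; "
            "increase spacing or shrink the region")
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts_bohr = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    rho, grad, hess = promolecular_density(
        model, pts_bohr / BOHR_PER_ANGSTROM)
    gnorm = np.linalg.norm(grad, axis=1)
    s = reduced_gradient(rho, gnorm)
    signed = signed_density(hess, rho)

    field = RDGField(
        origin_bohr=lo_b, spacing_bohr=spacing, shape=shape,
        rho=rho.reshape(shape), s=s.reshape(shape),
        signed_rho=signed.reshape(shape))

    mask = (field.s <= s_iso) & (field.rho < rho_cutoff) & (field.rho > rho_floor)
    labels, n_clusters = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))

    summary = []
    pos_b = model.positions_bohr
    for k in range(1, n_clusters + 1):
        idx = np.argwhere(labels == k)
        svals = field.s[idx[:, 0], idx[:, 1], idx[:, 2]]
        imin = idx[np.argmin(svals)]
        point_b = lo_b + spacing * imin
        sr = float(field.signed_rho[tuple(imin)])
        if sr < -attract_threshold:
            cls = "attraction"
        elif sr > attract_threshold:
            cls = "repulsion"
        else:
            cls = "weak"
        dists = np.linalg.norm(pos_b - point_b, axis=1)
        order = np.argsort(dists)[:2]
        pair = [f"{model.elements[i]}{i + 1}" for i in order]
        summary.append({
            "cluster": k,
            "n_points": int(len(idx)),
            "class": cls,
            "signed_rho_at_min_s": sr,
            "min_s": float(svals.min()),
            "rho_at_min_s": float(field.rho[tuple(imin)]),
            "between": pair,
        })
    return field, summary


def write_cube(field: RDGField, model: DensityModel, path, which: str = "s",
               comment: str = "") -> None:
    """Write a Gaussian cube file of ``s`` or ``signed_rho`` (bohr units)."""
    data = {"s": field.s, "signed_rho": field.signed_rho,
            "rho": field.rho}.get(which)
    if data is None:
        raise ValueError(f"unknown field {which!r} (use s/signed_rho/rho)")
    lines = [f"gfpstate NCI field: {which}", comment or "promolecular density"]
    nat = len(model.elements)
    o = field.origin_bohr
    lines.append(f"{nat:5d}{o[0]:12.6f}{o[1]:12.6f}{o[2]:12.6f}")
    d = field.spacing_bohr
    for i, vec in enumerate(np.eye(3) * d):
        lines.append(f"{field.shape[i]:5d}{vec[0]:12.6f}{vec[1]:12.6f}{vec[2]:12.6f}")
    for elem, p in zip(model.elements, model.positions_bohr):
        z = _ATOMIC_NUMBER.get(elem.upper(), 0)
        lines.append(f"{z:5d}{float(z):12.6f}{p[0]:12.6f}{p[1]:12.6f}{p[2]:12.6f}")
    flat = data.reshape(field.shape)
    out = []
    for ix in range(field.shape[0]):
        for iy in range(field.shape[1]):
            row = flat[ix, iy, :]
            for start in range(0, len(row), 6):
                out.append("".join(f"{v:13.5E}" for v in row[start:start + 6]))
    Path(path).write_text("\n".join(lines + out) + "\n")
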