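"""Weighted Henderson–Hasselbalch fitting of the I-state fraction vs pH.

The deprotonated (I-state) fraction of a single titrating site follows

    f(pH) = 1 / (1 + 10^(pKa − pH))

with Hill coefficient fixed at 1 (one protonation site).  ``fit_pka``
minimises the weighted sum of squares Σ w_k (f_k − f(pH_k; pKa))² over pKa,
with w_k = 1/sd_k² when per-point standard deviations are given and unit
weights otherwise.  The 1-σ uncertainty of pKa comes from the curvature of
the objective at the optimum scaled by the residual variance (the standard
Gauss–Newton estimate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = ["TitrationDataset", "TitrationFit", "NonIdentifiableError",
           "hh_fraction", "fit_pka", "fraction_from_spectra",
           "load_titration_csv"]


class NonIdentifiableError(ValueError):
    """The data sample no transition; pKa cannot be determined."""


def hh_fraction(ph, pka):
    """Deprotonated fraction 1/(1 + 10^(pKa − pH)); monotone increasing in pH."""
    ph = np.asarray(ph, dtype=float)
    out = 1.0 / (1.0 + 10.0 ** (pka - ph))
    return float(out) if out.ndim == 0 else out


@dataclass
class TitrationDataset:
    """Titration points: pH, deprotonated fraction, optional per-point sd."""

    ph: np.ndarray
    fraction: np.ndarray
    sd: Optional[np.ndarray] = None
    replicate_id: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.ph.shape != self.fraction.shape:
            raise ValueError("ph and fraction must have the same shape")
        if np.any((self.ph < 2.0) | (self.ph > 12.0)):
            raise ValueError("pH values outside the physically sensible 2-12 range")
        if np.any((self.fraction < 0.0) | (self.fraction > 1.0)):
            raise ValueError("fractions must lie in [0, 1]")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if np.any(self.sd <= 0):
                raise ValueError("per-point sd must be positive")

    @property
    def weights(self) -> np.ndarray:
        if self.sd is None:
            return np.ones_like(self.ph)
        return 1.0 / self.sd ** 2

    def to_frame(self) -> pd.DataFrame:
        d = {"ph": self.ph, "fraction": self.fraction}
        if self.sd is not None:
            d["sd"] = self.sd
        if self.replicate_id is not None:
            d["replicate_id"] = self.replicate_id
        return pd.DataFrame(d)


@dataclass
class TitrationFit:
    """Result of a weighted Henderson–Hasselbalch fit."""

    pka: float
    pka_sd: float
    residual_sum: float
    n_points: int

    def fitted_curve(self, ph):
        return hh_fraction(ph, self.pka)

    def to_dict(self) -> dict:
        return {"pka": self.pka, "pka_sd": self.pka_sd,
                "residual_sum": self.residual_sum, "n_points": self.n_points}


def fit_pka(data: TitrationDataset) -> TitrationFit:
    """Weighted least-squares pKa estimate with 1-σ uncertainty.

    Raises :class:`NonIdentifiableError` when the data never sample the
    transition (all fractions ≈ 0 or ≈ 1), and :class:`ValueError` for
    fewer than 3 distinct pH values.
    """
    if len(np.unique(np.round(data.ph, 6))) < 3:
        raise ValueError("need at least 3 distinct pH values")
    f = data.fraction
    if f.max() < 0.05 or f.min() > 0.95:
        raise NonIdentifiableError(
            "no acid-base transition sampled (all fractions near 0 or near 1)")

    sqrt_w = np.sqrt(data.weights)

    def residuals(p):
        return sqrt_w * (f - hh_fraction(data.ph, p[0]))

    # crude start: pH closest to fraction 0.5
    p0 = float(data.ph[np.argmin(np.abs(f - 0.5))])
    sol = least_squares(residuals, x0=[p0], method="lm")
    pka = float(sol.x[0])
    n = len(f)
    rss = float(np.sum(sol.fun ** 2))
    # curvature of the weighted objective at the optimum: S'' ~ 2 J^T J
    jtj = float(np.sum(sol.jac ** 2))
    dof = max(n - 1, 1)
    sigma2 = rss / dof
    pka_sd = float(np.sqrt(sigma2 / jtj)) if jtj > 0 else float("inf")
    return TitrationFit(pka=pka, pka_sd=pka_sd, residual_sum=rss, n_points=n)


def fraction_from_spectra(abs_a_peak: float, abs_i_peak: float,
                          eps_ratio: float = 1.0) -> float:
    """I-state fraction by two-state linear unmixing of peak absorbances.

    ``eps_ratio`` is ε_I/ε_A, the ratio of the molar extinction coefficients
    at the two band maxima (default 1.0; configurable because reference
    coefficients vary between variants).
    """
    if abs_a_peak < 0 or abs_i_peak < 0:
        raise ValueError("absorbances must be non-negative")
    ci = abs_i_peak / eps_ratio
    ca = abs_a_peak
    if ci + ca == 0:
        raise ValueError("both absorbances zero: fraction undefined")
    return ci / (ci + ca)


def load_titration_csv(path) -> TitrationDataset:
    """Read a CSV with columns ``ph``, ``fraction`` and optional ``sd``."""
    df = pd.read_csv(path)
    missing = {"ph", "fraction"} - set(df.columns)
    if missing:
        raise ValueError(f"titration CSV lacks columns {sorted(missing)}")
    return TitrationDataset(
        ph=df["ph"].to_numpy(),
        fraction=df["fraction"].to_numpy(),
        sd=df["sd"].to_numpy() if "sd" in df.columns else None,
        replicate_id=df["replicate_id"].to_numpy() if "replicate_id" in df.columns else None,
    )
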