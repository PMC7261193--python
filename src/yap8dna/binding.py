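"""Equilibrium binding affinity from fluorescence anisotropy titrations.

For 1:1 binding of a protein (total concentration ``E_T``) to a labelled
DNA probe (total concentration ``D_T``, held fixed, typically 1 nM) the
anisotropy change follows the *stoichiometric* (exact, quadratic)
isotherm, which does not assume protein excess:

    dA = dA_T / (2 D_T) * [ (E_T + D_T + K_d)
                            - sqrt((E_T + D_T + K_d)^2 - 4 E_T D_T) ]

where ``dA_T`` is the total anisotropy change at saturation and ``K_d``
the dissociation constant.  The bracket is twice the bound-DNA
concentration, so ``dA/dA_T`` is the bound fraction.  As ``D_T -> 0``
the expression reduces to the familiar hyperbola ``E_T / (E_T + K_d)``.

``fit_isotherm`` recovers ``(K_d, dA_T)`` by unweighted nonlinear least
squares, with the standard error of ``K_d`` taken from the Jacobian-based
covariance at the optimum.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DegenerateDataError, FitError, ValidationError


@dataclass
class Titration:
    """One titration series: protein concentrations (nM, strictly
    ascending), total DNA concentration (nM) and anisotropy changes."""

    E_T: np.ndarray
    D_T: float
    dA: np.ndarray

    def __post_init__(self) -> None:
        self.E_T = np.asarray(self.E_T, dtype=float)
        self.dA = np.asarray(self.dA, dtype=float)
        if self.E_T.ndim != 1 or self.E_T.shape != self.dA.shape:
            raise ValidationError("E_T and dA must be 1-D arrays of equal length")
        if (self.E_T < 0).any():
            raise ValidationError("protein concentrations must be non-negative")
        if (np.diff(self.E_T) <= 0).any():
            raise ValidationError("E_T must be strictly increasing")
        if self.D_T <= 0:
            raise ValidationError("D_T must be positive")

    @property
    def n_points(self) -> int:
        return self.E_T.size


@dataclass(frozen=True)
class IsothermFit:
    K_d: float  # nM
    dA_T: float
    rss: float
    se_Kd: float  # nM
    n_points: int
    converged: bool = True


def isotherm(E_T, D_T: float, K_d: float, dA_T: float):
    """Exact 1:1 binding isotherm; concentrations in nM (any consistent
    unit works, the expression is scale-free)."""
    E_T = np.asarray(E_T, dtype=float)
    if D_T <= 0:
        raise ValidationError("D_T must be positive")
    if K_d < 0 or (E_T < 0).any():
        raise ValidationError("concentrations must be non-negative")
    s = E_T + D_T + K_d
    disc = s * s - 4.0 * E_T * D_T
    if np.any(disc < -1e-9 * np.maximum(s * s, 1.0)):
        raise FitError("negative discriminant in binding isotherm")
    return dA_T / (2.0 * D_T) * (s - np.sqrt(np.maximum(disc, 0.0)))


def fit_isotherm(titration: Titration) -> IsothermFit:
    """Nonlinear least-squares fit of (K_d, dA_T) to one titration.

    The K_d start value is the protein concentration nearest half of the
    maximal observed signal; dA_T starts at the maximal observed signal.
    K_d is constrained positive.
    """
    E, dA, D_T = titration.E_T, titration.dA, titration.D_T
    if titration.n_points < 4:
        raise FitError("need at least 4 titration points")
    dA_max = float(np.max(np.abs(dA)))
    if dA_max == 0.0:
        raise DegenerateDataError("anisotropy changes are identically zero")

    half = 0.5 * float(dA[np.argmax(np.abs(dA))])
    k0 = float(E[np.argmin(np.abs(dA - half))])
    if k0 <= 0:
        positive = E[E > 0]
        k0 = float(np.median(positive)) if positive.size else 1.0
    p0 = (max(k0, 1e-6), float(dA[np.argmax(np.abs(dA))]))

    def model(E_T, K_d, dA_T):
        return isotherm(E_T, D_T, K_d, dA_T)

    try:
        popt, pcov = curve_fit(model, E, dA, p0=p0,
                               bounds=([1e-12, -np.inf], [np.inf, np.inf]),
                               xtol=1e-14, ftol=1e-14, gtol=1e-14,
                               maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"isotherm fit did not converge: {exc}") from exc

    resid = dA - model(E, *popt)
    se_Kd = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else float("nan")
    return IsothermFit(K_d=float(popt[0]), dA_T=float(popt[1]),
                       rss=float(resid @ resid), se_Kd=se_Kd,
                       n_points=titration.n_points, converged=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_titration_csv(path: str | Path, D_T: float | None = None) -> Titration:
    """Read a titration table (columns ``E_T_nM``, ``dA``, optionally
    ``D_T_nM``; ``D_T`` argument overrides the column)."""
    df = pd.read_csv(path)
    if not {"E_T_nM", "dA"} <= set(df.columns):
        raise ValidationError("titration CSV needs columns E_T_nM and dA")
    if D_T is None:
        if "D_T_nM" not in df.columns:
            raise ValidationError("supply D_T or a D_T_nM column")
        D_T = float(df["D_T_nM"].iloc[0])
    return Titration(E_T=df["E_T_nM"].to_numpy(), D_T=D_T, dA=df["dA"].to_numpy())


def write_fit_report(fit: IsothermFit, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({"K_d_nM": fit.K_d, "dA_T": fit.dA_T, "rss": fit.rss,
                   "se_Kd_nM": fit.se_Kd, "n_points": fit.n_points,
                   "converged": fit.converged}, fh, indent=1)
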