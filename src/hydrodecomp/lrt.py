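"""Linear-response-theory (LRT) fits for solvation free-energy components.

LRT says a free-energy component is a fixed fraction of the corresponding
ensemble-averaged solute–solvent interaction energy: turning on the
electrostatic coupling polarizes the solvent gradually, giving
ΔA_ES = ⟨U_ES⟩/2 (slope 0.5); turning on dispersion causes no dipolar
relaxation, giving ΔA_disp = ⟨U_vdW⟩ (slope 1).  Empirical global fits
across polar and non-polar solutes put the electrostatic slope near 0.41.

Because LRT predicts a zero intercept, the origin-constrained regression
is the default; an ordinary least-squares fit is provided for models with
a genuine intercept (e.g. the ASA-linear non-electrostatic models).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "EnergyPair",
    "LinearFit",
    "DegenerateFitError",
    "fit_through_origin",
    "fit_ordinary",
    "lrt_scale",
    "ALPHA_THEORY",
    "ALPHA_GLOBAL_FIT",
    "ALPHA_DISPERSION",
]

#: Theoretical LRT coefficient for electrostatics (gradual polarization).
ALPHA_THEORY = 0.5
#: Global empirical electrostatic coefficient across polar + non-polar sets.
ALPHA_GLOBAL_FIT = 0.41
#: LRT coefficient for dispersion (no solvent relaxation).
ALPHA_DISPERSION = 1.0


class DegenerateFitError(ValueError):
    """Raised when the regression problem has no unique solution."""


@dataclass(frozen=True)
class EnergyPair:
    """A free-energy component dA paired with its mean interaction energy."""

    dA: float
    u_mean: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.dA) and np.isfinite(self.u_mean)):
            raise ValueError(f"{self.label or 'pair'}: non-finite energy")


@dataclass(frozen=True)
class LinearFit:
    """Slope/intercept/R²/n of a linear fit.

    For origin-constrained fits the intercept is exactly 0 and R² is
    defined as 1 − SS_res/SS_tot with SS_tot taken about the data mean
    (so a forced-origin fit can in principle score below an intercept
    model; clipped to [0, 1]).
    """

    slope: float
    intercept: float
    r2: float
    n: int


def _r2(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return float(min(1.0, max(0.0, 1.0 - ss_res / ss_tot)))


def fit_through_origin(pairs: Sequence[EnergyPair]) -> LinearFit:
    """Least-squares slope of dA on u_mean with the intercept pinned at 0.

    The estimator is the closed form Σ(x·y)/Σ(x²).
    """
    if len(pairs) < 1:
        raise DegenerateFitError("need at least one pair")
    x = np.array([p.u_mean for p in pairs])
    y = np.array([p.dA for p in pairs])
    sxx = float(x @ x)
    if sxx == 0.0:
        raise DegenerateFitError("all u_mean are zero; slope undefined")
    slope = float(x @ y) / sxx
    return LinearFit(slope=slope, intercept=0.0, r2=_r2(y, slope * x), n=len(pairs))


def fit_ordinary(x: Sequence[float], y: Sequence[float]) -> LinearFit:
    """Ordinary least-squares line y = a·x + b; R² = squared Pearson r."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    n = xa.size
    if n < 2:
        raise DegenerateFitError("need at least two points for an ordinary fit")
    dx = xa - xa.mean()
    sxx = float(dx @ dx)
    if sxx == 0.0:
        raise DegenerateFitError("x is constant; slope undefined")
    slope = float(dx @ (ya - ya.mean())) / sxx
    intercept = float(ya.mean() - slope * xa.mean())
    return LinearFit(slope=slope, intercept=intercept, r2=_r2(ya, slope * xa + intercept), n=n)


def lrt_scale(u: float, alpha: float = ALPHA_THEORY) -> float:
    """Map an interaction energy to a free energy: ΔA = α·⟨U⟩."""
    return alpha * u
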