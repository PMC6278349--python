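"""ASA-linear non-electrostatic models and PB-style hydration predictors.

Continuum (Poisson–Boltzmann) solvation models estimate the
non-electrostatic part of the hydration free energy as a linear function
of the solvent-accessible surface area.  Two parameterizations are
shipped as frozen constants:

* ``ORIGINAL_PB``  — ΔA_nonES = +0.005·ASA + 1.09, the aliphatic-trained
  line used by standard PB implementations;
* ``MODIFIED_PB``  — ΔA_nonES = −0.0131·ASA + 4.92, refit on explicit-
  solvation component data for aromatic hydrocarbons; its intercept is
  3.56 plus a +1.36 offset that cancels the systematic electrostatic
  overestimate of the continuum reaction field.

The full predictor recombines ΔA_hyd = E_reorg + ΔA_ES + ΔA_nonES, where
ΔA_ES may be rescaled from the theoretical LRT coefficient 0.5 to the
empirical 0.41 (a multiplicative 0.82 on the PB electrostatic term).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import lrt
from .decomposition import SoluteRecord

__all__ = [
    "NonESModel",
    "HydrationPrediction",
    "ErrorReport",
    "ORIGINAL_PB",
    "MODIFIED_PB",
    "ES_OFFSET_MODIFIED",
    "ES_OFFSET_ORIGINAL",
    "eval_non_es",
    "corrected_intercept",
    "rescale_es",
    "predict",
    "predict_all",
    "score",
    "refit_non_es",
]


@dataclass(frozen=True)
class NonESModel:
    """ASA-linear non-electrostatic model: slope (kcal/mol/Å²) + intercept (kcal/mol)."""

    slope: float
    intercept: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise ValueError("model coefficients must be finite")


#: Aliphatic-trained PB non-electrostatic line.
ORIGINAL_PB = NonESModel(slope=0.005, intercept=1.09, label="original")
#: Aromatic refit (slope −0.0131, intercept 3.56) with the +1.36 offset folded in.
MODIFIED_PB = NonESModel(slope=-0.0131, intercept=4.92, label="modified")

#: Electrostatic offsets (kcal/mol) by which the PB reaction field
#: overestimates ΔA_ES under the original (α=0.5) and modified (α=0.41)
#: LRT coefficients; the modified one is folded into MODIFIED_PB's intercept.
ES_OFFSET_ORIGINAL = 1.65
ES_OFFSET_MODIFIED = 1.36


@dataclass(frozen=True)
class HydrationPrediction:
    """Predicted ΔA_hyd for one solute with its three addends (kcal/mol)."""

    name: str
    e_reorg: float
    dA_es_used: float
    dA_non_es_used: float
    dA_hyd_pred: float


@dataclass(frozen=True)
class ErrorReport:
    """MAE and RMSE (kcal/mol) over n prediction/reference pairs."""

    mae: float
    rmse: float
    n: int


def eval_non_es(model: NonESModel, asa: float) -> float:
    """Evaluate a non-electrostatic model at a given ASA (Å², ≥ 0)."""
    if asa < 0:
        raise ValueError(f"ASA must be non-negative, got {asa}")
    return model.slope * asa + model.intercept


def corrected_intercept(base: float, es_offset: float) -> float:
    """Shift a non-ES intercept to absorb an electrostatic offset error."""
    return base + es_offset


def rescale_es(dA_es_pb: float, alpha_from: float, alpha_to: float) -> float:
    """Reinterpret a PB electrostatic free energy under a new LRT coefficient.

    A PB ΔA_ES computed as α_from·U_ES becomes α_to·U_ES, i.e. is
    multiplied by α_to/α_from.
    """
    if alpha_from == 0:
        raise ValueError("alpha_from must be nonzero")
    return dA_es_pb * (alpha_to / alpha_from)


def predict(
    rec: SoluteRecord,
    model: NonESModel,
    alpha_from: float | None = None,
    alpha_to: float | None = None,
) -> HydrationPrediction:
    """Predict ΔA_hyd = E_reorg + ΔA_ES + model(ASA) for one solute.

    When both ``alpha_from`` and ``alpha_to`` are given, the record's
    electrostatic component is rescaled between LRT coefficients first;
    otherwise it is used as given.
    """
    if rec.asa is None:
        raise ValueError(f"{rec.name}: no ASA on record; required for prediction")
    es = rec.dA_es
    if alpha_from is not None or alpha_to is not None:
        if alpha_from is None or alpha_to is None:
            raise ValueError("give both alpha_from and alpha_to, or neither")
        es = rescale_es(es, alpha_from, alpha_to)
    non_es = eval_non_es(model, rec.asa)
    return HydrationPrediction(
        name=rec.name,
        e_reorg=rec.e_reorg,
        dA_es_used=es,
        dA_non_es_used=non_es,
        dA_hyd_pred=rec.e_reorg + es + non_es,
    )


def predict_all(
    records: Sequence[SoluteRecord],
    model: NonESModel,
    alpha_from: float | None = None,
    alpha_to: float | None = None,
) -> list[HydrationPrediction]:
    return [predict(r, model, alpha_from, alpha_to) for r in records]


def score(preds: Sequence[float], refs: Sequence[float]) -> ErrorReport:
    """Mean absolute and root-mean-square error between two energy vectors."""
    p = np.asarray(preds, dtype=float)
    r = np.asarray(refs, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise ValueError(f"length mismatch: {p.shape} vs {r.shape}")
    if p.size < 1:
        raise ValueError("need at least one pair to score")
    d = p - r
    return ErrorReport(
        mae=float(np.mean(np.abs(d))),
        rmse=float(np.sqrt(np.mean(d * d))),
        n=int(p.size),
    )


def refit_non_es(records: Sequence[SoluteRecord], label: str = "refit") -> NonESModel:
    """Refit the ASA-linear non-ES model on (ASA, ΔA_disp + ΔA_cav) data.

    Ordinary least squares via :func:`hydrodecomp.lrt.fit_ordinary`; needs
    every record to carry an ASA.
    """
    missing = [r.name for r in records if r.asa is None]
    if missing:
        raise ValueError(f"records without ASA: {', '.join(missing)}")
    if len(records) < 2:
        raise lrt.DegenerateFitError("need at least two records to refit")
    x = [r.asa for r in records]
    y = [r.dA_disp + r.dA_cav for r in records]
    fit = lrt.fit_ordinary(x, y)
    return NonESModel(slope=fit.slope, intercept=fit.intercept, label=label)
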