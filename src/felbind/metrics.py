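"""Experimental-affinity conversion and benchmark error metrics.

IC50 and Ki values are both treated as surrogates for the dissociation
constant, so dG_exp = RT ln(c / c0) with c0 = 1 M; sub-molar affinities
give negative (favourable) free energies and 1 M gives exactly zero.
Prediction quality against experiment is summarised by MAE, RMSE and the
Pearson and Spearman correlation coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError
from .units import R_KCAL

__all__ = [
    "EvaluationReport",
    "MOLAR_FACTORS",
    "dg_from_affinity",
    "evaluate",
    "count_within",
]

MOLAR_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}


def dg_from_affinity(
    value: float, unit: str, kind: str = "IC50", temperature: float = 298.0
) -> float:
    """Binding free energy (kcal/mol) from an IC50 or Ki measurement.

    Both measurement kinds get the same Kd-surrogate conversion
    RT ln(c / 1 M); ``kind`` is validated but does not change the formula.
    """
    if value <= 0:
        raise ValidationError(f"affinity must be positive, got {value}")
    if unit not in MOLAR_FACTORS:
        raise ValidationError(
            f"unknown affinity unit {unit!r}; expected one of {sorted(MOLAR_FACTORS)}"
        )
    if kind not in ("IC50", "Ki"):
        raise ValidationError(f"unknown affinity kind {kind!r}")
    c = value * MOLAR_FACTORS[unit]
    return float(R_KCAL * temperature * np.log(c))


@dataclass
class EvaluationReport:
    """Error metrics of predicted vs reference free energies, kcal/mol."""

    mae: float
    rmse: float
    pearson: float
    spearman: float
    n: int
    per_complex_error: np.ndarray

    def as_dict(self) -> dict:
        return {
            "mae": self.mae,
            "rmse": self.rmse,
            "pearson": self.pearson,
            "spearman": self.spearman,
            "n": self.n,
        }


def _check_pair(pred, ref) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(pred, dtype=float)
    r = np.asarray(ref, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise ValidationError(
            f"pred and ref must be 1-D and equal length, got {p.shape} vs {r.shape}"
        )
    return p, r


def evaluate(pred, ref) -> EvaluationReport:
    """MAE, RMSE, Pearson and Spearman of predictions against reference.

    Spearman uses average ranks for ties.  Requires n >= 2.
    """
    p, r = _check_pair(pred, ref)
    if p.size < 2:
        raise ValidationError("need at least 2 points")
    err = p - r
    return EvaluationReport(
        mae=float(np.mean(np.abs(err))),
        rmse=float(np.sqrt(np.mean(err**2))),
        pearson=float(stats.pearsonr(p, r).statistic),
        spearman=float(stats.spearmanr(p, r).statistic),
        n=int(p.size),
        per_complex_error=err,
    )


def count_within(pred, ref, threshold: float = 2.0) -> int:
    """Number of predictions within ``threshold`` kcal/mol of reference (inclusive)."""
    p, r = _check_pair(pred, ref)
    return int(np.sum(np.abs(p - r) <= threshold))
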