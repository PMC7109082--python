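"""Linear relation between mutational load and exome TMB, per tumour type.

ML and TMB are linearly related but in a tumour-type-specific manner, so a
shared TMB cut-off maps to different neoantigen-relevant loads in different
cancers. Plain ordinary least squares of ML (response) on exome TMB
(predictor) per type; no robust or weighted variants.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .tmb import SampleProfile

DEFAULT_TUMOUR_TYPES = ("colorectal", "skin", "lung", "breast")


class RegressionError(ValueError):
    pass


@dataclass(frozen=True)
class RegressionFit:
    tumour_type: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    slope_stderr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise RegressionError(f"r_squared {self.r_squared} outside [0, 1]")
        if self.n < 3:
            raise RegressionError("regression requires n >= 3")


def fit_ml_vs_tmb(profiles: Sequence[SampleProfile], tumour_type: str) -> RegressionFit:
    """OLS fit of mutational load on exome TMB for one tumour type."""
    pts = [
        p
        for p in profiles
        if p.tumour_type == tumour_type and p.mutational_load is not None
    ]
    if len(pts) < 3:
        raise RegressionError(
            f"tumour type {tumour_type!r}: need >= 3 samples with mutational load, "
            f"got {len(pts)}"
        )
    x = np.array([p.exome_tmb for p in pts], dtype=float)
    y = np.array([p.mutational_load for p in pts], dtype=float)
    if np.ptp(x) == 0.0:
        raise RegressionError(f"tumour type {tumour_type!r}: degenerate predictor")
    if np.ptp(y) == 0.0:
        # Constant response: flat line, no variance explained.
        return RegressionFit(tumour_type, 0.0, float(y[0]), 0.0, len(pts), 0.0)
    res = stats.linregress(x, y)
    return RegressionFit(
        tumour_type=tumour_type,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(pts),
        slope_stderr=float(res.stderr),
    )


def predict_ml(fit: RegressionFit, tmb: float) -> float:
    """Predicted mutational load at a given exome TMB."""
    return fit.slope * tmb + fit.intercept
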