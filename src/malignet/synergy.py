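"""Median-effect dose-response fitting and Chou-Talalay combination index.

The median-effect equation ``fa/fu = (D/Dm)^m`` links dose D to fraction
affected fa (fu = 1 - fa); Dm is the median-effect dose and m the
sigmoidicity. Single-agent parameters come from ordinary least squares
on the linearized plot ``log(fa/fu) = m log D - m log Dm``. For a
combination point observed at fraction affected fa, the combination
index is ``CI = D1/Dx1(fa) + D2/Dx2(fa)`` with ``Dx = Dm (fa/fu)^(1/m)``
the single-agent dose producing the same effect; CI = 1 is additive,
CI < 1 synergistic, CI > 1 antagonistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "MedianEffectFit",
    "CIRecord",
    "normalize_to_control",
    "fit_median_effect",
    "dose_for_effect",
    "combination_index",
]

log = logging.getLogger(__name__)


@dataclass
class MedianEffectFit:
    m: float
    dm: float
    r_squared: float
    n_points: int


@dataclass
class CIRecord:
    dose_a: float
    dose_b: float
    fa: float
    ci: float
    classification: str


def normalize_to_control(signal, control_signal) -> np.ndarray:
    """Viability fractions from raw readouts and untreated-control readouts."""
    control = np.mean(np.asarray(control_signal, dtype=float))
    if control <= 0:
        raise InputError("control signal must be positive")
    return np.asarray(signal, dtype=float) / control


def fit_median_effect(doses, viability) -> MedianEffectFit:
    """Least-squares fit of (m, Dm) on the linearized median-effect plot.

    Only points with dose > 0 and fraction affected strictly inside
    (0, 1) carry information; others are excluded with a logged count.
    """
    d = np.asarray(doses, dtype=float)
    v = np.asarray(viability, dtype=float)
    if d.shape != v.shape or d.ndim != 1:
        raise InputError("doses and viability must be equal-length 1-D")
    fa = 1.0 - v
    usable = (d > 0) & (fa > 0) & (fa < 1)
    n_dropped = int((~usable).sum())
    if n_dropped:
        log.info("excluding %d dose points with fa outside (0, 1)", n_dropped)
    d, fa = d[usable], fa[usable]
    if len(d) < 2 or len(np.unique(d)) < 2:
        raise InputError("no information in (0, 1): need >= 2 usable distinct doses")
    x = np.log(d)
    y = np.log(fa / (1.0 - fa))
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise InputError("fitted slope m <= 0; dose-response is not increasing")
    dm = float(np.exp(-res.intercept / m))
    return MedianEffectFit(m=m, dm=dm, r_squared=float(res.rvalue**2), n_points=len(d))


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dose producing fraction affected fa: ``Dx = Dm (fa/(1-fa))^(1/m)``."""
    if not 0 < fa < 1:
        raise InputError("fa must lie strictly in (0, 1)")
    return float(fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def combination_index(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    combo_points: pd.DataFrame,
    additive_tol: float = 1e-9,
) -> list[CIRecord]:
    """Per-point Chou-Talalay combination index for a combo design.

    ``combo_points`` needs columns dose_a, dose_b, viability. Points with
    fraction affected outside (0, 1) are skipped with a log entry. No
    averaging across points is performed. Classification uses
    ``additive_tol`` only to absorb floating-point noise around CI = 1.
    """
    required = {"dose_a", "dose_b", "viability"}
    if required - set(combo_points.columns):
        raise InputError(f"combo_points needs columns {sorted(required)}")
    records = []
    for row in combo_points.itertuples(index=False):
        fa = 1.0 - float(row.viability)
        if not 0 < fa < 1:
            log.info("skipping combo point with fa=%.3f outside (0, 1)", fa)
            continue
        if row.dose_a < 0 or row.dose_b < 0 or (row.dose_a == 0 and row.dose_b == 0):
            raise InputError("combo point requires at least one positive dose")
        ci = 0.0
        if row.dose_a > 0:
            ci += row.dose_a / dose_for_effect(fit_a, fa)
        if row.dose_b > 0:
            ci += row.dose_b / dose_for_effect(fit_b, fa)
        if abs(ci - 1.0) <= additive_tol:
            cls = "additive"
        elif ci < 1.0:
            cls = "synergistic"
        else:
            cls = "antagonistic"
        records.append(
            CIRecord(
                dose_a=float(row.dose_a),
                dose_b=float(row.dose_b),
                fa=fa,
                ci=float(ci),
                classification=cls,
            )
        )
    return records
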