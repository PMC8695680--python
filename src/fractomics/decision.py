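"""Regimen decision curves from two fitted cohort models.

Given one logistic 5yDFS model per chemotherapy regimen cohort
(oxaliplatin-based vs fluoropyrimidine-only), the decision curve
evaluates both predicted probabilities over a grid of maxFD_30-50
values, locates their crossing in closed form, and recommends the
regimen with the higher predicted 5yDFS — or declares the regimens
equivalent when the difference is within a configurable margin.

Outputs are model-predicted probabilities, not clinical advice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import LogisticModel, predict_prob

#: Reference cohort models for locally advanced rectal cancer, relating
#: maxFD_30-50 on staging T2-w MRI to 5-year disease-free survival.
#: Coefficients as reported for the oxaliplatin-treated cohort
#: (intercept 19.43 +/- 7.57, slope -10.91 +/- 4.62) and the cohort
#: treated without oxaliplatin (22.15 +/- 10.15, -12.67 +/- 6.25).
REFERENCE_OXA_MODEL = LogisticModel(beta0=19.43, beta1=-10.91, se0=7.57, se1=4.62, p0=0.01, p1=0.02)
REFERENCE_NO_OXA_MODEL = LogisticModel(beta0=22.15, beta1=-12.67, se0=10.15, se1=6.25, p0=0.03, p1=0.04)


@dataclass
class DecisionCurve:
    fd_grid: np.ndarray
    p_oxa: np.ndarray
    p_noxa: np.ndarray
    crossing_fd: float | None


@dataclass
class Recommendation:
    fd: float
    p_oxa: float
    p_noxa: float
    preferred: str  # OXA | NO_OXA | EQUIVALENT
    margin: float


def crossing_point(model_oxa: LogisticModel, model_noxa: LogisticModel) -> float | None:
    """FD at which the two model curves intersect, or None for equal slopes.

    Equal linear predictors require beta0_oxa + beta1_oxa*fd =
    beta0_noxa + beta1_noxa*fd, giving fd = (beta0_noxa - beta0_oxa) /
    (beta1_oxa - beta1_noxa).
    """
    dslope = model_oxa.beta1 - model_noxa.beta1
    if dslope == 0:
        return None
    return (model_noxa.beta0 - model_oxa.beta0) / dslope


def decision_curve(
    model_oxa: LogisticModel,
    model_noxa: LogisticModel,
    fd_min: float = 1.4,
    fd_max: float = 2.0,
    step: float = 0.01,
) -> DecisionCurve:
    """Evaluate both 5yDFS curves on an FD grid and locate their crossing."""
    if not fd_min < fd_max:
        raise ValueError("fd_min must be < fd_max")
    if step <= 0:
        raise ValueError("step must be positive")
    grid = np.arange(fd_min, fd_max + step / 2.0, step)
    cross = crossing_point(model_oxa, model_noxa)
    if cross is not None and not (fd_min <= cross <= fd_max):
        cross = None
    return DecisionCurve(
        fd_grid=grid,
        p_oxa=np.asarray(predict_prob(model_oxa, grid)),
        p_noxa=np.asarray(predict_prob(model_noxa, grid)),
        crossing_fd=cross,
    )


def recommend(
    fd: float,
    model_oxa: LogisticModel,
    model_noxa: LogisticModel,
    equivalence_margin: float = 0.02,
) -> Recommendation:
    """Recommend the regimen with the higher predicted 5yDFS at this FD.

    Within ``equivalence_margin`` (absolute probability) the regimens
    are reported as EQUIVALENT.
    """
    if not np.isfinite(fd):
        raise ValueError("fd must be finite")
    p_oxa = float(predict_prob(model_oxa, fd))
    p_noxa = float(predict_prob(model_noxa, fd))
    diff = p_oxa - p_noxa
    if abs(diff) < equivalence_margin:
        preferred = "EQUIVALENT"
    else:
        preferred = "OXA" if diff > 0 else "NO_OXA"
    return Recommendation(fd=float(fd), p_oxa=p_oxa, p_noxa=p_noxa, preferred=preferred, margin=diff)
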