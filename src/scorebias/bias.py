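"""Analytic bias of the two-stage score estimator under an invalid instrument.

If an instrument ``z`` has a direct effect ``delta`` on the outcome (i.e. it
violates the exclusion restriction) while its Stage I coefficient on the
exposure is ``d``, the two-stage coefficient on the predicted score picks up
a bias of ``delta / d``: the direct path from z to the outcome is
misattributed to the exposure, scaled by how strongly z predicts the
exposure.  The expected distorted estimate is therefore
``theta + delta / d`` where ``theta`` is the true exposure effect.

The ratio is exact for a linear Stage II.  For a Cox Stage II it is a
first-order approximation: the unmodelled exposure residual and any omitted
determinants act as extra frailty and attenuate all log-hazard coefficients
slightly toward zero, so the empirical Monte Carlo mean falls a few percent
short of ``theta + delta / d`` (see the experiments module).

As ``d -> 0`` the bias diverges; instead of raising inside batch sweeps,
``analytic_bias`` returns a report flagged ``finite=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InfiniteBiasError

__all__ = [
    "BiasReport",
    "D_TOLERANCE",
    "analytic_bias",
    "expected_biased_estimate",
    "multi_instrument_bias_linear",
    "decompose_applied",
    "bias_sensitivity_curve",
]

#: below this |d| the bias ratio is treated as unbounded
D_TOLERANCE = 1e-8


@dataclass(frozen=True)
class BiasReport:
    """Omitted-instrument bias delta/d and the distorted estimate it implies.

    ``finite`` is False exactly when ``|d|`` is numerically zero; in that
    case ``bias`` and ``expected_estimate`` are NaN placeholders and must
    not be interpreted.
    """

    delta: float
    d: float
    bias: float
    finite: bool
    theta: float = None
    expected_estimate: float = None


def analytic_bias(delta: float, d: float, theta: float = None) -> BiasReport:
    """Bias of the score coefficient when the instrument has direct effect
    ``delta`` on the outcome and Stage I coefficient ``d`` on the exposure.

    When ``theta`` (the true exposure effect) is supplied, the report also
    carries ``expected_estimate = theta + delta / d``.
    """
    if abs(d) < D_TOLERANCE:
        return BiasReport(delta=float(delta), d=float(d), bias=math.nan,
                          finite=False, theta=theta,
                          expected_estimate=math.nan if theta is not None
                          else None)
    bias = float(delta) / float(d)
    expected = None if theta is None else float(theta) + bias
    return BiasReport(delta=float(delta), d=float(d), bias=bias, finite=True,
                      theta=theta, expected_estimate=expected)


def expected_biased_estimate(theta: float, delta: float, d: float) -> float:
    """The distorted score coefficient ``theta + delta / d``.

    Raises :class:`InfiniteBiasError` when ``d`` is numerically zero.
    """
    if abs(d) < D_TOLERANCE:
        raise InfiniteBiasError(
            f"instrument-exposure coefficient d={d} is numerically zero; "
            "the omitted-instrument bias is unbounded"
        )
    return float(theta) + float(delta) / float(d)


def multi_instrument_bias_linear(deltas, ds, var_z=None) -> float:
    """Score-coefficient bias with several mutually independent instruments,
    linear outcome model.

    With instruments z_j (variance ``var_z[j]``), Stage I coefficients
    ``ds[j]`` and direct outcome effects ``deltas[j]``, the score varies
    across subjects (conditional on the common covariates) through
    sum_j d_j z_j, and regressing the outcome on the score projects the
    omitted direct effects onto it:

        bias = sum_j delta_j d_j var_j / sum_j d_j^2 var_j.

    Reduces to ``delta / d`` for a single instrument.  Valid only when the
    instruments are independent of each other and of the Stage II
    covariates.
    """
    deltas = np.asarray(deltas, dtype=float)
    ds = np.asarray(ds, dtype=float)
    if var_z is None:
        var_z = np.ones_like(ds)
    var_z = np.asarray(var_z, dtype=float)
    if not (deltas.shape == ds.shape == var_z.shape):
        raise ValueError("deltas, ds and var_z must have matching shapes")
    denom = float(np.sum(ds ** 2 * var_z))
    if denom < D_TOLERANCE ** 2:
        raise InfiniteBiasError(
            "all instrument-exposure coefficients are numerically zero; "
            "the score carries no instrument signal"
        )
    return float(np.sum(deltas * ds * var_z)) / denom


def decompose_applied(
    measured_effect: float,
    instrument_outcome_coef: float,
    instrument_exposure_coef: float,
) -> BiasReport:
    """Decompose an applied two-stage estimate into true effect plus bias.

    Parameters are the three regression coefficients of the applied
    analysis: the exposure effect estimated from *measured* exposure data
    (the benchmark), the instrument's coefficient in the outcome regression,
    and the instrument's Stage I coefficient on the exposure.  The report's
    ``expected_estimate`` is what the two-stage score coefficient should be
    if the bias mechanism is the whole story.
    """
    if abs(instrument_exposure_coef) < D_TOLERANCE:
        raise InfiniteBiasError(
            "instrument-exposure coefficient is numerically zero; "
            "decomposition undefined"
        )
    return analytic_bias(instrument_outcome_coef, instrument_exposure_coef,
                         theta=measured_effect)


def bias_sensitivity_curve(
    theta: float,
    grid,
    delta: float = None,
    d: float = None,
    min_abs_d: float = 0.05,
) -> pd.DataFrame:
    """Expected distorted estimate ``theta + delta/d`` along a grid.

    Exactly one of ``delta`` or ``d`` must be fixed; the grid then varies
    the other.  Grid points where ``|d|`` falls below ``min_abs_d`` are
    flagged ``evaluated=False`` and carry NaN instead of an exploding
    ratio.

    Returns a frame with columns ``(value, bias, expected_estimate,
    evaluated)``, one row per grid point.
    """
    if (delta is None) == (d is None):
        raise ValueError("fix exactly one of delta or d")
    grid = np.asarray(grid, dtype=float)
    if not np.all(np.isfinite(grid)):
        raise ValueError("grid values must be finite")
    rows = []
    for g in grid:
        cur_delta = g if delta is None else delta
        cur_d = g if d is None else d
        if abs(cur_d) < min_abs_d:
            rows.append((g, math.nan, math.nan, False))
        else:
            b = cur_delta / cur_d
            rows.append((g, b, theta + b, True))
    return pd.DataFrame(
        rows, columns=["value", "bias", "expected_estimate", "evaluated"]
    )
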