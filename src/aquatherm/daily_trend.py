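"""Quadratic daytime trend in operative and body temperatures.

Shallow water warms through the day and the warming decelerates, so both
operative (T_e) and body (T_b) temperatures follow a concave quadratic in
clock hour over the observation window (10:00-17:00).  This module fits
the fixed-effects skeleton of that model by ordinary least squares,

    T = b0 + b1 * hour + b2 * hour**2 + b3 * species + error,

with hours on the raw decimal clock scale and the species term as a
treatment-coded offset.  Random individual intercepts/slopes and variance
weighting are deliberately out of scope, so OLS standard errors here are
not exchangeable with those of a mixed-model fit on the same data; the
point estimates of the fixed coefficients are.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DesignError, LabelError

__all__ = ["TrendModel", "fit_quadratic_trend", "predict_trend"]


@dataclass(frozen=True)
class TrendModel:
    """Fitted quadratic trend with an optional species offset.

    ``species_levels`` holds (baseline, offset) level names when a species
    term was fitted; the offset applies to the second level.
    """

    intercept: float
    linear: float
    quadratic: float
    species_offset: float = 0.0
    response: str = "Te"
    stderr: dict = field(default_factory=dict)
    species_levels: tuple = ()
    hour_span: tuple = (10.0, 17.0)

    @property
    def peak_hour(self) -> float:
        """Vertex of the parabola, -b1/(2*b2); NaN for a flat quadratic."""
        if self.quadratic == 0:
            return float("nan")
        return -self.linear / (2.0 * self.quadratic)


def fit_quadratic_trend(
    observations: pd.DataFrame,
    value_col: str = "value",
    response: str = "Te",
    species_col: str | None = "species",
) -> TrendModel:
    """OLS fit of ``value ~ 1 + hour + hour^2 [+ species]``.

    ``observations`` needs columns ``hour`` and ``value_col`` (plus
    ``species_col`` for the two-level species offset; pass ``None`` to
    drop the term).  At least four distinct hours are required for a
    quadratic plus residual.
    """
    hours = observations["hour"].to_numpy(dtype=float)
    y = observations[value_col].to_numpy(dtype=float)
    if len(np.unique(hours)) < 4:
        raise DesignError("need >= 4 distinct hours to fit a quadratic trend")
    cols = {"const": np.ones_like(hours), "hour": hours, "hour2": hours**2}
    levels: tuple = ()
    if species_col is not None:
        sp = observations[species_col].astype(str).to_numpy()
        uniq = sorted(pd.unique(sp))
        if len(uniq) == 1:
            raise DesignError("species term requested but only one species present")
        if len(uniq) > 2:
            raise DesignError("species offset supports exactly two species")
        levels = tuple(uniq)
        cols["species"] = (sp == uniq[1]).astype(float)
    X = pd.DataFrame(cols)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise DesignError("rank-deficient design matrix")
    fit = sm.OLS(y, X).fit()
    params, bse = fit.params, fit.bse
    return TrendModel(
        intercept=float(params["const"]),
        linear=float(params["hour"]),
        quadratic=float(params["hour2"]),
        species_offset=float(params.get("species", 0.0)),
        response=response,
        stderr={k: float(v) for k, v in bse.items()},
        species_levels=levels,
        hour_span=(float(hours.min()), float(hours.max())),
    )


def predict_trend(model: TrendModel, hour: float, species: str | None = None) -> float:
    """Evaluate the fitted trend at a clock hour for a species.

    Hours outside the fitted span trigger an extrapolation warning (the
    parabola keeps no physical meaning outside the observation window).
    """
    h = float(hour)
    lo, hi = model.hour_span
    if h < lo or h > hi:
        warnings.warn(
            f"hour {h:g} outside fitted span [{lo:g}, {hi:g}]; extrapolating",
            stacklevel=2,
        )
    offset = 0.0
    if model.species_levels:
        if species is None or species not in model.species_levels:
            raise LabelError(
                f"species must be one of {model.species_levels}, got {species!r}"
            )
        if species == model.species_levels[1]:
            offset = model.species_offset
    elif species is not None:
        raise LabelError("model was fitted without a species term")
    return model.intercept + model.linear * h + model.quadratic * h**2 + offset
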