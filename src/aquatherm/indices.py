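"""Thermoregulatory indices: habitat thermal quality (d_e), accuracy of
thermoregulation (d_b), and effectiveness (E).

All three are deviations from the preferred-temperature (T_p) range:

* d_e — deviation of the (mean) operative temperature from the T_p range;
  0 when the habitat offers preferred temperatures, larger when it is
  thermally worse.
* d_b — the same deviation computed on the animal's body temperature;
  smaller means more accurate thermoregulation.
* E — effectiveness.  The difference form ``E = d_e - d_b`` is the
  default: ~0 indicates thermoconformity, positive values active
  thermoregulation, negative values avoidance of preferred temperatures.
  The historical ratio form ``E = d_b / d_e`` is also provided; it is
  undefined (NaN) when d_e = 0.  Note that the classical ratio-based
  effectiveness is often written 1 - d_b/d_e elsewhere; here the plain
  ratio is computed and the choice is left to the caller.

Indices are computed per individual per hour because the water column
warms through the day, then summarised per species with bootstrap CIs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    JoinError,
    LabelError,
    MissingDataError,
    ParameterError,
)
from .thermal_environment import TeProfile, column_at, te_at

OBSERVATION_COLUMNS = (
    "individual_id",
    "species",
    "tank_id",
    "date",
    "hour",
    "depth_cm",
)

DE_CONVENTIONS = ("deviation_of_mean", "mean_of_deviations")
E_VARIANTS = ("difference", "ratio")


@dataclass(frozen=True)
class TpRange:
    """Preferred-temperature interval [lower_C, upper_C]."""

    lower_C: float
    upper_C: float

    def __post_init__(self):
        if self.lower_C > self.upper_C:
            raise ParameterError(
                f"inverted T_p range: lower {self.lower_C} > upper {self.upper_C}"
            )


def load_observations(path) -> pd.DataFrame:
    """Read a behavioral-observation CSV (header
    ``individual_id,species,tank_id,date,hour,depth_cm``)."""
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"no data rows in {path}") from None
    missing = [c for c in OBSERVATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"observation CSV missing column(s): {', '.join(missing)}")
    if df.empty:
        raise EmptyInputError(f"no data rows in {path}")
    df["date"] = pd.to_datetime(df["date"])
    df["hour"] = df["hour"].astype(float)
    df["depth_cm"] = df["depth_cm"].astype(float)
    for c in ("individual_id", "species", "tank_id"):
        df[c] = df[c].astype(str)
    return df[list(OBSERVATION_COLUMNS)]


def deviation_from_range(temp, tp_range: TpRange):
    """Distance (deg C, >= 0) of a temperature from the T_p range; exactly
    0 inside the range.  Accepts scalars or arrays."""
    t = np.asarray(temp, dtype=float)
    if not np.all(np.isfinite(t)):
        raise MissingDataError("non-finite temperature passed to deviation")
    dev = np.where(
        t < tp_range.lower_C,
        tp_range.lower_C - t,
        np.where(t > tp_range.upper_C, t - tp_range.upper_C, 0.0),
    )
    return float(dev) if np.isscalar(temp) or dev.ndim == 0 else dev


def compute_de(
    profile: TeProfile,
    tp_range: TpRange,
    hours,
    convention: str = "deviation_of_mean",
    date=None,
) -> pd.Series:
    """Habitat thermal quality d_e at each clock hour.

    ``deviation_of_mean`` (default): deviation of the column-mean T_e from
    the range.  ``mean_of_deviations``: mean over depths of each depth's
    own deviation — the convention under which a depth-indifferent animal
    has E = 0 in expectation.
    """
    if convention not in DE_CONVENTIONS:
        raise ParameterError(
            f"unknown d_e convention {convention!r}; choose from {DE_CONVENTIONS}"
        )
    base = profile.date if date is None else pd.Timestamp(date).normalize()
    out = {}
    for h in hours:
        col = column_at(profile, base + pd.Timedelta(hours=float(h)))
        if convention == "deviation_of_mean":
            out[float(h)] = deviation_from_range(float(col.mean()), tp_range)
        else:
            out[float(h)] = float(np.mean(deviation_from_range(col, tp_range)))
    return pd.Series(out, name="de_C")


def compute_db(tb_C, tp_range: TpRange):
    """Accuracy of thermoregulation: deviation of body temperature from
    the T_p range (same rule as d_e, applied to T_b)."""
    if tb_C is None or (np.isscalar(tb_C) and not np.isfinite(tb_C)):
        raise MissingDataError("body temperature not assigned")
    return deviation_from_range(tb_C, tp_range)


def compute_effectiveness(de_C, db_C, variant: str = "difference"):
    """Effectiveness of thermoregulation from d_e and d_b.

    ``difference``: E = d_e - d_b.  ``ratio``: E = d_b / d_e, NaN where
    d_e = 0 (undefined).  Inputs must be non-negative.
    """
    if variant not in E_VARIANTS:
        raise ParameterError(f"unknown E variant {variant!r}; choose from {E_VARIANTS}")
    de = np.asarray(de_C, dtype=float)
    db = np.asarray(db_C, dtype=float)
    if np.any(de < 0) or np.any(db < 0):
        raise ParameterError("d_e and d_b must be non-negative")
    if variant == "difference":
        e = de - db
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            e = np.where(de == 0, np.nan, db / de)
    return float(e) if e.ndim == 0 else e


def build_index_table(
    observations: pd.DataFrame,
    profiles: Mapping[str, TeProfile],
    ranges: Mapping[str, TpRange],
    convention: str = "deviation_of_mean",
    variant: str = "difference",
    tank_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """One index record per individual-hour observation.

    Body temperature is assigned from the tank's temperature profile at
    the occupied depth (``te_at``).  Tanks without their own loggers are
    routed to a logger-equipped tank through ``tank_map``.

    Returns a DataFrame with columns individual_id, species, tank_id,
    date, hour, depth_cm, tb_C, te_mean_C, de_C, db_C, e_diff_C, e_ratio.
    """
    tank_map = dict(tank_map or {})
    missing_tanks = sorted(
        {t for t in observations["tank_id"].unique() if tank_map.get(t, t) not in profiles}
    )
    if missing_tanks:
        raise JoinError(f"no temperature profile for tank(s): {missing_tanks}")
    missing_sp = sorted(set(observations["species"].unique()) - set(ranges))
    if missing_sp:
        raise JoinError(f"no T_p range for species: {missing_sp}")

    rows = []
    for obs in observations.itertuples(index=False):
        profile = profiles[tank_map.get(obs.tank_id, obs.tank_id)]
        when = pd.Timestamp(obs.date).normalize() + pd.Timedelta(hours=float(obs.hour))
        tb = te_at(profile, obs.depth_cm, when)
        col = column_at(profile, when)
        rng = ranges[obs.species]
        if convention == "deviation_of_mean":
            de = deviation_from_range(float(col.mean()), rng)
        else:
            de = float(np.mean(deviation_from_range(col, rng)))
        db = compute_db(tb, rng)
        rows.append(
            {
                "individual_id": obs.individual_id,
                "species": obs.species,
                "tank_id": obs.tank_id,
                "date": pd.Timestamp(obs.date).normalize(),
                "hour": float(obs.hour),
                "depth_cm": float(obs.depth_cm),
                "tb_C": tb,
                "te_mean_C": float(col.mean()),
                "de_C": de,
                "db_C": db,
                "e_diff_C": de - db,
                "e_ratio": compute_effectiveness(de, db, "ratio"),
            }
        )
    if convention not in DE_CONVENTIONS:
        raise ParameterError(f"unknown d_e convention {convention!r}")
    if variant not in E_VARIANTS:
        raise ParameterError(f"unknown E variant {variant!r}")
    return pd.DataFrame(rows)


def summarize_indices(
    records: pd.DataFrame,
    group_by: str = "species",
    per_individual_first: bool = False,
    n_boot: int = 9999,
    level: float = 0.95,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-group means of T_e, T_b, d_e, d_b and E with bootstrap CIs.

    Default aggregation is the grand mean over individual-hour records;
    ``per_individual_first`` averages within individuals before taking
    the group mean (the aggregation order is a reporting choice, so both
    are offered).
    """
    from .resampling import bootstrap_ci

    if records.empty:
        raise EmptyInputError("no index records to summarise")
    if group_by not in records.columns:
        raise LabelError(f"grouping column {group_by!r} not in records")
    metrics = ["te_mean_C", "tb_C", "de_C", "db_C", "e_diff_C"]
    rng = np.random.default_rng(seed)
    rows = []
    for grp_label, grp in records.groupby(group_by, sort=True):
        data = grp.groupby("individual_id")[metrics].mean() if per_individual_first else grp
        row = {group_by: grp_label, "n_records": len(grp),
               "n_individuals": grp["individual_id"].nunique()}
        for m in metrics:
            vals = data[m].to_numpy(dtype=float)
            row[f"{m}_mean"] = float(vals.mean())
            if len(vals) >= 2:
                ci = bootstrap_ci(
                    vals, n_boot=n_boot, level=level,
                    seed=int(rng.integers(2**31 - 1)),
                )
                row[f"{m}_ci_lower"], row[f"{m}_ci_upper"] = ci.lower, ci.upper
            else:
                row[f"{m}_ci_lower"] = row[f"{m}_ci_upper"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
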