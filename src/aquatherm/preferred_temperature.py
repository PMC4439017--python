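"""Preferred-temperature (T_p) ranges from thermal-gradient trials.

Animals free to move along a horizontal aquatic gradient (compartments at
8-30 deg C in 2 deg C steps by default) reveal the body-temperature range
they defend when thermoregulation is cost-free.  Body temperature is read
off as the nominal temperature of the occupied compartment (small-bodied
ectotherms equilibrate with the surrounding water within minutes), the
range is bounded by the 10th and 90th percentiles of each individual's
selected temperatures, and individuals that spent almost the whole trial
inactive or out of the water are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    FormatError,
    LabelError,
    ParameterError,
    SampleSizeError,
)

GRADIENT_COLUMNS = (
    "individual_id",
    "species",
    "timestamp",
    "compartment",
    "in_water",
    "active",
)


@dataclass(frozen=True)
class GradientConfig:
    """Geometry of the thermal gradient: one nominal temperature per
    compartment, with the engineering tolerance on each step."""

    compartment_temps: tuple = tuple(float(t) for t in range(8, 31, 2))
    tolerance_C: float = 0.5

    def __post_init__(self):
        temps = np.asarray(self.compartment_temps, dtype=float)
        if len(temps) < 2 or not (
            np.all(np.diff(temps) > 0) or np.all(np.diff(temps) < 0)
        ):
            raise ParameterError("compartment temperatures must be strictly monotone")
        if self.tolerance_C <= 0:
            raise ParameterError("tolerance must be positive")


@dataclass(frozen=True)
class TpEstimate:
    """One individual's preferred-temperature range.

    ``lower_C``/``upper_C`` are the 10th/90th percentiles (or whatever
    percentiles were requested) of its selected body temperatures.  Note
    the mean is not constrained to lie inside the percentile band: a
    sufficiently skewed sample can push it outside.
    """

    individual_id: str
    species: str
    lower_C: float
    upper_C: float
    mean_C: float
    n_obs: int

    def __post_init__(self):
        if self.lower_C > self.upper_C:
            raise ValueError("require lower_C <= upper_C")


@dataclass(frozen=True)
class SpeciesTpSummary:
    species: str
    mean_C: float
    ci_lower_C: float | None
    ci_upper_C: float | None
    n_individuals: int


def load_gradient_records(path) -> pd.DataFrame:
    """Read a gradient-trial CSV (header
    ``individual_id,species,timestamp,compartment,in_water,active``)."""
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"no data rows in {path}") from None
    missing = [c for c in GRADIENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gradient CSV missing column(s): {', '.join(missing)}")
    if df.empty:
        raise EmptyInputError(f"no data rows in {path}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["compartment"] = df["compartment"].astype(int)
    df["in_water"] = df["in_water"].astype(bool)
    df["active"] = df["active"].astype(bool)
    df["individual_id"] = df["individual_id"].astype(str)
    df["species"] = df["species"].astype(str)
    return df[list(GRADIENT_COLUMNS)]


def assign_tb_from_compartment(
    records: pd.DataFrame, config: GradientConfig | None = None
) -> pd.Series:
    """Body temperature per record: the occupied compartment's nominal
    temperature.  The +-tolerance band is deliberately ignored."""
    config = config or GradientConfig()
    temps = np.asarray(config.compartment_temps, dtype=float)
    comp = records["compartment"].to_numpy()
    bad = (comp < 0) | (comp >= len(temps))
    if bad.any():
        raise IndexError(
            f"compartment index out of range for a {len(temps)}-compartment "
            f"gradient: {sorted(set(comp[bad]))}"
        )
    return pd.Series(temps[comp], index=records.index, name="tb_C")


def filter_inactive(
    records: pd.DataFrame, threshold: float = 0.90
) -> tuple[list[str], pd.DataFrame]:
    """Exclude individuals that were inactive or out of the water for more
    than ``threshold`` of their records (strict inequality: exactly at the
    threshold is retained).

    Returns ``(retained_ids, report)`` where the report lists every
    individual with its inactive fraction and exclusion flag.
    """
    if not (0 < threshold <= 1):
        raise ParameterError(f"threshold must lie in (0, 1], got {threshold}")
    flagged = ~records["active"].astype(bool) | ~records["in_water"].astype(bool)
    frac = flagged.groupby(records["individual_id"]).mean()
    report = pd.DataFrame(
        {
            "individual_id": frac.index,
            "inactive_fraction": frac.to_numpy(),
            "excluded": (frac > threshold).to_numpy(),
        }
    ).reset_index(drop=True)
    retained = report.loc[~report["excluded"], "individual_id"].tolist()
    return retained, report


def estimate_tp_range(
    tb_samples,
    p_low: float = 10.0,
    p_high: float = 90.0,
    min_n: int = 10,
    individual_id: str = "",
    species: str = "",
) -> TpEstimate:
    """Percentile bounds and mean of one individual's selected temperatures.

    Percentiles use linear interpolation between order statistics (sorted
    sample, rank position ``(n-1)*p/100``).
    """
    x = np.asarray(list(tb_samples), dtype=float)
    if len(x) < min_n:
        raise SampleSizeError(
            f"need at least {min_n} body-temperature samples, got {len(x)}"
        )
    if not (0 <= p_low <= p_high <= 100):
        raise ParameterError("require 0 <= p_low <= p_high <= 100")
    lo, hi = np.percentile(x, [p_low, p_high], method="linear")
    return TpEstimate(
        individual_id=str(individual_id),
        species=str(species),
        lower_C=float(lo),
        upper_C=float(hi),
        mean_C=float(x.mean()),
        n_obs=len(x),
    )


def estimate_tp_table(
    records: pd.DataFrame,
    config: GradientConfig | None = None,
    p_low: float = 10.0,
    p_high: float = 90.0,
    inactivity_threshold: float = 0.90,
    min_n: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full gradient-trial workflow: activity filter, T_b assignment,
    per-individual percentile ranges.

    Only records where the animal was active and in the water enter the
    percentile calculation.  Returns ``(tp_table, exclusion_report)``.
    """
    config = config or GradientConfig()
    retained, report = filter_inactive(records, threshold=inactivity_threshold)
    usable = records[
        records["individual_id"].isin(retained)
        & records["active"].astype(bool)
        & records["in_water"].astype(bool)
    ].copy()
    usable["tb_C"] = assign_tb_from_compartment(usable, config)
    rows = []
    for (ind, sp), grp in usable.groupby(["individual_id", "species"], sort=True):
        est = estimate_tp_range(
            grp["tb_C"], p_low, p_high, min_n=min_n, individual_id=ind, species=sp
        )
        rows.append(
            {
                "individual_id": est.individual_id,
                "species": est.species,
                "lower_C": est.lower_C,
                "upper_C": est.upper_C,
                "mean_C": est.mean_C,
                "n_obs": est.n_obs,
            }
        )
    return pd.DataFrame(rows), report


def summarize_species_tp(
    estimates: pd.DataFrame,
    species: str,
    n_boot: int = 9999,
    level: float = 0.95,
    seed: int | None = None,
) -> SpeciesTpSummary:
    """Species mean of individual mean T_p with a percentile bootstrap CI.

    A species with a single individual gets its mean back with the CI
    flagged unavailable (``None`` bounds).
    """
    from .resampling import bootstrap_ci

    sub = estimates[estimates["species"] == species]
    if sub.empty:
        known = sorted(estimates["species"].unique())
        raise LabelError(f"unknown species {species!r}; have {known}")
    means = sub["mean_C"].to_numpy(dtype=float)
    if len(means) < 2:
        return SpeciesTpSummary(species, float(means.mean()), None, None, len(means))
    ci = bootstrap_ci(means, n_boot=n_boot, level=level, seed=seed)
    return SpeciesTpSummary(species, ci.point, ci.lower, ci.upper, len(means))


def species_tp_ranges(estimates: pd.DataFrame) -> dict[str, tuple[float, float]]:
    """Pooled species-level T_p range: the mean of individual lower bounds
    and the mean of individual upper bounds, per species."""
    out = {}
    for sp, grp in estimates.groupby("species"):
        out[str(sp)] = (float(grp["lower_C"].mean()), float(grp["upper_C"].mean()))
    return out
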