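"""Synthetic studies: stratified water columns plus behaving agents.

No raw field data accompany the analysis this package implements, so the
generator builds complete studies with known ground truth instead:

* a water column (45 cm deep, logged every 5 cm and every 30 min) whose
  surface follows the concave quadratic daytime warming observed in
  outdoor tanks in June, with linear thermal stratification (surface
  warmer than the bottom) and logger noise;
* agents observed hourly from 10:00 to 17:00 under one of two behavioral
  rules — a *thermoregulator* that, with a given effort probability,
  moves to the depth whose temperature deviates least from its preferred
  range (ties resolved to the deepest such depth), and a *conformer*
  that picks depths uniformly at random, i.e. passively samples the
  column;
* a laboratory thermal-gradient trial per species, from which the
  preferred-temperature range is re-estimated downstream.

Every generated table re-parses through the loaders of the analysis
modules, so the whole pipeline can be exercised end to end against the
analytic expectations stored in :class:`GroundTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .indices import TpRange, deviation_from_range
from .thermal_environment import TeProfile, column_at

BEHAVIORS = ("thermoregulator", "conformer")


@dataclass(frozen=True)
class SimConfig:
    """One species' study arm: column physics plus behavioral rule.

    Surface temperature follows ``a + b*t + c*t**2`` in decimal clock
    hours; the column cools linearly with depth at
    ``stratification_C_per_cm``; independent Gaussian logger noise is
    added per grid cell.
    """

    seed: int
    species: str = "sp_regulator"
    behavior: str = "thermoregulator"
    tp_range: TpRange = field(default_factory=lambda: TpRange(16.5, 19.0))
    effort: float = 0.8
    n_individuals: int = 30
    depth_max_cm: float = 45.0
    depth_step_cm: float = 5.0
    hours: tuple = tuple(range(10, 18))
    surface_trend: tuple = (-17.076, 4.912, -0.144)
    stratification_C_per_cm: float = 0.08
    noise_sd_C: float = 0.2
    n_gradient_individuals: int = 15
    n_gradient_inactive: int = 0
    gradient_temps: tuple = tuple(float(t) for t in range(8, 31, 2))

    def __post_init__(self):
        if self.behavior not in BEHAVIORS:
            raise ConfigError(f"behavior must be one of {BEHAVIORS}")
        if not (0 <= self.effort <= 1):
            raise ConfigError("effort must lie in [0, 1]")
        if self.noise_sd_C < 0:
            raise ConfigError("noise_sd_C must be >= 0")
        if self.depth_step_cm <= 0 or self.depth_max_cm % self.depth_step_cm:
            raise ConfigError("depth grid must divide depth_max_cm evenly")

    @property
    def depths(self) -> np.ndarray:
        return np.arange(0.0, self.depth_max_cm + self.depth_step_cm, self.depth_step_cm)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, for recovery checks downstream.

    ``expected_E_mod_C`` is the analytic expectation of the difference
    effectiveness under the mean-of-deviations habitat convention given
    the realised column: effort * mean_over_hours(mean_dev - min_dev).
    It is exactly 0 for a conformer.
    """

    species: str
    behavior: str
    effort: float
    tp_lower_C: float
    tp_upper_C: float
    expected_E_mod_C: float
    seed: int
    behaviors_by_individual: dict = field(default_factory=dict)


@dataclass
class StudyData:
    """A complete synthetic study: all input tables plus the truth ledger."""

    logger_readings: pd.DataFrame
    observations: pd.DataFrame
    gradient_records: pd.DataFrame
    truths: list
    profiles: dict
    tank_by_species: dict
    seed: int


def simulate_te_profile(
    config: SimConfig, tank_id: str = "tank_A", date: str = "2014-06-10",
    rng: np.random.Generator | None = None,
) -> TeProfile:
    """Simulate one tank's operative-temperature grid on 30-min timestamps.

    The time grid extends half an hour beyond the observation hours on
    each side so hourly evaluations never sit on the boundary.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    a, b, c = config.surface_trend
    t0, t1 = min(config.hours) - 0.5, max(config.hours) + 0.5
    t_hours = np.arange(t0, t1 + 0.25, 0.5)
    base = pd.Timestamp(date)
    times = pd.DatetimeIndex([base + pd.Timedelta(hours=float(t)) for t in t_hours])
    depths = config.depths
    surface = a + b * t_hours + c * t_hours**2
    grid = surface[None, :] - config.stratification_C_per_cm * depths[:, None]
    if config.noise_sd_C > 0:
        grid = grid + rng.normal(0.0, config.noise_sd_C, size=grid.shape)
    return TeProfile(tank_id=tank_id, depths=depths.astype(float), times=times,
                     grid=grid)


def expected_effectiveness(profile: TeProfile, config: SimConfig) -> float:
    """Analytic expected E (difference form, mean-of-deviations d_e) under
    the behavioral rule, given the realised column."""
    per_hour = []
    for h in config.hours:
        col = column_at(profile, profile.date + pd.Timedelta(hours=float(h)))
        devs = deviation_from_range(col, config.tp_range)
        per_hour.append(float(devs.mean() - devs.min()))
    effort = config.effort if config.behavior == "thermoregulator" else 0.0
    return effort * float(np.mean(per_hour))


def simulate_agent_positions(
    profile: TeProfile, config: SimConfig, id_prefix: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Hourly depth observations for ``config.n_individuals`` agents.

    Thermoregulators choose, with probability ``effort``, the depth whose
    temperature deviates least from the preferred range (ties broken
    toward the deepest such depth, since refuge from warm surface water
    lies below); otherwise — and always, for conformers — depth is
    uniform over the grid.
    """
    if len(profile.depths) == 0:
        raise ConfigError("empty depth grid")
    for h in config.hours:
        # raises OutOfRangeError if the profile does not cover the hours
        column_at(profile, profile.date + pd.Timedelta(hours=float(h)))
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    prefix = id_prefix if id_prefix is not None else f"{config.species}_"
    depths = profile.depths
    best_depth = {}
    for h in config.hours:
        col = column_at(profile, profile.date + pd.Timedelta(hours=float(h)))
        devs = deviation_from_range(col, config.tp_range)
        # deepest among the minimizers
        best = np.flatnonzero(devs == devs.min()).max()
        best_depth[h] = depths[best]
    rows = []
    date = profile.date.date().isoformat()
    for i in range(config.n_individuals):
        ind = f"{prefix}{i + 1:02d}"
        for h in config.hours:
            # one effort coin per record regardless of behavior, so that an
            # effort-0 regulator consumes the RNG exactly like a conformer
            u = rng.random()
            regulate = config.behavior == "thermoregulator" and u < config.effort
            depth = best_depth[h] if regulate else depths[rng.integers(len(depths))]
            rows.append(
                {
                    "individual_id": ind,
                    "species": config.species,
                    "tank_id": profile.tank_id,
                    "date": date,
                    "hour": int(h),
                    "depth_cm": float(depth),
                }
            )
    obs = pd.DataFrame(rows)
    truth = GroundTruth(
        species=config.species,
        behavior=config.behavior,
        effort=config.effort if config.behavior == "thermoregulator" else 0.0,
        tp_lower_C=config.tp_range.lower_C,
        tp_upper_C=config.tp_range.upper_C,
        expected_E_mod_C=expected_effectiveness(profile, config),
        seed=config.seed,
        behaviors_by_individual={
            f"{prefix}{i + 1:02d}": config.behavior
            for i in range(config.n_individuals)
        },
    )
    return obs, truth


def simulate_gradient_trial(
    config: SimConfig, rng: np.random.Generator | None = None,
    date: str = "2014-05-20",
) -> pd.DataFrame:
    """Laboratory gradient records whose selected temperatures reproduce
    the configured preferred range.

    Selected temperatures are drawn normal around the range midpoint with
    the spread chosen so the 10th/90th percentiles land on the range
    bounds, then snapped to the nearest compartment.  Optional inactive
    individuals sit motionless out of the water for the whole trial and
    should be excluded downstream.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    temps = np.asarray(config.gradient_temps, dtype=float)
    lo, hi = config.tp_range.lower_C, config.tp_range.upper_C
    center, spread = (lo + hi) / 2.0, max((hi - lo) / 2.0, 0.5)
    sd = spread / 1.2816  # z such that P10/P90 hit the range bounds
    times = pd.date_range(f"{date} 10:00", f"{date} 17:00", freq="10min")
    rows = []
    n_total = config.n_gradient_individuals + config.n_gradient_inactive
    for i in range(n_total):
        ind = f"{config.species}_g{i + 1:02d}"
        inactive = i >= config.n_gradient_individuals
        for ts in times:
            if inactive:
                comp, in_water, active = 0, False, False
            else:
                tb = rng.normal(center, sd)
                comp = int(np.argmin(np.abs(temps - tb)))
                in_water, active = True, True
            rows.append(
                {
                    "individual_id": ind,
                    "species": config.species,
                    "timestamp": ts.isoformat(),
                    "compartment": comp,
                    "in_water": in_water,
                    "active": active,
                }
            )
    return pd.DataFrame(rows)


def default_study_configs(seed: int) -> tuple[SimConfig, SimConfig]:
    """The canonical two-arm design: 30 thermoregulators defending a cool
    range versus 26 conformers with a warmer range that the afternoon
    column largely satisfies."""
    regulator = SimConfig(
        seed=seed,
        species="sp_regulator",
        behavior="thermoregulator",
        tp_range=TpRange(16.5, 19.0),
        effort=0.8,
        n_individuals=30,
    )
    conformer = SimConfig(
        seed=seed + 1,
        species="sp_conformer",
        behavior="conformer",
        tp_range=TpRange(20.5, 23.5),
        effort=0.0,
        n_individuals=26,
    )
    return regulator, conformer


def generate_study(
    config_a: SimConfig, config_b: SimConfig, out_dir=None,
    date: str = "2014-06-10",
) -> StudyData:
    """Generate a complete two-species study (one tank per species).

    Returns the in-memory tables; with ``out_dir`` set, also writes
    ``logger.csv``, ``observations.csv``, ``gradient.csv`` and
    ``truth.json`` (each CSV carries its seed in a ``#`` header comment).
    """
    if (
        not np.array_equal(config_a.depths, config_b.depths)
        or tuple(config_a.hours) != tuple(config_b.hours)
    ):
        raise ConfigError("study arms must share the depth grid and hours")
    arms = [(config_a, "tank_A"), (config_b, "tank_B")]
    loggers, observations, gradients, truths, profiles, tank_by_species = (
        [], [], [], [], {}, {}
    )
    for cfg, tank in arms:
        rng = np.random.default_rng(cfg.seed)
        profile = simulate_te_profile(cfg, tank_id=tank, date=date, rng=rng)
        obs, truth = simulate_agent_positions(profile, cfg, rng=rng)
        grad = simulate_gradient_trial(cfg, rng=rng)
        profiles[tank] = profile
        tank_by_species[cfg.species] = tank
        observations.append(obs)
        gradients.append(grad)
        truths.append(truth)
        long = pd.DataFrame(
            {
                "tank_id": tank,
                "depth_cm": np.repeat(profile.depths.astype(int), len(profile.times)),
                "timestamp": np.tile(profile.times.to_numpy(), len(profile.depths)),
                "temp_C": profile.grid.ravel(),
            }
        )
        loggers.append(long)
    study = StudyData(
        logger_readings=pd.concat(loggers, ignore_index=True),
        observations=pd.concat(observations, ignore_index=True),
        gradient_records=pd.concat(gradients, ignore_index=True),
        truths=truths,
        profiles=profiles,
        tank_by_species=tank_by_species,
        seed=config_a.seed,
    )
    if out_dir is not None:
        write_study(study, out_dir)
    return study


def write_study(study: StudyData, out_dir) -> dict[str, Path]:
    """Write the study's CSVs and truth JSON into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "logger": out / "logger.csv",
        "observations": out / "observations.csv",
        "gradient": out / "gradient.csv",
        "truth": out / "truth.json",
    }
    header = f"# seed={study.seed}\n"
    for key, frame in (
        ("logger", study.logger_readings),
        ("observations", study.observations),
        ("gradient", study.gradient_records),
    ):
        with open(paths[key], "w") as fh:
            fh.write(header)
            frame.to_csv(fh, index=False)
    with open(paths["truth"], "w") as fh:
        json.dump([asdict(t) for t in study.truths], fh, indent=2, default=str)
    return paths
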