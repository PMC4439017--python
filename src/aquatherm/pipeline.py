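"""End-to-end orchestration: gradient trials -> T_p ranges -> operative
profiles -> index table -> summaries, tests and trend fits.

The pipeline is deterministic given a config: the seed drives every
resampling step, conventions are recorded in the run log, and reruns on
identical inputs produce identical tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .daily_trend import fit_quadratic_trend
from .errors import AquathermError, StageError
from .indices import (
    TpRange,
    build_index_table,
    load_observations,
    summarize_indices,
)
from .preferred_temperature import (
    estimate_tp_table,
    load_gradient_records,
    species_tp_ranges,
)
from .resampling import (
    PermutationSpec,
    factorial_permutation,
    permutation_anova,
    variance_explained,
)
from .thermal_environment import (
    build_profile,
    check_inter_tank_consistency,
    load_te_readings,
)


@dataclass
class RunConfig:
    """Everything a reproducible run needs.

    ``tank_map`` routes tanks without loggers to logger-equipped tanks
    (identity for unmapped tanks).  Conventions default to the ones used
    throughout: 10th/90th percentile T_p bounds, deviation-of-mean d_e,
    difference-form E, individual-level permutation.
    """

    gradient_csv: str
    logger_csv: str
    observation_csv: str
    out_dir: str = "aquatherm_out"
    seed: int = 42
    tank_map: dict = field(default_factory=dict)
    p_low: float = 10.0
    p_high: float = 90.0
    inactivity_threshold: float = 0.90
    min_tp_obs: int = 10
    de_convention: str = "deviation_of_mean"
    e_variant: str = "difference"
    n_perm: int = 9999
    n_boot: int = 9999
    ci_level: float = 0.95
    permutation_unit: str = "individual"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.__dict__, sort_keys=False)


@dataclass
class PipelineReport:
    """All tables a run produces, plus the log lines."""

    tp_table: pd.DataFrame
    exclusion_report: pd.DataFrame
    species_ranges: dict
    index_table: pd.DataFrame
    summary_table: pd.DataFrame
    test_results: pd.DataFrame
    trend_table: pd.DataFrame
    consistency: object
    log_lines: list


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except AquathermError as exc:
        raise StageError(name, str(exc)) from exc
    except FileNotFoundError as exc:
        raise StageError(name, f"missing input file: {exc.filename}") from exc


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineReport:
    """Run every stage and (optionally) write the output tables.

    Outputs under ``config.out_dir``: ``tp_table.csv``, ``index_table.csv``,
    ``summary_table.csv``, ``tests.csv``, ``trend.csv``, ``run_log.txt``.
    Any stage failure propagates as a :class:`~aquatherm.errors.StageError`
    naming the stage.
    """
    log = [
        f"aquatherm {__version__}",
        f"seed={config.seed}",
        f"percentiles=({config.p_low}, {config.p_high})",
        f"de_convention={config.de_convention} e_variant={config.e_variant}",
        f"permutation_unit={config.permutation_unit} n_perm={config.n_perm} "
        f"n_boot={config.n_boot}",
    ]
    rng = np.random.default_rng(config.seed)

    # --- preferred temperatures -------------------------------------------
    gradient = _stage("load_gradient", load_gradient_records, config.gradient_csv)
    tp_table, exclusions = _stage(
        "tp_estimation",
        estimate_tp_table,
        gradient,
        p_low=config.p_low,
        p_high=config.p_high,
        inactivity_threshold=config.inactivity_threshold,
        min_n=config.min_tp_obs,
    )
    n_excl = int(exclusions["excluded"].sum())
    log.append(
        f"tp_estimation: {gradient['individual_id'].nunique()} individuals in, "
        f"{n_excl} excluded as inactive, {len(tp_table)} ranges out"
    )
    ranges = {
        sp: TpRange(lo, hi) for sp, (lo, hi) in species_tp_ranges(tp_table).items()
    }

    # --- operative temperature profiles -----------------------------------
    readings = _stage("load_logger", load_te_readings, config.logger_csv)
    tanks = sorted(readings["tank_id"].unique())
    profiles = {
        t: _stage("build_profile", build_profile, readings, t) for t in tanks
    }
    consistency = None
    if len(profiles) >= 2:
        try:
            consistency = check_inter_tank_consistency(list(profiles.values()))
            log.append(
                f"inter-tank max |dT|={consistency.max_abs_diff_C:.2f} C "
                f"(>{consistency.threshold_C} C: {consistency.exceeds})"
            )
        except AquathermError as exc:
            log.append(f"inter-tank check skipped: {exc}")
    log.append(f"profiles: {len(profiles)} tanks ({', '.join(tanks)})")

    # --- indices -----------------------------------------------------------
    observations = _stage("load_observations", load_observations, config.observation_csv)
    index_table = _stage(
        "index_table",
        build_index_table,
        observations,
        profiles,
        ranges,
        convention=config.de_convention,
        variant=config.e_variant,
        tank_map=config.tank_map,
    )
    log.append(
        f"index_table: {len(observations)} observations in, "
        f"{len(index_table)} individual-hour records out"
    )
    summary = _stage(
        "summaries",
        summarize_indices,
        index_table,
        n_boot=config.n_boot,
        level=config.ci_level,
        seed=int(rng.integers(2**31 - 1)),
    )

    # --- inference ---------------------------------------------------------
    tests = []
    spec1 = PermutationSpec(
        n_perm=config.n_perm,
        seed=int(rng.integers(2**31 - 1)),
        unit=config.permutation_unit,
    )
    for metric in ("de_C", "db_C", "e_diff_C"):
        res = _stage(
            "permutation_tests",
            permutation_anova,
            index_table[metric],
            index_table["species"],
            spec1,
            individuals=index_table["individual_id"],
        )
        tests.append(
            {
                "test": f"species effect on {metric}",
                "statistic": res.statistic_name,
                "observed": res.observed,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "p_value": res.p_value,
                "n_perm": res.n_perm_used,
            }
        )
    spec2 = PermutationSpec(
        n_perm=config.n_perm, seed=int(rng.integers(2**31 - 1)), unit="record"
    )
    fact = _stage(
        "permutation_tests",
        factorial_permutation,
        index_table["e_diff_C"],
        index_table["species"],
        index_table["hour"],
        spec2,
    )
    for key, label in (
        ("a", "species effect on e_diff_C (factorial)"),
        ("b", "hour effect on e_diff_C"),
        ("interaction", "hour x species interaction on e_diff_C"),
    ):
        res = fact[key]
        tests.append(
            {
                "test": label,
                "statistic": res.statistic_name,
                "observed": res.observed,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "p_value": res.p_value,
                "n_perm": res.n_perm_used,
            }
        )
    vc = _stage(
        "variance_components",
        variance_explained,
        index_table["e_diff_C"],
        index_table["individual_id"],
    )
    tests.append(
        {
            "test": "variance in e_diff_C explained by individual (%)",
            "statistic": "pct_between",
            "observed": vc.pct_between_individuals,
            "df_between": index_table["individual_id"].nunique() - 1,
            "df_within": len(index_table) - index_table["individual_id"].nunique(),
            "p_value": np.nan,
            "n_perm": 0,
        }
    )
    test_results = pd.DataFrame(tests)

    # --- daily trend -------------------------------------------------------
    trend_rows = []
    for response, col in (("Te", "te_mean_C"), ("Tb", "tb_C")):
        df = index_table.rename(columns={col: "value"})[["hour", "value", "species"]]
        species_col = "species" if df["species"].nunique() == 2 else None
        model = _stage(
            "daily_trend",
            fit_quadratic_trend,
            df,
            response=response,
            species_col=species_col,
        )
        trend_rows.append(
            {
                "response": response,
                "intercept": model.intercept,
                "linear": model.linear,
                "quadratic": model.quadratic,
                "species_offset": model.species_offset,
                "peak_hour": model.peak_hour,
            }
        )
    trend_table = pd.DataFrame(trend_rows)

    report = PipelineReport(
        tp_table=tp_table,
        exclusion_report=exclusions,
        species_ranges={k: (v.lower_C, v.upper_C) for k, v in ranges.items()},
        index_table=index_table,
        summary_table=summary,
        test_results=test_results,
        trend_table=trend_table,
        consistency=consistency,
        log_lines=log,
    )
    if write:
        _write_report(report, config)
    return report


def _write_report(report: PipelineReport, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.6g"
    report.tp_table.to_csv(out / "tp_table.csv", index=False, float_format=float_fmt)
    report.index_table.to_csv(out / "index_table.csv", index=False, float_format=float_fmt)
    report.summary_table.to_csv(out / "summary_table.csv", index=False, float_format=float_fmt)
    report.test_results.to_csv(out / "tests.csv", index=False, float_format=float_fmt)
    report.trend_table.to_csv(out / "trend.csv", index=False, float_format=float_fmt)
    with open(out / "species_ranges.json", "w") as fh:
        json.dump(report.species_ranges, fh, indent=2)
    with open(out / "run_log.txt", "w") as fh:
        fh.write("\n".join(report.log_lines) + "\n")
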