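"""Randomization inference: permutation ANOVA, bootstrap CIs, variance
components.

Index values and T_p boundaries are bounded, often skewed and carry
outliers, so group comparisons use a pseudo-F statistic whose null
distribution comes from permuting group labels rather than from the
parametric F distribution.  P values use the add-one rule,
``p = (1 + #{F* >= F_obs}) / (1 + n_perm)``, which keeps p in (0, 1] and
counts ties as extreme.  Confidence intervals for means are percentile
bootstrap intervals.

Repeated measures: hourly index records are pseudoreplicated within
individuals, so the default permutation unit is the individual — records
are collapsed to individual means before labels are shuffled.  Record
level permutation is available explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .errors import DesignError, ParameterError, SampleSizeError

UNITS = ("individual", "record")
SCHEMES = ("raw-label", "residual")


@dataclass(frozen=True)
class PermutationSpec:
    """How to run a permutation test: number of permutations, RNG seed,
    analysis unit, and the label-permutation scheme."""

    n_perm: int = 9999
    seed: int | None = None
    unit: str = "individual"
    scheme: str = "raw-label"

    def __post_init__(self):
        if self.n_perm < 1:
            raise ParameterError("n_perm must be >= 1")
        if self.unit not in UNITS:
            raise ParameterError(f"unit must be one of {UNITS}")
        if self.scheme not in SCHEMES:
            raise ParameterError(f"scheme must be one of {SCHEMES}")


@dataclass(frozen=True)
class TestResult:
    statistic_name: str
    observed: float
    p_value: float
    n_perm_used: int
    df_between: int
    df_within: int

    def __post_init__(self):
        if not (0 < self.p_value <= 1):
            raise ValueError("add-one p values lie in (0, 1]")


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    lower: float
    upper: float
    n_boot: int = 9999
    level: float = 0.95


@dataclass(frozen=True)
class VarianceComponents:
    """One-way decomposition of record variance by individual identity."""

    pct_between_individuals: float
    ss_between: float
    ss_total: float
    undefined: bool = False


def _group_codes(labels) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(labels))
    return codes, len(uniques)


def _pseudo_f_matrix(Y: np.ndarray, codes: np.ndarray, k: int) -> np.ndarray:
    """Row-wise one-way pseudo-F for a (n_perm, n) matrix of responses.

    Permuting responses against fixed labels is equivalent to permuting
    labels against fixed responses.
    """
    n = Y.shape[1]
    onehot = np.eye(k)[codes]  # (n, k)
    counts = onehot.sum(axis=0)
    grand = Y.mean(axis=1, keepdims=True)
    means = (Y @ onehot) / counts
    ssb = (counts * (means - grand) ** 2).sum(axis=1)
    sst = ((Y - grand) ** 2).sum(axis=1)
    ssw = np.maximum(sst - ssb, 0.0)  # guard against catastrophic cancellation
    dfb, dfw = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    return np.where((ssw == 0) & (ssb > 0), np.inf, f)


def _add_one_p(perm_stats: np.ndarray, observed: float) -> float:
    # ties count as >=; a tolerance absorbs last-ulp noise from summing the
    # same values in a permuted order, which would otherwise break exact ties
    thresh = observed - 1e-9 * (1.0 + abs(observed))
    return float((1 + np.sum(perm_stats >= thresh)) / (1 + len(perm_stats)))


def permutation_anova(
    values,
    groups,
    spec: PermutationSpec | None = None,
    individuals=None,
) -> TestResult:
    """One-way permutation ANOVA on a pseudo-F statistic.

    With ``spec.unit == "individual"`` (the default) and ``individuals``
    given, records are first collapsed to per-individual means so that the
    exchangeable units are individuals, not pseudoreplicated records.

    Raises :class:`~aquatherm.errors.DesignError` for fewer than two
    groups or any group with fewer than two units.
    """
    spec = spec or PermutationSpec()
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if individuals is not None and spec.unit == "individual":
        df = pd.DataFrame({"v": v, "g": g, "ind": np.asarray(individuals)})
        per_ind = df.groupby("ind").agg(v=("v", "mean"), g=("g", "first"))
        bad = df.groupby("ind")["g"].nunique()
        if (bad > 1).any():
            raise DesignError("an individual appears under more than one group")
        v, g = per_ind["v"].to_numpy(), per_ind["g"].to_numpy()
    codes, k = _group_codes(g)
    if k < 2:
        raise DesignError("need at least two groups")
    counts = np.bincount(codes, minlength=k)
    if counts.min() < 2:
        raise DesignError("every group needs at least two analysis units")
    observed = float(_pseudo_f_matrix(v[None, :], codes, k)[0])
    rng = np.random.default_rng(spec.seed)
    Y = rng.permuted(np.broadcast_to(v, (spec.n_perm, len(v))).copy(), axis=1)
    perm_stats = _pseudo_f_matrix(Y, codes, k)
    return TestResult(
        statistic_name="pseudo-F",
        observed=observed,
        p_value=_add_one_p(perm_stats, observed),
        n_perm_used=spec.n_perm,
        df_between=k - 1,
        df_within=len(v) - k,
    )


def _design(codes: np.ndarray, k: int) -> np.ndarray:
    """Treatment-coded dummy block (k-1 columns) for one factor."""
    d = np.eye(k)[codes]
    return d[:, 1:]


def _q_of(X: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(X)
    return q


def _rss(Y: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Row-wise residual sum of squares after projecting onto span(Q)."""
    return (Y**2).sum(axis=1) - ((Y @ Q) ** 2).sum(axis=1)


def _permute_within_blocks(
    rng: np.random.Generator, n_perm: int, n: int, blocks: np.ndarray
) -> np.ndarray:
    """(n_perm, n) index matrix permuting positions within each block."""
    idx = np.broadcast_to(np.arange(n), (n_perm, n)).copy()
    for b in np.unique(blocks):
        cols = np.flatnonzero(blocks == b)
        sub = np.broadcast_to(cols, (n_perm, len(cols))).copy()
        idx[:, cols] = rng.permuted(sub, axis=1)
    return idx


def factorial_permutation(
    values,
    factor_a,
    factor_b=None,
    spec: PermutationSpec | None = None,
) -> dict[str, TestResult]:
    """Two-way crossed permutation ANOVA (main effects + interaction).

    Main effects are tested by restricted permutation: responses are
    shuffled only within levels of the other factor, holding its effect
    fixed.  The interaction is tested by Freedman-Lane residual
    permutation: residuals from the additive (main-effects) fit are
    shuffled, re-attached to the additive fitted values, and the
    interaction pseudo-F is recomputed.

    With ``factor_b=None`` this degenerates to :func:`permutation_anova`.
    Returns ``{"a": ..., "b": ..., "interaction": ...}``.
    """
    spec = spec or PermutationSpec()
    if factor_b is None:
        return {"a": permutation_anova(values, factor_a, spec)}
    y = np.asarray(values, dtype=float)
    a_codes, ka = _group_codes(factor_a)
    b_codes, kb = _group_codes(factor_b)
    if ka < 2 or kb < 2:
        raise DesignError("both factors need at least two levels")
    cells = np.zeros((ka, kb), dtype=int)
    np.add.at(cells, (a_codes, b_codes), 1)
    if (cells == 0).any():
        empty = np.argwhere(cells == 0)
        raise DesignError(f"empty design cell(s) at (a, b) level indices {empty.tolist()}")
    n = len(y)
    ones = np.ones((n, 1))
    A, B = _design(a_codes, ka), _design(b_codes, kb)
    AB = (A[:, :, None] * B[:, None, :]).reshape(n, -1)
    Q_a = _q_of(np.hstack([ones, A]))
    Q_b = _q_of(np.hstack([ones, B]))
    Q_add = _q_of(np.hstack([ones, A, B]))
    Q_full = _q_of(np.hstack([ones, A, B, AB]))
    df_a, df_b, df_int = ka - 1, kb - 1, (ka - 1) * (kb - 1)
    rank_add, rank_full = 1 + df_a + df_b, ka * kb
    if n <= rank_full:
        raise DesignError("no residual degrees of freedom for the full model")

    def f_effect(Y, Q_reduced, Q_model, df_effect, rank_model):
        num = (_rss(Y, Q_reduced) - _rss(Y, Q_model)) / df_effect
        den = _rss(Y, Q_model) / (Y.shape[1] - rank_model)
        with np.errstate(divide="ignore", invalid="ignore"):
            return num / den

    rng = np.random.default_rng(spec.seed)
    results: dict[str, TestResult] = {}
    # main effects: restricted raw-label permutation within the other factor
    for name, Q_red, blocks, df_eff in (
        ("a", Q_b, b_codes, df_a),
        ("b", Q_a, a_codes, df_b),
    ):
        obs = float(f_effect(y[None, :], Q_red, Q_add, df_eff, rank_add)[0])
        idx = _permute_within_blocks(rng, spec.n_perm, n, blocks)
        perm = f_effect(y[idx], Q_red, Q_add, df_eff, rank_add)
        results[name] = TestResult(
            "pseudo-F", obs, _add_one_p(perm, obs), spec.n_perm, df_eff, n - rank_add
        )
    # interaction: Freedman-Lane permutation of additive-model residuals
    fitted = (y @ Q_add) @ Q_add.T
    resid = y - fitted
    obs = float(f_effect(y[None, :], Q_add, Q_full, df_int, rank_full)[0])
    R = rng.permuted(np.broadcast_to(resid, (spec.n_perm, n)).copy(), axis=1)
    perm = f_effect(fitted[None, :] + R, Q_add, Q_full, df_int, rank_full)
    results["interaction"] = TestResult(
        "pseudo-F", obs, _add_one_p(perm, obs), spec.n_perm, df_int, n - rank_full
    )
    return results


def bootstrap_ci(
    values,
    statistic: str | Callable = "mean",
    n_boot: int = 9999,
    level: float = 0.95,
    seed: int | None = None,
) -> BootstrapCI:
    """Percentile bootstrap CI for a statistic of one sample.

    Resamples with replacement at the original sample size; the interval
    is the ``(1-level)/2`` and ``1-(1-level)/2`` percentiles of the
    resampled statistic distribution.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise SampleSizeError("bootstrap needs at least two values")
    if not (0 < level < 1):
        raise ParameterError("level must lie in (0, 1)")
    fn = np.mean if statistic == "mean" else statistic
    if not callable(fn):
        raise ParameterError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    samples = x[idx]
    stats = samples.mean(axis=1) if fn is np.mean else np.apply_along_axis(fn, 1, samples)
    alpha = (1 - level) / 2
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapCI(
        point=float(fn(x)), lower=float(lo), upper=float(hi),
        n_boot=n_boot, level=level,
    )


def variance_explained(values, individual_ids) -> VarianceComponents:
    """Share of total sum of squares attributable to individual identity.

    One-way decomposition over records: ``pct = 100 * SS_between /
    SS_total``.  With zero total variance the share is undefined and
    flagged rather than forced to a number.
    """
    v = np.asarray(values, dtype=float)
    ids = np.asarray(individual_ids)
    codes, k = _group_codes(ids)
    if k < 2:
        raise DesignError("need at least two individuals")
    grand = v.mean()
    ss_total = float(((v - grand) ** 2).sum())
    counts = np.bincount(codes, minlength=k)
    sums = np.bincount(codes, weights=v, minlength=k)
    means = sums / counts
    ss_between = float((counts * (means - grand) ** 2).sum())
    if ss_total == 0:
        return VarianceComponents(np.nan, 0.0, 0.0, undefined=True)
    return VarianceComponents(
        pct_between_individuals=100.0 * ss_between / ss_total,
        ss_between=ss_between,
        ss_total=ss_total,
    )
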