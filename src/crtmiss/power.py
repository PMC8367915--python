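"""Power, relative efficiency and sample-size search for design comparison.

Power for the Wald test on the treatment effect uses the normal
approximation: with standardized effect d and estimator variance v,

    power = Phi(|d| / sqrt(v) - z_{1-alpha})        (one-sided)
    power = Phi(|d| / sqrt(v) - z_{1-alpha/2})      (two-sided, far tail ignored)

Relative efficiency of an alternative design versus a reference is the ratio
of their treatment-effect variances, reference variance in the numerator, so
RE < 1 means the alternative needs (1/RE - 1) x 100% extra clusters to match
the reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignError, SchemeMixture, TestSpec, TrialDesign
from .dropout import DropoutModel, count_probabilities, expected_counts, sample_counts
from .variance import (
    CorrelationStructure,
    _cluster_information,
    _invert_information,
    variance_treatment_effect,
)

__all__ = [
    "relative_efficiency",
    "extra_clusters_percent",
    "power",
    "design_variance",
    "required_m",
    "evaluate_designs",
    "mixture_variance",
]

#: Sentinel returned by :func:`required_m` when no m within the cap suffices.
UNATTAINABLE = -1


def relative_efficiency(var_reference: float, var_alternative: float) -> float:
    """Efficiency of an alternative design relative to a reference.

    ``var_reference / var_alternative``: values below one mean the
    alternative is less efficient than the reference.
    """
    if var_reference <= 0 or var_alternative <= 0:
        raise DesignError("variances must be positive")
    return var_reference / var_alternative


def extra_clusters_percent(re: float) -> float:
    """Percentage of extra clusters needed to offset relative efficiency ``re``."""
    if re <= 0:
        raise DesignError("relative efficiency must be positive")
    return (1.0 / re - 1.0) * 100.0


def power(variance: float, test: TestSpec) -> float:
    """Normal-approximation power of the test on treatment effect."""
    if variance <= 0:
        raise DesignError(f"variance must be positive, got {variance!r}")
    tail = test.alpha if test.sided == "one" else test.alpha / 2.0
    z = stats.norm.ppf(1.0 - tail)
    return float(stats.norm.cdf(abs(test.d) / np.sqrt(variance) - z))


def _dropout_weights(
    design: TrialDesign,
    dropout_by_arm: tuple[DropoutModel, DropoutModel] | None,
    mode: str,
    draws: int,
    rng: np.random.Generator | None,
) -> list[tuple[np.ndarray | None, np.ndarray | None]]:
    """Per-arm count-weight vectors; a list of one entry per variance evaluation."""
    if dropout_by_arm is None:
        return [(None, None)]
    ps = [count_probabilities(design, model) for model in dropout_by_arm]
    k = design.clusters
    if mode == "expected":
        return [(expected_counts(k, ps[0]), expected_counts(k, ps[1]))]
    if mode == "sampled":
        if rng is None:
            raise DesignError("sampled mode requires an rng or seed")
        return [
            (
                sample_counts(k, ps[0], rng).astype(float),
                sample_counts(k, ps[1], rng).astype(float),
            )
            for _ in range(draws)
        ]
    raise DesignError(f"mode: expected 'expected' or 'sampled', got {mode!r}")


def design_variance(
    design: TrialDesign,
    corr: CorrelationStructure,
    dropout_by_arm: tuple[DropoutModel, DropoutModel] | None = None,
    mode: str = "expected",
    draws: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Treatment-effect variance of a design, optionally under cluster dropout.

    With ``mode="expected"`` (default) the random per-count cluster numbers
    are replaced by their expectation ``k * p`` — fast and deterministic.
    ``mode="sampled"`` averages the variance over ``draws`` multinomial
    realizations of the dropout pattern instead.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    weight_sets = _dropout_weights(design, dropout_by_arm, mode, draws, rng)
    variances = [
        variance_treatment_effect(design, corr, weights) for weights in weight_sets
    ]
    return float(np.mean(variances))


def required_m(
    design_template: TrialDesign,
    corr: CorrelationStructure,
    test: TestSpec,
    target_power: float = 0.8,
    dropout_by_arm: tuple[DropoutModel, DropoutModel] | None = None,
    m_max: int = 20,
) -> int:
    """Smallest subjects per cluster-period reaching the target power.

    Searches ascending integers ``m = 1..m_max``; returns ``UNATTAINABLE``
    (-1) when even ``m_max`` falls short — power levels off in ``m``, so
    attainability is not guaranteed.
    """
    if not 0 < target_power < 1:
        raise DesignError(f"target_power: must be in (0, 1), got {target_power!r}")
    if m_max < 1:
        raise DesignError(f"m_max: must be >= 1, got {m_max!r}")
    for m in range(1, m_max + 1):
        var = design_variance(design_template.with_subjects(m), corr, dropout_by_arm)
        if power(var, test) >= target_power:
            return m
    return UNATTAINABLE


def evaluate_designs(
    designs: list[TrialDesign],
    m_range: range | list[int],
    corr: CorrelationStructure,
    test: TestSpec,
    dropout_by_arm: tuple[DropoutModel, DropoutModel] | None = None,
    mode: str = "expected",
    draws: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Variance, power and efficiency table over designs and cluster-period sizes.

    One row per ``m``; per design ``i`` (1-based) columns ``var_i`` and
    ``power_i``, plus ``RE_i`` (efficiency relative to design 1 at the same
    ``m``) for designs beyond the first.  Mirrors the layout of the
    comparison app's output table.
    """
    if not 1 <= len(designs) <= 5:
        raise DesignError(f"between 1 and 5 designs expected, got {len(designs)}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    rows = []
    for m in m_range:
        row: dict[str, float] = {"m": m}
        variances = []
        for i, design in enumerate(designs, start=1):
            var = design_variance(
                design.with_subjects(m), corr, dropout_by_arm, mode, draws, rng
            )
            variances.append(var)
            row[f"var_{i}"] = var
            row[f"power_{i}"] = power(var, test)
        for i in range(2, len(designs) + 1):
            row[f"RE_{i}"] = relative_efficiency(variances[0], variances[i - 1])
        rows.append(row)
    return pd.DataFrame(rows)


def mixture_variance(
    mix: SchemeMixture,
    weeks: int,
    clusters: int,
    subjects: int,
    corr: CorrelationStructure,
    dropout_by_arm: tuple[DropoutModel, DropoutModel] | None = None,
) -> float:
    """Treatment-effect variance when clusters follow a mixture of weekly schemes.

    All component schemes share the same number of weeks; per arm,
    ``k * w_l`` clusters follow scheme ``l``.  Period effects are indexed by
    the union of calendar days across the component schemes, so the
    information matrices of the components accumulate in a common fixed-effect
    parameterization before inversion.  A single-component mixture reduces to
    the plain design variance.
    """
    designs = [
        TrialDesign(scheme, weeks, clusters, subjects) for scheme in mix.schemes
    ]
    all_days = sorted({d for dsg in designs for d in dsg.calendar_days})
    day_col = {day: i for i, day in enumerate(all_days)}
    n_cols = len(all_days)
    info = np.zeros((n_cols + 1, n_cols + 1))
    for design, w in zip(designs, mix.weights):
        days = np.asarray(design.calendar_days, dtype=float)
        cols = np.array([day_col[d] for d in design.calendar_days])
        T = design.n_periods
        for arm in (0, 1):
            if dropout_by_arm is None:
                weights = np.zeros(T)
                weights[-1] = clusters
            else:
                weights = expected_counts(
                    clusters, count_probabilities(design, dropout_by_arm[arm])
                )
            for h in range(1, T + 1):
                if weights[h - 1] == 0.0:
                    continue
                info += (
                    w
                    * weights[h - 1]
                    * _cluster_information(days[:h], cols[:h], n_cols, subjects, corr, arm)
                )
    cov = _invert_information(info, n_cols)
    return float(cov[-1, -1])
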