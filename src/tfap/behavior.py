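"""Social-interaction phenotyping and behavioral effect statistics.

SI-rate is the ratio of interaction-zone times between the
target-present and target-absent phases of the social interaction
test. Stressed animals with SI-rate < 1 are called susceptible,
>= 1 resilient; SI-rates above 4 are excluded as outliers before
classification. The original Methods text literally describes the
inverse ratio (empty : occupied), which contradicts the
susceptible < 1 cutoff; the direction is therefore configurable and
defaults to occupied : empty.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tfap._errors import DegenerateDataError, MissingControlError

OUTLIER_SI_THRESHOLD = 4.0
SUSCEPTIBLE_SI_CUTOFF = 1.0


def si_rate(
    time_with_mouse: float,
    time_no_mouse: float,
    direction: str = "with_over_without",
) -> float:
    """Social-interaction rate for one trial.

    direction 'with_over_without' (default) returns occupied/empty;
    'without_over_with' returns the literal Methods-text inverse.
    """
    if direction == "with_over_without":
        num, den = time_with_mouse, time_no_mouse
    elif direction == "without_over_with":
        num, den = time_no_mouse, time_with_mouse
    else:
        raise ValueError(f"unknown SI direction {direction!r}")
    if den <= 0:
        raise ZeroDivisionError("denominator time is zero; SI-rate undefined")
    return num / den


def compute_si_rates(
    trials: pd.DataFrame, direction: str = "with_over_without"
) -> pd.DataFrame:
    """Add ``si_rate`` and an ``excluded`` flag to a trials table.

    Trials whose denominator time is zero get ``si_rate`` NaN and are
    excluded with a warning.
    """
    out = trials.copy()
    rates = np.full(len(out), np.nan)
    excluded = np.zeros(len(out), dtype=bool)
    reasons = [""] * len(out)
    for i, row in enumerate(out.itertuples()):
        try:
            rates[i] = si_rate(
                row.time_with_mouse, row.time_no_mouse, direction
            )
        except ZeroDivisionError:
            excluded[i] = True
            reasons[i] = "undefined_si_rate"
            warnings.warn(
                f"trial of {row.animal_id} day {row.day}: zero denominator "
                "time, SI-rate undefined; trial excluded",
                stacklevel=2,
            )
    out["si_rate"] = rates
    out["excluded"] = excluded
    out["exclusion_reason"] = reasons
    return out


def apply_outlier_rule(trials: pd.DataFrame) -> pd.DataFrame:
    """Exclude trials with SI-rate strictly larger than 4 (4.0 retained)."""
    out = trials.copy()
    outlier = out["si_rate"] > OUTLIER_SI_THRESHOLD
    out.loc[outlier, "excluded"] = True
    out.loc[outlier, "exclusion_reason"] = "si_rate_outlier"
    return out


def classify_phenotype(si: float, stressed: bool) -> str:
    """Susceptible iff stressed and SI-rate < 1; resilient iff >= 1."""
    if not stressed:
        return "control"
    return "susceptible" if si < SUSCEPTIBLE_SI_CUTOFF else "resilient"


def classify_phenotypes(
    trials: pd.DataFrame, stressed_groups: Sequence[str]
) -> pd.DataFrame:
    """Per-animal phenotype classes from flagged trials.

    Excluded trials contribute the ``excluded_outlier`` class;
    classification never sees an excluded SI value.
    """
    rows = []
    for row in trials.itertuples():
        if row.excluded:
            cls = "excluded_outlier"
        else:
            cls = classify_phenotype(row.si_rate, row.group in stressed_groups)
        rows.append(
            {"animal_id": row.animal_id, "day": row.day, "phenotype": cls}
        )
    return pd.DataFrame(rows)


def normalize_si_by_day(
    trials: pd.DataFrame, control_group: str = "control"
) -> pd.DataFrame:
    """Divide each SI-rate by the same-day control mean.

    Excluded trials are ignored both as controls and as outputs.
    """
    usable = trials[~trials["excluded"]]
    control_means = (
        usable[usable["group"] == control_group]
        .groupby("day")["si_rate"]
        .mean()
    )
    out = usable.copy()
    norm = np.full(len(out), np.nan)
    for i, row in enumerate(out.itertuples()):
        if row.day not in control_means.index:
            raise MissingControlError(
                f"no {control_group!r} trials on day {row.day}"
            )
        norm[i] = row.si_rate / control_means.loc[row.day]
    out["normalized_si"] = norm
    return out


def hedges_g(
    group_a: Sequence[float], group_b: Sequence[float]
) -> float:
    """Bias-corrected standardized mean difference.

    ``g = (meanA - meanB) / pooled_sd * J`` with the small-sample
    correction ``J = 1 - 3 / (4 (nA + nB) - 9)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled_var = (
        (na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)
    ) / (na + nb - 2)
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0
        raise DegenerateDataError("zero pooled SD with unequal means")
    j = 1.0 - 3.0 / (4.0 * (na + nb) - 9.0)
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var) * j)


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down family-wise adjustment."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, val)
        adjusted[idx] = running_max
    return adjusted


def binomial_two_sided_p(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial p (minimum-likelihood definition)."""
    if not 0 < p0 < 1:
        raise DegenerateDataError(f"degenerate null proportion {p0}")
    return float(stats.binomtest(k, n, p0).pvalue)


def recovery_proportion_test(
    cohort_flags: Mapping[str, Sequence[bool]],
    vehicle_flags: Sequence[bool],
) -> pd.DataFrame:
    """Per-cohort recovery proportions vs the vehicle proportion.

    ``flags`` mark animals not exhibiting depressive symptoms (the
    flag definition is the caller's; normalized SI >= 1 is the
    conventional default). Each cohort's success count is tested
    against the vehicle proportion with an exact two-sided binomial
    test; p-values are Holm-adjusted across cohorts.
    """
    vehicle = np.asarray(vehicle_flags, dtype=bool)
    p0 = vehicle.mean()
    if p0 <= 0 or p0 >= 1:
        raise DegenerateDataError(
            f"vehicle recovery proportion {p0} is degenerate"
        )
    names = list(cohort_flags)
    raw = []
    rows = []
    for name in names:
        flags = np.asarray(cohort_flags[name], dtype=bool)
        k, n = int(flags.sum()), flags.size
        p = binomial_two_sided_p(k, n, p0)
        raw.append(p)
        rows.append(
            {"cohort": name, "k": k, "n": n, "proportion": k / n, "p_raw": p}
        )
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(raw)
    return table
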