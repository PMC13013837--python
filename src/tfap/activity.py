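"""Assembly of the TF-activity profile (TFAP) and group statistics.

Raw reporter activities are normalized to the mean activity of the
same TF in the control animals of the same experiment, then pooled
across experiments into a long-format profile. Group-level changes
are summarized on the log2 scale relative to a reference group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tfap._errors import DegenerateDataError, MissingControlError

TFAP_COLUMNS = [
    "animal_id",
    "experiment_id",
    "group",
    "tf_id",
    "normalized_activity",
]


@dataclass(frozen=True)
class GroupActivitySummary:
    """Mean +/- SEM log2 activity change of one TF in one group."""

    tf_id: str
    group: str
    reference_group: str
    mean_log2fc: float
    sem_log2fc: float
    n: int


def normalize_to_controls(
    measurements: pd.DataFrame,
    group_labels: Mapping[str, str],
    control_group: str = "control",
) -> pd.DataFrame:
    """Normalize raw activities by within-experiment control means.

    Every (experiment_id, tf_id) stratum must contain at least one
    control animal; its mean raw activity becomes the denominator for
    all animals in that stratum. Returns the long-format TFAP.
    """
    work = measurements.copy()
    work["group"] = work["animal_id"].map(group_labels)
    if work["group"].isna().any():
        missing = work.loc[work["group"].isna(), "animal_id"].unique()
        raise KeyError(f"animals without a group label: {list(missing)[:5]}")

    out_rows = []
    for (exp, tf), sub in work.groupby(["experiment_id", "tf_id"], sort=True):
        ctrl = sub.loc[sub["group"] == control_group, "raw_activity"]
        if ctrl.empty:
            raise MissingControlError(
                f"no {control_group!r} measurements for TF {tf!r} in "
                f"experiment {exp!r}"
            )
        denom = float(ctrl.mean())
        norm = sub["raw_activity"] / denom
        out_rows.append(
            pd.DataFrame(
                {
                    "animal_id": sub["animal_id"],
                    "experiment_id": exp,
                    "group": sub["group"],
                    "tf_id": tf,
                    "normalized_activity": norm,
                }
            )
        )
    tfap = pd.concat(out_rows, ignore_index=True)
    return tfap[TFAP_COLUMNS]


def group_log2fc(
    tfap: pd.DataFrame,
    tf_id: str,
    group: str,
    reference_group: str = "control",
) -> GroupActivitySummary:
    """Corrected mean log2 activity change of ``group`` vs reference.

    Computed as mean per-animal log2(normalized activity) in ``group``
    minus the same mean in ``reference_group``; the SEM is that of the
    target group. The reference correction is a declared convention —
    the source data format does not pin down the "corrected mean".
    """
    sub = tfap[tfap["tf_id"] == tf_id]
    g = sub.loc[sub["group"] == group, "normalized_activity"]
    ref = sub.loc[sub["group"] == reference_group, "normalized_activity"]
    if g.empty:
        raise ValueError(f"no measurements for TF {tf_id!r} in group {group!r}")
    if ref.empty:
        raise ValueError(
            f"no measurements for TF {tf_id!r} in reference group "
            f"{reference_group!r}"
        )
    log_g = np.log2(g.to_numpy(dtype=float))
    log_ref = np.log2(ref.to_numpy(dtype=float))
    mean = float(log_g.mean() - log_ref.mean())
    sem = float(log_g.std(ddof=1) / np.sqrt(log_g.size)) if log_g.size > 1 else 0.0
    return GroupActivitySummary(
        tf_id=tf_id,
        group=group,
        reference_group=reference_group,
        mean_log2fc=mean,
        sem_log2fc=sem,
        n=int(log_g.size),
    )


def summarize_groups(
    tfap: pd.DataFrame, reference_group: str = "control"
) -> pd.DataFrame:
    """Group summary for every (TF, non-reference group) pair."""
    rows = []
    for tf_id in sorted(tfap["tf_id"].unique()):
        sub = tfap[tfap["tf_id"] == tf_id]
        for group in sorted(sub["group"].unique()):
            if group == reference_group:
                continue
            s = group_log2fc(tfap, tf_id, group, reference_group)
            rows.append(
                {
                    "tf_id": s.tf_id,
                    "group": s.group,
                    "reference_group": s.reference_group,
                    "mean_log2fc": s.mean_log2fc,
                    "sem_log2fc": s.sem_log2fc,
                    "n": s.n,
                }
            )
    return pd.DataFrame(rows)


def welch_t(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's unequal-variance t test, two-sided.

    Returns (t, Welch-Satterthwaite df, p). Implemented from the
    textbook formulas so it can be cross-checked against a reference
    implementation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise DegenerateDataError("zero variance in both groups")
    sa = va / a.size
    sb = vb / b.size
    t = (a.mean() - b.mean()) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (
        sa**2 / (a.size - 1) + sb**2 / (b.size - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def dunnett_many_to_one(
    control_values: Sequence[float],
    treatment_groups: Sequence[Sequence[float]],
    n_mc: int = 10_000,
    seed: int | None = None,
) -> np.ndarray:
    """Many-to-one comparisons vs control, family-wise adjusted.

    The adjustment simulates the joint null distribution of the
    maximum absolute Welch t across comparisons by Monte Carlo
    (standard normal draws at the observed sample sizes); the adjusted
    p for comparison i is ``P(max|t_null| >= |t_i|)`` with a +1
    continuity correction. With a single treatment group this reduces
    to the unadjusted Welch p within Monte-Carlo error.
    """
    control = np.asarray(control_values, dtype=float)
    if len(treatment_groups) < 1:
        raise ValueError("need at least one treatment group")
    groups = [np.asarray(g, dtype=float) for g in treatment_groups]
    if control.size < 2 or any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    if n_mc < 1000:
        warnings.warn(
            f"n_mc={n_mc} < 1000 gives coarse adjusted p-values",
            stacklevel=2,
        )
    t_obs = np.array([welch_t(g, control)[0] for g in groups])

    rng = np.random.default_rng(seed)
    null_ctrl = rng.normal(size=(n_mc, control.size))
    max_abs_t = np.zeros(n_mc)
    for g in groups:
        null_g = rng.normal(size=(n_mc, g.size))
        t_null = _welch_t_rows(null_g, null_ctrl)
        np.maximum(max_abs_t, np.abs(t_null), out=max_abs_t)
    adj = np.array(
        [(np.sum(max_abs_t >= abs(t)) + 1.0) / (n_mc + 1.0) for t in t_obs]
    )
    return np.minimum(adj, 1.0)


def _welch_t_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Welch t statistic for two (n_rep, n) sample matrices."""
    sa = a.var(axis=1, ddof=1) / a.shape[1]
    sb = b.var(axis=1, ddof=1) / b.shape[1]
    return (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(sa + sb)


def classify_cell_activity(
    cell_activities: Mapping[str, float],
    cluster_labels: Mapping[str, str],
    control_cluster_means: Mapping[str, float],
) -> dict[str, str]:
    """Per-cell high/low call against the control mean of the cell's cluster.

    ``high`` iff activity strictly exceeds the control average of the
    cluster; ties go to ``low``.
    """
    out: dict[str, str] = {}
    for cell, activity in cell_activities.items():
        cluster = cluster_labels[cell]
        if cluster not in control_cluster_means:
            raise MissingControlError(
                f"no control mean for cluster {cluster!r} (cell {cell!r})"
            )
        out[cell] = "high" if activity > control_cluster_means[cluster] else "low"
    return out
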