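"""Absolute qPCR quantification and raw reporter activity.

Transcript copy numbers are estimated against dilution series of
standards of known concentration: a linear standard curve (Cq vs
log10 copies) is fitted per amplicon and inverted for the samples.
The raw activity of a TF reporter construct is the ratio of reporter
to reference transcript copies within the same construct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tfap._errors import DegenerateDataError, FitError

logger = logging.getLogger(__name__)

MEASUREMENT_COLUMNS = [
    "animal_id",
    "experiment_id",
    "tf_id",
    "reporter_copies",
    "reference_copies",
    "raw_activity",
]


@dataclass(frozen=True)
class QpcrStandardSeries:
    """Dilution series of one amplicon standard.

    ``points`` holds (log10_copies, cq_cycles) pairs; at least three
    points are required for a curve fit.
    """

    target_id: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise FitError(
                f"standard series {self.target_id!r}: need >=3 dilution "
                f"points, got {len(self.points)}"
            )

    @property
    def log10_copies(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def cq(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted linear standard curve, Cq = intercept + slope * log10(copies)."""

    target_id: str
    slope: float  # cycles per log10 copies; negative for a working assay
    intercept: float  # cycles at 1 copy
    efficiency: float  # fractional amplification efficiency, 1.0 == 100%
    r_squared: float


def fit_standard_curve(series: QpcrStandardSeries) -> StandardCurve:
    """Ordinary least squares of Cq on log10 copies.

    Efficiency follows the standard qPCR convention
    ``E = 10**(-1/slope) - 1``.

    Raises
    ------
    FitError
        If the fitted slope is nonnegative (more template must never
        raise Cq) or the series is degenerate.
    """
    x = series.log10_copies
    y = series.cq
    if np.ptp(x) == 0:
        raise FitError(
            f"standard series {series.target_id!r}: all points share the "
            "same copy number"
        )
    fit = stats.linregress(x, y)
    if not fit.slope < 0:
        raise FitError(
            f"standard series {series.target_id!r}: fitted slope "
            f"{fit.slope:.4g} is nonnegative"
        )
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurve(
        target_id=series.target_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(efficiency),
        r_squared=float(fit.rvalue**2),
    )


def cq_to_copies(cq: float, curve: StandardCurve) -> float:
    """Invert a standard curve: ``copies = 10**((cq - intercept)/slope)``."""
    copies = 10.0 ** ((cq - curve.intercept) / curve.slope)
    if copies < 1.0:
        logger.warning(
            "sub-unit copy estimate %.3g for %s at Cq=%.3f",
            copies,
            curve.target_id,
            cq,
        )
    return copies


def raw_activity(reporter_copies: float, reference_copies: float) -> float:
    """Reporter-to-reference transcript copy ratio.

    The ratio is reported as-is for every TF, including
    repression-capable ones (elevated ratio == elevated activity).
    """
    if reference_copies <= 0:
        raise DegenerateDataError(
            f"reference copies must be positive, got {reference_copies}"
        )
    if reporter_copies <= 0:
        raise DegenerateDataError(
            f"reporter copies must be positive, got {reporter_copies}"
        )
    return reporter_copies / reference_copies


def read_standards_tsv(path) -> dict[str, QpcrStandardSeries]:
    """Read a standards table (target_id, log10_copies, cq) into series."""
    table = pd.read_csv(path, sep="\t")
    out: dict[str, QpcrStandardSeries] = {}
    for target_id, sub in table.groupby("target_id", sort=True):
        pts = tuple(zip(sub["log10_copies"].astype(float), sub["cq"].astype(float)))
        out[str(target_id)] = QpcrStandardSeries(str(target_id), pts)
    return out


def fit_all_curves(
    standards: dict[str, QpcrStandardSeries]
) -> dict[str, StandardCurve]:
    return {tid: fit_standard_curve(s) for tid, s in standards.items()}


def quantify_qpcr_table(
    qpcr: pd.DataFrame, curves: dict[str, StandardCurve]
) -> pd.DataFrame:
    """Convert a long qPCR table to absolute copies and raw activities.

    ``qpcr`` columns: animal_id, experiment_id, tf_id, role
    ('reporter'|'reference'), target_id, cq. Returns one row per
    animal x TF with reporter/reference copies and their ratio.
    """
    required = {"animal_id", "experiment_id", "tf_id", "role", "target_id", "cq"}
    missing = required - set(qpcr.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    copies = np.array(
        [
            cq_to_copies(row.cq, curves[row.target_id])
            for row in qpcr.itertuples()
        ]
    )
    work = qpcr.assign(copies=copies)
    wide = work.pivot_table(
        index=["animal_id", "experiment_id", "tf_id"],
        columns="role",
        values="copies",
        aggfunc="mean",
    ).reset_index()
    rows = []
    for row in wide.itertuples():
        rows.append(
            {
                "animal_id": row.animal_id,
                "experiment_id": row.experiment_id,
                "tf_id": row.tf_id,
                "reporter_copies": row.reporter,
                "reference_copies": row.reference,
                "raw_activity": raw_activity(row.reporter, row.reference),
            }
        )
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def write_measurements_tsv(measurements: pd.DataFrame, path) -> None:
    measurements.to_csv(path, sep="\t", index=False)


def simulate_standard_series(
    slope: float,
    intercept: float,
    copies: Sequence[float],
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    target_id: str = "standard",
) -> QpcrStandardSeries:
    """Generate a dilution series under a known linear curve.

    ``Cq = intercept + slope * log10(copies) + N(0, noise_sd)``.
    Lives here (next to the curve types) and is re-exported by the
    synthetic-data module.
    """
    copies = np.asarray(copies, dtype=float)
    if copies.size < 3:
        raise FitError(f"need >=3 dilution points, got {copies.size}")
    if np.any(copies <= 0):
        raise ValueError("standard copies must be strictly positive")
    log10_copies = np.log10(copies)
    cq = intercept + slope * log10_copies
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        cq = cq + rng.normal(0.0, noise_sd, size=cq.shape)
    return QpcrStandardSeries(target_id, tuple(zip(log10_copies, cq)))
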