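"""Coupling TF activities to downstream expression changes.

For each TF, the group-level activity change is paired with the mean
log2 fold change of its predicted regulon, plus regulon-level
statistics: DEG enrichment (hypergeometric, upper tail), absolute
fold-change shift (Wilcoxon rank-sum), variance broadening between
two contrasts (F test), a composite driver score, and activity vs
behavior Pearson correlations.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from tfap._errors import DegenerateDataError
from tfap.regulon import RegulonMap

INTEGRATION_COLUMNS = [
    "tf_id",
    "activity_log2fc",
    "mean_target_log2fc",
    "n_targets",
    "enrichment_p",
    "shift_p",
    "driver_score",
]


def tf_regulon_coupling(
    tfap_summary: pd.DataFrame,
    de_results: pd.DataFrame,
    regulon_map: RegulonMap,
    weighted: bool = False,
) -> pd.DataFrame:
    """Pair each TF's activity change with its regulon's mean log2FC.

    ``tfap_summary`` needs columns tf_id and mean_log2fc (one row per
    TF for the contrast of interest). The target mean is unweighted by
    default; ``weighted`` weights by the motif best score. TFs whose
    regulon has no gene with a DE result are excluded with a warning.
    """
    de_fc = de_results["log2fc"]
    rows = []
    for row in tfap_summary.itertuples():
        tf = row.tf_id
        targets = regulon_map.scores.get(tf, {})
        present = [g for g in targets if g in de_fc.index]
        if not present:
            warnings.warn(
                f"TF {tf!r}: no regulon target with a DE result; excluded",
                stacklevel=2,
            )
            continue
        fc = de_fc.loc[present].to_numpy(dtype=float)
        if weighted:
            w = np.array([targets[g] for g in present], dtype=float)
            mean_fc = float(np.average(fc, weights=w))
        else:
            mean_fc = float(fc.mean())
        rows.append(
            {
                "tf_id": tf,
                "activity_log2fc": float(row.mean_log2fc),
                "mean_target_log2fc": mean_fc,
                "n_targets": len(present),
            }
        )
    return pd.DataFrame(
        rows, columns=["tf_id", "activity_log2fc", "mean_target_log2fc", "n_targets"]
    )


def regulon_deg_enrichment(
    deg_set: set[str], regulon: set[str], universe: set[str]
) -> float:
    """Upper-tail hypergeometric p of the DEG / regulon overlap.

    Population N = |universe|, successes K = |regulon|, draws
    n = |deg_set|; returns P(overlap >= observed).
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not deg_set <= universe or not regulon <= universe:
        raise ValueError("deg_set and regulon must be subsets of the universe")
    overlap = len(deg_set & regulon)
    return float(
        stats.hypergeom.sf(
            overlap - 1, len(universe), len(regulon), len(deg_set)
        )
    )


def regulon_shift_test(
    de_log2fc: pd.Series, regulon_membership: Sequence[str] | set[str]
) -> tuple[float, float]:
    """Rank-sum test of |log2FC| for regulon vs non-regulon genes.

    Returns (W, p) where W is the rank sum of the regulon genes'
    absolute fold changes. Exact p for small tie-free samples, normal
    approximation with tie correction otherwise; if every |log2FC| is
    tied the test is flagged degenerate with p = 1.
    """
    member = de_log2fc.index.isin(set(regulon_membership))
    inside = np.abs(de_log2fc[member].to_numpy(dtype=float))
    outside = np.abs(de_log2fc[~member].to_numpy(dtype=float))
    if inside.size == 0 or outside.size == 0:
        raise ValueError("need at least one gene inside and outside the regulon")
    combined = np.concatenate([inside, outside])
    if np.all(combined == combined[0]):
        warnings.warn("all |log2fc| tied; shift test degenerate", stacklevel=2)
        return float(stats.rankdata(combined)[: inside.size].sum()), 1.0
    has_ties = np.unique(combined).size < combined.size
    small = inside.size + outside.size <= 25
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        inside, outside, alternative="two-sided", method=method,
        use_continuity=False,
    )
    w = float(stats.rankdata(combined)[: inside.size].sum())
    return w, float(res.pvalue)


def variance_broadening_test(
    log2fc_contrast1: Sequence[float], log2fc_contrast2: Sequence[float]
) -> tuple[float, int, int, float]:
    """Two-sided variance-ratio F test between two contrast vectors.

    F = var1 / var2 with df (n1 - 1, n2 - 1);
    p = min(1, 2 * min(P(F <= f), P(F >= f))).
    """
    x1 = np.asarray(log2fc_contrast1, dtype=float)
    x2 = np.asarray(log2fc_contrast2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each contrast needs at least 2 values")
    v1 = x1.var(ddof=1)
    v2 = x2.var(ddof=1)
    if v2 == 0:
        raise DegenerateDataError("zero variance in the denominator contrast")
    f = v1 / v2
    df1, df2 = x1.size - 1, x2.size - 1
    p = 2.0 * min(stats.f.cdf(f, df1, df2), stats.f.sf(f, df1, df2))
    return float(f), df1, df2, float(min(p, 1.0))


def rank_candidate_drivers(
    records: pd.DataFrame, discordant_multiplier: float = 0.25
) -> pd.DataFrame:
    """Order TFs by a composite driver score.

    score = |activity_log2fc| * |mean_target_log2fc| * c, where c = 1
    when the two changes share a sign and ``discordant_multiplier``
    otherwise. This criterion is a declared artifact convention (the
    underlying study does not state one). Ties break by enrichment_p
    (ascending, missing last) then TF name.
    """
    if records.empty:
        raise ValueError("need at least one integration record")
    out = records.copy()
    concordant = (
        np.sign(out["activity_log2fc"]) == np.sign(out["mean_target_log2fc"])
    )
    multiplier = np.where(concordant, 1.0, discordant_multiplier)
    out["driver_score"] = (
        out["activity_log2fc"].abs()
        * out["mean_target_log2fc"].abs()
        * multiplier
    )
    if "enrichment_p" not in out.columns:
        out["enrichment_p"] = np.nan
    out = out.sort_values(
        by=["driver_score", "enrichment_p", "tf_id"],
        ascending=[False, True, True],
        na_position="last",
        kind="stable",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Pearson r with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise DegenerateDataError("zero variance in a correlation input")
    r = float((xc * yc).sum() / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(min(p, 1.0))


def activity_behavior_correlation(
    tfap: pd.DataFrame,
    si_rates: Mapping[str, float],
    tf_subset: Sequence[str],
    joint: bool = False,
) -> dict[str, tuple[float, float]]:
    """Pearson correlation of per-animal TF activity with SI-rate.

    Per-TF mode returns {tf: (r, p)} over animals measured for that
    TF. Joint mode regresses SI on all TFs in ``tf_subset`` over
    animals with complete measurements and returns
    {'joint': (multiple_R, F_p)}.
    """
    wide = tfap.pivot_table(
        index="animal_id", columns="tf_id", values="normalized_activity",
        aggfunc="mean",
    )
    si = pd.Series(dict(si_rates), dtype=float)
    if not joint:
        out: dict[str, tuple[float, float]] = {}
        for tf in tf_subset:
            col = wide[tf].dropna()
            animals = col.index.intersection(si.index)
            out[tf] = pearson_correlation(
                col.loc[animals].to_numpy(), si.loc[animals].to_numpy()
            )
        return out
    sub = wide[list(tf_subset)].dropna()
    animals = sub.index.intersection(si.index)
    x = sub.loc[animals].to_numpy(dtype=float)
    y = si.loc[animals].to_numpy(dtype=float)
    n, k = x.shape
    if n < k + 2:
        raise ValueError("too few complete animals for the joint model")
    design = np.column_stack([np.ones(n), x])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise DegenerateDataError("zero variance in SI-rates")
    r2 = 1.0 - ss_res / ss_tot
    r2 = max(0.0, min(1.0, r2))
    if r2 == 1.0:
        return {"joint": (1.0, 0.0)}
    f = (r2 / k) / ((1.0 - r2) / (n - k - 1))
    p = float(stats.f.sf(f, k, n - k - 1))
    return {"joint": (float(np.sqrt(r2)), p)}


def integrate(
    tfap_summary: pd.DataFrame,
    de_results: pd.DataFrame,
    regulon_map: RegulonMap,
    deg_classes: pd.Series | None = None,
    discordant_multiplier: float = 0.25,
) -> pd.DataFrame:
    """Full integration table: coupling + enrichment + shift + ranking."""
    records = tf_regulon_coupling(tfap_summary, de_results, regulon_map)
    universe = set(de_results.index.astype(str))
    if deg_classes is not None:
        deg_set = set(deg_classes.index[deg_classes != "none"].astype(str))
    else:
        deg_set = set()
    enrich = []
    shift = []
    for tf in records["tf_id"]:
        reg = {g for g in regulon_map.targets(tf) if g in universe}
        enrich.append(
            regulon_deg_enrichment(deg_set, reg, universe) if deg_set else np.nan
        )
        shift.append(regulon_shift_test(de_results["log2fc"], reg)[1])
    records["enrichment_p"] = enrich
    records["shift_p"] = shift
    return rank_candidate_drivers(records, discordant_multiplier)
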