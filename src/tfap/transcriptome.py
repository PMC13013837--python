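"""TPM normalization, differential expression and DEG calling.

Differential expression uses Welch's t test on log2(value +
pseudocount) per gene with Benjamini-Hochberg correction. DEGs are
called with the rule p < 0.05 and fold change > 2 or < 0.5; gating on
the BH q-value instead is configurable.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tfap._errors import DegenerateDataError
from tfap.activity import welch_t

DEG_P_THRESHOLD = 0.05
DEG_FC_UP = 2.0
DEG_FC_DOWN = 0.5


def counts_to_tpm(counts: pd.DataFrame, lengths_bp: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million from a genes x samples count matrix.

    Per sample: rate = count / length_kb; TPM = rate / sum(rate) * 1e6.
    """
    lengths = lengths_bp.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()]
        raise KeyError(f"genes without lengths: {list(missing)[:5]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    rate = counts.div(lengths / 1000.0, axis=0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        dead = totals.index[totals == 0]
        raise DegenerateDataError(f"all-zero samples: {list(dead)[:5]}")
    return rate.div(totals, axis=1) * 1e6


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, monotone and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce step-up monotonicity from the largest p downwards
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_expression(
    expr: pd.DataFrame,
    sample_groups: Mapping[str, str],
    group_a: str,
    group_b: str,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene DE of group_a vs group_b on a genes x samples matrix.

    log2fc = log2((meanA + ps) / (meanB + ps)) on the input scale;
    p from Welch's t on log2(value + ps); q from BH. Genes with zero
    variance in both groups are flagged (``degenerate``) with p = 1.
    """
    cols_a = [s for s in expr.columns if sample_groups.get(s) == group_a]
    cols_b = [s for s in expr.columns if sample_groups.get(s) == group_b]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {len(cols_a)} vs {len(cols_b)}"
        )
    a = expr[cols_a].to_numpy(dtype=float)
    b = expr[cols_b].to_numpy(dtype=float)
    log2fc = np.log2(a.mean(axis=1) + pseudocount) - np.log2(
        b.mean(axis=1) + pseudocount
    )
    log_a = np.log2(a + pseudocount)
    log_b = np.log2(b + pseudocount)
    p = np.ones(expr.shape[0])
    degenerate = np.zeros(expr.shape[0], dtype=bool)
    for i in range(expr.shape[0]):
        try:
            _, _, p[i] = welch_t(log_a[i], log_b[i])
        except DegenerateDataError:
            # no within-group variation: identical means carry no
            # evidence (p=1); different means are noiseless separation
            degenerate[i] = True
            p[i] = 1.0 if log_a[i].mean() == log_b[i].mean() else 0.0
    return pd.DataFrame(
        {
            "gene": expr.index,
            "log2fc": log2fc,
            "p_value": p,
            "q_value": bh_adjust(p),
            "degenerate": degenerate,
        }
    ).set_index("gene")


def call_degs(
    de_results: pd.DataFrame,
    p_thresh: float = DEG_P_THRESHOLD,
    fc_up: float = DEG_FC_UP,
    fc_down: float = DEG_FC_DOWN,
    use_q: bool = False,
) -> pd.Series:
    """Classify each gene as up / down / none.

    up iff p < p_thresh and FC > fc_up; down iff p < p_thresh and
    FC < fc_down (FC on the linear scale, 2**log2fc). ``use_q``
    gates on the BH q-value instead of the raw p.
    """
    p = de_results["q_value"] if use_q else de_results["p_value"]
    fc = 2.0 ** de_results["log2fc"]
    cls = pd.Series("none", index=de_results.index, name="deg_class")
    cls[(p < p_thresh) & (fc > fc_up)] = "up"
    cls[(p < p_thresh) & (fc < fc_down)] = "down"
    return cls


def scale_rows(
    expr: pd.DataFrame, genes: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-gene z-scores across samples (sample SD, ddof=1).

    Zero-variance genes are dropped with a warning.
    """
    sub = expr if genes is None else expr.loc[list(genes)]
    sd = sub.std(axis=1, ddof=1)
    dead = sd[sd == 0].index
    if len(dead) > 0:
        warnings.warn(
            f"dropping {len(dead)} constant gene(s) from scaling",
            stacklevel=2,
        )
        sub = sub.drop(index=dead)
        sd = sd.drop(index=dead)
    return sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
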