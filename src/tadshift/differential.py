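"""Differential boundary insulation between conditions, with FDR control.

Per boundary, insulation scores (log2 scale, approximately Gaussian) are
modelled with a Gaussian identity-link GLM ``score ~ condition``. The
condition coefficient Delta is the treated-minus-control shift; its
two-sided p-value comes from the coefficient t-statistic, which for a
two-group design is exactly the pooled two-sample t-test. A boundary is
classified condensate-sensitive ("HDS") when its Benjamini-Hochberg
q-value is below the threshold AND Delta > 0 — insulation weakening moves
a boundary's (negative) score up toward zero.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientReplicationError, InvalidParameterError

__all__ = [
    "boundary_shift_test",
    "boundary_shift_glm",
    "classify_boundaries",
    "differential_boundary_table",
    "overlap_timepoints",
]

HDS = "HDS"
UNAFFECTED = "unaffected"


def _condition_columns(sample_sheet: pd.DataFrame, condition: str) -> list[str]:
    cols = sample_sheet.loc[sample_sheet["condition"] == condition, "sample"].tolist()
    if len(cols) < 2:
        raise InsufficientReplicationError(
            f"condition {condition!r} has {len(cols)} replicate(s); >= 2 required"
        )
    return cols


def boundary_shift_test(
    scores: pd.DataFrame,
    control_cols: list[str],
    treated_cols: list[str],
) -> pd.DataFrame:
    """Vectorized per-boundary two-condition test.

    ``scores`` has one row per boundary and one column per sample. Returns
    a DataFrame with per-boundary group means, the effect ``delta``
    (treated - control), the t statistic, degrees of freedom and two-sided
    p-value. Rows with fewer than two finite replicates in either group, or
    zero pooled variance, get p = NaN and are excluded from FDR downstream.
    """
    if len(control_cols) < 2 or len(treated_cols) < 2:
        raise InsufficientReplicationError(
            "each condition needs >= 2 replicate columns"
        )
    a = scores[control_cols].to_numpy(dtype=float)
    b = scores[treated_cols].to_numpy(dtype=float)
    n1 = np.isfinite(a).sum(axis=1)
    n2 = np.isfinite(b).sum(axis=1)
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(a, axis=1)
        m2 = np.nanmean(b, axis=1)
        v1 = np.nanvar(a, axis=1, ddof=1)
        v2 = np.nanvar(b, axis=1, ddof=1)
        df = n1 + n2 - 2
        s2 = np.where(df > 0, ((n1 - 1) * v1 + (n2 - 1) * v2) / np.maximum(df, 1), np.nan)
        se = np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
        t = (m2 - m1) / se
        p = 2.0 * scipy.stats.t.sf(np.abs(t), np.maximum(df, 1))
    usable = (n1 >= 2) & (n2 >= 2) & np.isfinite(se) & (se > 0)
    t = np.where(usable, t, np.nan)
    p = np.where(usable, p, np.nan)
    return pd.DataFrame(
        {
            "mean_control": m1,
            "mean_treated": m2,
            "delta": m2 - m1,
            "t": t,
            "df": df,
            "p": p,
        },
        index=scores.index,
    )


def boundary_shift_glm(control: np.ndarray, treated: np.ndarray) -> tuple[float, float, float]:
    """Single-boundary Gaussian GLM ``score ~ condition`` (independent route).

    Returns (delta, t, p). Agrees with the pooled t-test of
    :func:`boundary_shift_test` on any two-group design; kept as the explicit
    model formulation and cross-check.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if len(control) < 2 or len(treated) < 2:
        raise InsufficientReplicationError("each condition needs >= 2 replicates")
    y = np.concatenate([control, treated])
    x = sm.add_constant(np.r_[np.zeros(len(control)), np.ones(len(treated))])
    res = sm.GLM(y, x, family=sm.families.Gaussian()).fit(use_t=True)
    return float(res.params[1]), float(res.tvalues[1]), float(res.pvalues[1])


def classify_boundaries(table: pd.DataFrame, q_threshold: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg correction and HDS classification.

    Boundaries with NaN p-values are excluded from the correction and left
    unclassified (class NaN). HDS requires q < ``q_threshold`` and
    delta > 0; everything else tested is "unaffected".
    """
    if not 0 < q_threshold < 1:
        raise InvalidParameterError(f"q_threshold must be in (0, 1), got {q_threshold}")
    out = table.copy()
    out["q"] = np.nan
    out["class"] = pd.Series(pd.NA, index=out.index, dtype="object")
    tested = out["p"].notna()
    if tested.any():
        _, q, _, _ = multipletests(out.loc[tested, "p"], method="fdr_bh")
        out.loc[tested, "q"] = q
        hds = tested & (out["q"] < q_threshold) & (out["delta"] > 0)
        out.loc[tested, "class"] = UNAFFECTED
        out.loc[hds, "class"] = HDS
    return out


def differential_boundary_table(
    scores: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    control: str,
    treated: str,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-shot differential analysis: test every boundary, then classify.

    ``sample_sheet`` must carry columns ``sample`` and ``condition``;
    score columns are looked up by sample name.
    """
    ctrl_cols = _condition_columns(sample_sheet, control)
    trt_cols = _condition_columns(sample_sheet, treated)
    table = boundary_shift_test(scores, ctrl_cols, trt_cols)
    for col in ("chrom", "bin", "midpoint"):
        if col in scores.columns:
            table.insert(0, col, scores[col])
    return classify_boundaries(table, q_threshold)


def class_counts(table: pd.DataFrame) -> dict[str, int]:
    return {
        "n_hds": int((table["class"] == HDS).sum()),
        "n_unaffected": int((table["class"] == UNAFFECTED).sum()),
        "n_untested": int(table["class"].isna().sum()),
    }


def overlap_timepoints(hds_sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Pairwise and higher-order intersection sizes of per-time-point HDS sets.

    Keys are tuples of time-point labels (singletons give set sizes);
    values are intersection cardinalities.
    """
    labels = list(hds_sets)
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for combo in itertools.combinations(labels, r):
            inter = set.intersection(*(hds_sets[c] for c in combo))
            out[combo] = len(inter)
    return out
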