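"""Differential statistics for metabolite peak-area tables.

Volcano-style analytics: per-feature log2 fold change of group means on the
log2 scale, two-tailed unpaired t tests, Benjamini-Hochberg adjustment, and
a hit flag at configurable q and fold-change thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidConfigError

__all__ = ["DifferentialResult", "bh_adjust", "group_differential"]

#: default thresholds for calling a hit
Q_MAX_DEFAULT = 0.015
LOG2FC_MIN_DEFAULT = 1.0


@dataclass
class DifferentialResult:
    """Per-feature differential outcome with the thresholds that produced it."""

    feature_id: str
    log2fc: float
    p: float
    q: float
    hit: bool
    testable: bool
    q_max: float = Q_MAX_DEFAULT
    log2fc_min: float = LOG2FC_MIN_DEFAULT


def bh_adjust(p: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped to [0, 1]; NaN inputs are
    left NaN and excluded from the multiplicity count m.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise InvalidConfigError("p must be one-dimensional")
    finite = ~np.isnan(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise InvalidConfigError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    pv = p[finite]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order]
    scaled = ranked * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    q[finite] = out
    return q


def _student_t(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided pooled-variance (Student) t-test p-value; NaN if untestable."""
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        return float("nan")
    sa2 = a.var(ddof=1)
    sb2 = b.var(ddof=1)
    if sa2 == 0.0 and sb2 == 0.0:
        return float("nan")
    df = na + nb - 2
    sp2 = ((na - 1) * sa2 + (nb - 1) * sb2) / df
    t = (b.mean() - a.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return float(2.0 * stats.t.sf(abs(t), df))


def group_differential(
    table: pd.DataFrame,
    pair: tuple[str, str],
    q_max: float = Q_MAX_DEFAULT,
    log2fc_min: float = LOG2FC_MIN_DEFAULT,
    feature_col: str = "metabolite",
    group_col: str = "group",
    value_col: str = "area",
) -> list[DifferentialResult]:
    """Volcano statistics for every feature comparing group B against group A.

    Peak areas are log2-transformed; log2fc is mean(log2 B) - mean(log2 A)
    (the log2 ratio of group geometric means); p is a two-tailed unpaired
    Student t on the log2 values; q is BH across all testable features.
    Features with <2 replicates in a group, or zero variance in both groups,
    are flagged not-testable and carry NaN p/q.
    """
    a_label, b_label = pair
    for label in pair:
        if label not in set(table[group_col]):
            raise InvalidConfigError(f"group {label!r} absent from table")
    if (table[value_col].dropna() <= 0).any():
        raise InvalidConfigError("peak areas must be positive")

    feats, fcs, ps = [], [], []
    for feat, sub in table.groupby(feature_col, sort=True):
        a = np.log2(sub.loc[sub[group_col] == a_label, value_col].dropna().to_numpy(float))
        b = np.log2(sub.loc[sub[group_col] == b_label, value_col].dropna().to_numpy(float))
        fc = float(b.mean() - a.mean()) if a.size and b.size else float("nan")
        feats.append(str(feat))
        fcs.append(fc)
        ps.append(_student_t(a, b))
    qs = bh_adjust(ps)

    results = []
    for feat, fc, p, q in zip(feats, fcs, ps, qs):
        testable = not np.isnan(p)
        hit = bool(testable and q < q_max and abs(fc) > log2fc_min)
        results.append(
            DifferentialResult(
                feature_id=feat,
                log2fc=fc,
                p=p,
                q=float(q),
                hit=hit,
                testable=testable,
                q_max=q_max,
                log2fc_min=log2fc_min,
            )
        )
    return results
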