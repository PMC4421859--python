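"""Spearman and body-mass-controlled partial Spearman rank correlation.

These are the workhorse statistics of the whole analysis and are written
from first principles: values are replaced by mid-ranks (average ranks for
ties), the Spearman coefficient r_s is the Pearson correlation of the two
rank vectors, and the first-order partial coefficient controlling for a
third variable z is

    r_xy.z = (r_xy − r_xz r_yz) / sqrt((1 − r_xz²)(1 − r_yz²)).

Two-sided p-values use the t approximation, t = r sqrt((n − 2 − k)/(1 − r²))
on n − 2 − k degrees of freedom with k controlling variables; for the simple
coefficient at n ≤ 8 the exact permutation distribution over all n!
pairings is used instead.  p-values below 2.2e-16 are *printed* as
"< 2.2e-16" but stored as the computed float.

The module also provides the category screen — simple and mass-controlled
correlations of every functional-category proportion against mass-specific
metabolic rate, retained at p < alpha and ranked by partial coefficient —
and subgroup (e.g. volant / non-volant) partial correlations.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("oxilink.rank_stats")

#: smallest p-value printed numerically in text reports
P_REPORT_FLOOR = 2.2e-16

#: largest n for which the simple-Spearman p is computed by exact permutation
EXACT_PERMUTATION_MAX_N = 8


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    controlled: tuple[str, ...] = ()
    method: str = "spearman"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError(f"correlation {self.r} outside [-1, 1]")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p < 0.05

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "p": self.p,
            "n": self.n,
            "controlled": list(self.controlled),
            "method": self.method,
        }


@dataclass
class ScreenRow:
    category: str
    simple: CorrelationResult
    partial: CorrelationResult
    q_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "simple": self.simple.to_dict(),
            "partial": self.partial.to_dict(),
            "q_value": self.q_value,
        }


def format_p(p: float) -> str:
    """Text rendering of a p-value, flooring at the reporting convention."""
    if p < P_REPORT_FLOOR:
        return f"< {P_REPORT_FLOOR:.1e}"
    return f"{p:.3g}"


# ---------------------------------------------------------------------------
# rank machinery


def rank_transform(values: Sequence[float]) -> np.ndarray:
    """Mid-ranks 1..n, ties receiving the average of their positions."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise ValueError("need a non-empty 1-D vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite entries cannot be ranked")
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(v.size, dtype=float)
    sv = v[order]
    i = 0
    while i < v.size:
        j = i
        while j < v.size and sv[j] == sv[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j + 1)  # average of 1-based positions i+1..j
        i = j
    return ranks


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    ac = a - a.mean()
    bc = b - b.mean()
    denom = np.sqrt((ac @ ac) * (bc @ bc))
    if denom == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.clip((ac @ bc) / denom, -1.0, 1.0))


def _t_pvalue(r: float, df: int) -> float:
    if df < 1:
        raise ValueError("not enough degrees of freedom")
    if 1.0 - r * r <= 0.0:
        return 0.0  # |r| = 1: below any floating-point floor
    t = abs(r) * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * sps.t.sf(t, df))


def _exact_permutation_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """Two-sided p over all n! pairings of the rank vectors."""
    n = rx.size
    perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    cy = ry - ry.mean()
    cx = rx - rx.mean()
    norm = np.sqrt((cx @ cx) * (cy @ cy))
    r_all = (cx[perms] @ cy) / norm
    return float(np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12))


# ---------------------------------------------------------------------------
# coefficients


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    For n ≤ 8 the p-value is exact (all n! pairings); otherwise the usual
    t approximation on n − 2 degrees of freedom is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = rank_transform(x), rank_transform(y)
    r = _pearson(rx, ry)
    if n <= EXACT_PERMUTATION_MAX_N:
        p = _exact_permutation_p(rx, ry, r)
    else:
        p = _t_pvalue(r, n - 2)
    return CorrelationResult(r=r, p=p, n=n, method="spearman")


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    z: Sequence[float],
    control_name: str = "control",
) -> CorrelationResult:
    """First-order partial Spearman correlation of x and y controlling z."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("x, y, z must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations for a first-order partial")
    rx, ry, rz = rank_transform(x), rank_transform(y), rank_transform(z)
    r_xy, r_xz, r_yz = _pearson(rx, ry), _pearson(rx, rz), _pearson(ry, rz)
    if abs(r_xz) >= 1.0 or abs(r_yz) >= 1.0:
        raise ValueError("controller is rank-degenerate with a variable (|r| = 1)")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    r = float(np.clip(r, -1.0, 1.0))
    p = _t_pvalue(r, n - 3)
    return CorrelationResult(
        r=r, p=p, n=n, controlled=(control_name,), method="partial_spearman"
    )


# ---------------------------------------------------------------------------
# the category screen


def correlation_screen(
    profile_matrix: pd.DataFrame,
    q: Sequence[float],
    mass: Sequence[float],
    alpha: float = 0.05,
    keep_all: bool = False,
) -> list[ScreenRow]:
    """Screen every functional-category proportion against the rate q.

    For each category column (including the oxic pseudo-category) the simple
    Spearman correlation with q and the body-mass-controlled partial are
    computed on the same organisms.  Constant categories are dropped with a
    warning.  Rows with partial p < ``alpha`` are retained and sorted by
    partial coefficient, descending; Benjamini–Hochberg q-values over all
    tested categories are attached for reference (the primary screen uses
    raw p-values).  ``keep_all=True`` returns every tested row instead.
    """
    q = np.asarray(q, dtype=float)
    mass = np.asarray(mass, dtype=float)
    if len(profile_matrix) != q.size or q.size != mass.size:
        raise ValueError("profile matrix, q and mass must be row-aligned")
    if q.size < 4:
        raise ValueError("need at least 4 organisms for the screen")

    rows: list[ScreenRow] = []
    for category in profile_matrix.columns:
        values = profile_matrix[category].to_numpy(dtype=float)
        if np.ptp(values) == 0.0:
            logger.warning("category %r constant across organisms; dropped", category)
            continue
        try:
            rows.append(
                ScreenRow(
                    category=str(category),
                    simple=spearman(values, q),
                    partial=partial_spearman(values, q, mass, control_name="body_mass"),
                )
            )
        except ValueError as exc:  # rank-degenerate at tiny n
            logger.warning("category %r dropped from screen: %s", category, exc)
    if rows:
        qvals = multipletests([r.partial.p for r in rows], method="fdr_bh")[1]
        for row, qv in zip(rows, qvals):
            row.q_value = float(qv)
    rows.sort(key=lambda row: row.partial.r, reverse=True)
    if keep_all:
        return rows
    return [row for row in rows if row.partial.p < alpha]


def screen_to_frame(rows: Sequence[ScreenRow]) -> pd.DataFrame:
    """Machine-readable screen table (the Table-1 analogue)."""
    return pd.DataFrame(
        [
            {
                "category": row.category,
                "r_s": row.simple.r,
                "p": row.simple.p,
                "r_s_partial": row.partial.r,
                "p_partial": row.partial.p,
                "q_value_bh": row.q_value,
                "n": row.partial.n,
            }
            for row in rows
        ]
    )


def subgroup_partial(
    frame: pd.DataFrame,
    x_name: str,
    y_name: str,
    control_name: str,
    group_by: str,
    min_n: int = 4,
) -> dict[object, CorrelationResult]:
    """Mass-controlled partial correlation within each level of a trait flag.

    Groups with fewer than ``min_n`` complete rows are skipped with a
    warning.  Grouping on a constant flag therefore reduces to the ungrouped
    analysis under a single key.
    """
    needed = [x_name, y_name, control_name]
    results: dict[object, CorrelationResult] = {}
    for level, sub in frame.groupby(group_by, dropna=True):
        sub = sub.dropna(subset=needed)
        if len(sub) < min_n:
            logger.warning(
                "group %s=%r has n=%d < %d; skipped", group_by, level, len(sub), min_n
            )
            continue
        results[level] = partial_spearman(
            sub[x_name], sub[y_name], sub[control_name], control_name=control_name
        )
    return results
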