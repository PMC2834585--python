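"""Pairwise correlations among adherence measures.

Continuous-continuous pairs use the Pearson product-moment coefficient;
any pair involving a binary measure uses Kendall's tau-b (tie-corrected
rank correlation — with binary data the tie correction is what keeps the
coefficient on the [-1, 1] scale).  Each cell is estimated on the
pairwise-complete observations, so the n varies across cells: self-report
pairs drop patients recorded on the two-level coding, and schedule-based
timeliness pairs drop patients with no recorded scheduled dates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MeasureSpec",
    "CorrelationCell",
    "pearson_r",
    "kendall_tau",
    "correlation_matrix",
    "default_measure_specs",
]


@dataclass(frozen=True)
class MeasureSpec:
    """One measure entering the correlation matrix.

    ``extract`` maps a snapshot table (one row per patient) to a numeric
    Series; missing values mark patients for whom the measure is not
    available.
    """

    name: str
    kind: str  # "continuous" | "binary"
    extract: Callable[[pd.DataFrame], pd.Series]

    def __post_init__(self):
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"kind must be continuous or binary, got {self.kind!r}")


@dataclass(frozen=True)
class CorrelationCell:
    measure_x: str
    measure_y: str
    coefficient: float | None
    p_value: float | None
    n: int
    method: str  # "pearson" | "kendall"
    reason: str | None = None


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(pd.to_numeric(pd.Series(x), errors="coerce"), dtype=float)
    y = np.asarray(pd.to_numeric(pd.Series(y), errors="coerce"), dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    mask = ~(np.isnan(x) | np.isnan(y))
    return x[mask], y[mask]


def pearson_r(x, y, names: tuple[str, str] = ("x", "y")) -> CorrelationCell:
    """Pearson product-moment correlation on pairwise-complete pairs."""
    xs, ys = _pairwise_complete(x, y)
    n = len(xs)
    if n < 3:
        return CorrelationCell(*names, None, None, n, "pearson", "fewer than 3 pairs")
    if np.std(xs) == 0 or np.std(ys) == 0:
        return CorrelationCell(*names, None, None, n, "pearson", "zero variance")
    r, p = stats.pearsonr(xs, ys)
    return CorrelationCell(*names, float(r), float(p), n, "pearson")


def kendall_tau(
    x, y, names: tuple[str, str] = ("x", "y"),
    exact: bool = False, seed: int = 0,
) -> CorrelationCell:
    """Kendall tau-b rank correlation on pairwise-complete pairs.

    The default p-value is the asymptotic normal approximation.  With
    ``exact=True`` and n <= 12, a small-sample p-value is computed: the
    exact tau null distribution when there are no ties, otherwise a seeded
    Monte-Carlo permutation test (20,000 permutations).
    """
    xs, ys = _pairwise_complete(x, y)
    n = len(xs)
    if n < 3:
        return CorrelationCell(*names, None, None, n, "kendall", "fewer than 3 pairs")
    if np.all(xs == xs[0]) or np.all(ys == ys[0]):
        return CorrelationCell(*names, None, None, n, "kendall", "all observations tied")

    has_ties = len(np.unique(xs)) < n or len(np.unique(ys)) < n
    if exact and n <= 12 and not has_ties:
        res = stats.kendalltau(xs, ys, method="exact")
        return CorrelationCell(*names, float(res.statistic), float(res.pvalue), n, "kendall")
    res = stats.kendalltau(xs, ys, method="asymptotic")
    tau, p = float(res.statistic), float(res.pvalue)
    if exact and n <= 12 and has_ties:
        rng = np.random.default_rng(seed)
        obs = abs(tau)
        hits = 0
        nperm = 20_000
        for _ in range(nperm):
            t = stats.kendalltau(xs, rng.permutation(ys)).statistic
            if abs(t) >= obs - 1e-12:
                hits += 1
        p = (hits + 1) / (nperm + 1)
    return CorrelationCell(*names, tau, p, n, "kendall")


def correlation_matrix(
    snapshots: pd.DataFrame, specs: Sequence[MeasureSpec] | None = None
) -> pd.DataFrame:
    """Upper-triangular matrix of pairwise correlations among measures.

    Returns a tidy frame with one row per ordered pair (i < j): measure
    names, method (pearson iff both continuous, else kendall), coefficient,
    p-value, pairwise-complete n, and a reason when unestimable.
    """
    if specs is None:
        specs = default_measure_specs()
    series = {s.name: s.extract(snapshots) for s in specs}
    rows = []
    for i, sx in enumerate(specs):
        for sy in specs[i + 1:]:
            names = (sx.name, sy.name)
            if sx.kind == "continuous" and sy.kind == "continuous":
                cell = pearson_r(series[sx.name], series[sy.name], names)
            else:
                cell = kendall_tau(series[sx.name], series[sy.name], names)
            rows.append(cell.__dict__)
    return pd.DataFrame(rows)


def _num(col: str) -> Callable[[pd.DataFrame], pd.Series]:
    return lambda df: pd.to_numeric(df[col], errors="coerce")


def _thresh(col: str, cut: float) -> Callable[[pd.DataFrame], pd.Series]:
    def f(df: pd.DataFrame) -> pd.Series:
        v = pd.to_numeric(df[col], errors="coerce")
        return (v > cut).astype(float).where(v.notna())
    return f


def _bool(col: str) -> Callable[[pd.DataFrame], pd.Series]:
    def f(df: pd.DataFrame) -> pd.Series:
        v = df[col]
        return v.map(lambda b: np.nan if b is None or (isinstance(b, float) and np.isnan(b)) else float(bool(b)))
    return f


def default_measure_specs() -> list[MeasureSpec]:
    """The nine measures of the standard correlation table.

    Expects a snapshot table as produced by
    :func:`adhkit.indicators.snapshot_table`.
    """
    return [
        MeasureSpec("pct_days_covered", "continuous", _num("pct_days_covered")),
        MeasureSpec("coverage_gt80", "binary", _thresh("pct_days_covered", 80.0)),
        MeasureSpec("coverage_gt95", "binary", _thresh("pct_days_covered", 95.0)),
        MeasureSpec("gap_gt30", "binary", _bool("gap_gt30")),
        MeasureSpec("avg_selfreport", "continuous", _num("avg_selfreport")),
        MeasureSpec("any_imperfect_selfreport", "binary", _bool("any_imperfect_selfreport")),
        MeasureSpec("pct_visits_on_or_before", "continuous", _num("pct_visits_on_or_before")),
        MeasureSpec("pct_visits_within_3d", "continuous", _num("pct_visits_within_3d")),
        MeasureSpec("pct_visits_before_exhaustion", "continuous", _num("pct_visits_before_exhaustion")),
    ]
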