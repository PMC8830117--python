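"""Weighted fractional ranks, concentration indices and concentration curves.

The concentration index of a health variable :math:`y` over a socioeconomic
ranking is

.. math:: C = \\frac{2}{\\mu} \\, \\mathrm{cov}_w(y_i, R_i)

where :math:`R_i` is the weighted fractional rank of record *i* in the
wealth distribution, :math:`\\mu` the weighted mean of :math:`y`, and
:math:`\\mathrm{cov}_w` the *population* (not n-1) weighted covariance.  A
positive index means the outcome is concentrated among the better-off
(pro-rich inequality); the index is also exactly twice the area between the
concentration curve and the diagonal of equality, which this module exposes
as an independent oracle (:func:`ci_from_curve`).

Ranks follow the Lerman–Yitzhaki midpoint construction: with weights
normalised to sum to one and records sorted by the ranking score,
:math:`R_i = \\sum_{j<i} \\tilde w_j + \\tilde w_i / 2`.  Tied scores share
the weighted midpoint of their tied block, which makes the index invariant
to within-tie record order.  The weighted mean of the ranks is exactly 1/2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .survey import DataError, DomainError, SurveyTable, derive_indicators

logger = logging.getLogger("healthineq.ranking")

__all__ = [
    "RankedOutcome",
    "ConcentrationCurve",
    "ConcentrationResult",
    "weighted_mean",
    "weighted_cov",
    "fractional_rank",
    "weighted_quintiles",
    "concentration_index",
    "concentration_curve",
    "ci_from_curve",
    "ci_by_group",
    "ranks_for_table",
]

#: admissible ranking bases: the continuous wealth score, or tied midpoint
#: ranks per wealth quintile (the grouped variant)
RANKING_BASES = ("continuous_score", "quintile_groups")


def weighted_mean(x, w) -> float:
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    return float(np.sum(w * x) / np.sum(w))


def weighted_cov(x, y, w) -> float:
    """Population-form weighted covariance Σ w̃_i (x_i - x̄)(y_i - ȳ).

    The population form (normalised weights, no n-1 correction) is what makes
    the decomposition identity exact.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    wn = w / np.sum(w)
    xb = np.sum(wn * x)
    yb = np.sum(wn * y)
    return float(np.sum(wn * (x - xb) * (y - yb)))


@dataclass
class RankedOutcome:
    """Outcome values aligned with their fractional ranks and weights."""

    y: np.ndarray
    R: np.ndarray
    w: np.ndarray
    mu: float


@dataclass
class ConcentrationCurve:
    """Piecewise-linear concentration curve.

    ``p`` is the cumulative weighted population share (poorest first) and
    ``L`` the cumulative weighted outcome share; both start at 0 and end
    at 1.  Tied ranking scores are merged into a single point.
    """

    p: np.ndarray
    L: np.ndarray


@dataclass
class ConcentrationResult:
    """A concentration index together with the curve it summarises."""

    index: float
    mu: float
    n: int
    curve: ConcentrationCurve
    ranking_basis: str = "continuous_score"


def _check_weights(w: np.ndarray) -> None:
    if np.any(~np.isfinite(w)) or np.any(w <= 0):
        raise DomainError("weights must be positive and finite")


def fractional_rank(scores, weights) -> np.ndarray:
    """Weighted fractional ranks (Lerman–Yitzhaki midpoints), original order.

    Records are ranked by ``scores`` ascending; each record receives the
    midpoint of its own slice of the weight-normalised cumulative
    distribution, and a block of tied scores shares the midpoint of the whole
    block.  The weighted mean of the returned ranks is 1/2.
    """
    s = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s.shape != w.shape:
        raise DomainError("scores and weights must have equal length")
    _check_weights(w)

    order = np.argsort(s, kind="stable")
    wn = w[order] / np.sum(w)

    # tied blocks share the weighted midpoint of the whole block
    s_sorted = s[order]
    block_start = np.concatenate(([True], s_sorted[1:] != s_sorted[:-1]))
    block_id = np.cumsum(block_start) - 1
    block_w = np.bincount(block_id, weights=wn)
    block_end = np.cumsum(block_w)
    block_mid = block_end - block_w / 2.0

    ranks = np.empty_like(s)
    ranks[order] = block_mid[block_id]
    return ranks


def weighted_quintiles(scores, weights) -> np.ndarray:
    """Assign wealth quintiles 1..5 holding ~20% of total weight each.

    Assignment is monotone in the score and each tied block of scores is
    kept in a single quintile (the one containing the block's lower
    cumulative-weight edge).  With fewer than five distinct scores the split
    is degenerate and a warning is logged.
    """
    s = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if s.shape != w.shape:
        raise DomainError("scores and weights must have equal length")
    _check_weights(w)

    if np.unique(s).size < 5:
        logger.warning("fewer than 5 distinct wealth scores; quintile split is degenerate")

    order = np.argsort(s, kind="stable")
    wn = w[order] / np.sum(w)

    # a tied block is assigned by the cumulative weight before the block
    s_sorted = s[order]
    block_start = np.concatenate(([True], s_sorted[1:] != s_sorted[:-1]))
    block_id = np.cumsum(block_start) - 1
    block_w = np.bincount(block_id, weights=wn)
    block_edge = np.cumsum(block_w) - block_w

    edges = np.round(block_edge[block_id], 12)
    q_sorted = np.searchsorted([0.2, 0.4, 0.6, 0.8], edges, side="right") + 1
    q = np.empty(s.size, dtype=int)
    q[order] = q_sorted
    return q


def _curve_from_ranked(y: np.ndarray, key: np.ndarray, w: np.ndarray) -> ConcentrationCurve:
    """Cumulative-share curve over records sorted by ``key``; ties merged."""
    order = np.argsort(key, kind="stable")
    ys, ks, ws = y[order], key[order], w[order]
    wn = ws / np.sum(ws)
    shares = wn * ys
    total = np.sum(shares)
    cum_p = np.cumsum(wn)
    cum_L = np.cumsum(shares) / total
    keep = np.concatenate((ks[1:] != ks[:-1], [True]))  # last point of each tied block
    p = np.concatenate(([0.0], cum_p[keep]))
    L = np.concatenate(([0.0], cum_L[keep]))
    p[-1] = 1.0
    L[-1] = 1.0
    return ConcentrationCurve(p=p, L=L)


def concentration_index(y, ranks, weights,
                        ranking_basis: str = "continuous_score") -> ConcentrationResult:
    """Concentration index C = (2/μ) cov_w(y, R) with its curve.

    Requires μ > 0; a constant outcome gives C = 0 exactly.  For a binary
    outcome with equal weights, |C| ≤ 1 - μ + 1/n.
    """
    y = np.asarray(y, dtype=float)
    R = np.asarray(ranks, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (y.shape == R.shape == w.shape):
        raise DataError("y, ranks and weights must have equal length")
    _check_weights(w)
    mu = weighted_mean(y, w)
    if mu <= 0:
        raise DataError("concentration index undefined: weighted mean of outcome is not positive")
    c = 2.0 / mu * weighted_cov(y, R, w)
    curve = _curve_from_ranked(y, R, w)
    return ConcentrationResult(index=c, mu=mu, n=y.size, curve=curve,
                               ranking_basis=ranking_basis)


def concentration_curve(y, scores, weights) -> ConcentrationCurve:
    """Concentration curve: cumulative outcome share vs population share.

    Records are sorted poorest to richest by ``scores``; tied scores are
    merged into one point.  The curve is anchored at (0,0) and (1,1).
    """
    y = np.asarray(y, dtype=float)
    s = np.asarray(scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (y.shape == s.shape == w.shape):
        raise DataError("y, scores and weights must have equal length")
    _check_weights(w)
    if weighted_mean(y, w) <= 0:
        raise DataError("concentration curve undefined: weighted mean of outcome is not positive")
    return _curve_from_ranked(y, s, w)


def ci_from_curve(curve: ConcentrationCurve) -> float:
    """Index from the curve: twice the area between curve and diagonal.

    Exact trapezoid integration of the piecewise-linear curve,
    ``2 ∫ (p - L(p)) dp = 1 - 2 ∫ L dp``.  Serves as the independent oracle
    for :func:`concentration_index`: on distinct ranking scores the two agree
    to floating-point precision.
    """
    p, L = np.asarray(curve.p, float), np.asarray(curve.L, float)
    if p.size < 2 or p[0] != 0.0 or abs(p[-1] - 1.0) > 1e-12 or np.any(np.diff(p) < 0):
        raise DataError("curve must be anchored at p=0..1 and nondecreasing in p")
    if abs(L[0]) > 1e-12 or abs(L[-1] - 1.0) > 1e-9:
        raise DataError("curve must run from L=0 to L=1")
    area_under = np.trapezoid(L, p)
    return float(1.0 - 2.0 * area_under)


def ranks_for_table(table: SurveyTable,
                    ranking_basis: str = "continuous_score") -> np.ndarray:
    """Fractional ranks for a survey table under the chosen ranking basis.

    ``continuous_score`` ranks on the continuous wealth score;
    ``quintile_groups`` gives every member of a wealth quintile the tied
    midpoint rank of that quintile (the grouped construction implied by
    splitting the wealth index into five equal quintiles).
    """
    if ranking_basis not in RANKING_BASES:
        raise DomainError(f"unknown ranking basis {ranking_basis!r}; use one of {RANKING_BASES}")
    df = table.data
    w = df["weight"].to_numpy(float)
    if ranking_basis == "continuous_score":
        return fractional_rank(df["wealth_score"].to_numpy(float), w)
    return fractional_rank(df["wealth_quintile"].to_numpy(float), w)


def ci_by_group(table: SurveyTable, outcome: str, group: str,
                min_n: int = 250,
                ranking_basis: str = "continuous_score") -> dict[str, ConcentrationResult]:
    """Concentration indices within each level of a grouping column.

    Ranks are recomputed *within* each group, so each index reflects the
    group's own wealth distribution (e.g. state-specific rankings).  Groups
    with fewer than ``min_n`` records are skipped with a log entry, mirroring
    the exclusion of small-sample strata from published state comparisons.
    """
    df = table.data
    if outcome not in df.columns:
        df = derive_indicators(table).data
    if outcome not in df.columns:
        raise DataError(f"unknown outcome column: {outcome}")
    if group not in df.columns:
        raise DataError(f"unknown group column: {group}")

    out: dict[str, ConcentrationResult] = {}
    for level, sub in df.groupby(group, sort=True, observed=True):
        if len(sub) < min_n:
            logger.info("group %s=%s skipped: n=%d < %d", group, level, len(sub), min_n)
            continue
        sub_table = SurveyTable(sub.reset_index(drop=True), provenance=table.provenance)
        ranks = ranks_for_table(sub_table, ranking_basis)
        out[str(level)] = concentration_index(
            sub[outcome].to_numpy(float), ranks,
            sub["weight"].to_numpy(float), ranking_basis=ranking_basis)
    if not out:
        raise DataError(f"no level of {group!r} meets the minimum sample size {min_n}")
    return out
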