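"""Single change-point detectors for mean, variance, and linear trend.

Each detector scans every admissible split of the signal into two segments,
fits the segment model (constant / constant-variance Gaussian / straight
line), and reports the split with the lowest total cost. The reported day
is the first day of the new regime (1-based). The score is the cost
reduction against the one-segment fit; a (near-)zero score marks a
degenerate detection (e.g. a constant signal), which downstream pooling
counts as evidence of absence of change.

Confidence is a permutation bootstrap: the share of value-shuffled
surrogates whose best score stays strictly below the observed one.

The exhaustive split scan *is* the definition here; everything is
implemented over batches of signals (rows of a matrix) because surrogate
testing upstream evaluates thousands of shuffled copies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .errors import SeriesError

__all__ = [
    "ChangePoint",
    "cp_mean",
    "cp_variance",
    "cp_trend",
    "cp_confidence",
    "attach_confidence",
    "matrix_cp",
]

Kind = Literal["mean", "variance", "trend", "dc_mean", "rp_lines", "tfd_lines"]

#: guard added to segment variances before taking logs
_VAR_GUARD = 1e-9
#: scores at or below (relative) this are treated as "no change found"
_DEGENERATE_RTOL = 1e-9


@dataclass(frozen=True)
class ChangePoint:
    """A located change: its kind, day (first day of the new regime),
    bootstrap/line confidence, cost-reduction score, degeneracy flag."""

    kind: str
    day: int
    confidence: float
    score: float
    degenerate: bool = False


def _as_batch(signal: np.ndarray, min_n: int) -> np.ndarray:
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    if np.isnan(x).any():
        raise SeriesError("signal contains NaN; strip undefined values first")
    if x.shape[1] < min_n:
        raise SeriesError(f"signal needs at least {min_n} points, got {x.shape[1]}")
    return x


def _best_split_mean(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched two-constant-segment scan. Returns (day, score) per row."""
    b, n = x.shape
    s1 = np.concatenate([np.zeros((b, 1)), np.cumsum(x, axis=1)], axis=1)
    s2 = np.concatenate([np.zeros((b, 1)), np.cumsum(x * x, axis=1)], axis=1)
    k = np.arange(1, n)  # left segment length; split before index k
    sse_l = s2[:, k] - s1[:, k] ** 2 / k
    sse_r = (s2[:, [n]] - s2[:, k]) - (s1[:, [n]] - s1[:, k]) ** 2 / (n - k)
    total = sse_l + sse_r
    sse_one = s2[:, n] - s1[:, n] ** 2 / n
    best = np.argmin(total, axis=1)  # first minimum -> earliest day
    return k[best] + 1, sse_one - total[np.arange(b), best]


def _best_split_variance(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched two-segment Gaussian-variance scan (segments of length >= 2)."""
    b, n = x.shape
    s1 = np.concatenate([np.zeros((b, 1)), np.cumsum(x, axis=1)], axis=1)
    s2 = np.concatenate([np.zeros((b, 1)), np.cumsum(x * x, axis=1)], axis=1)
    k = np.arange(2, n - 1)
    var_l = np.maximum(s2[:, k] / k - (s1[:, k] / k) ** 2, 0.0)
    len_r = n - k
    var_r = np.maximum(
        (s2[:, [n]] - s2[:, k]) / len_r - ((s1[:, [n]] - s1[:, k]) / len_r) ** 2, 0.0
    )
    cost = k * np.log(var_l + _VAR_GUARD) + len_r * np.log(var_r + _VAR_GUARD)
    var_one = np.maximum(s2[:, n] / n - (s1[:, n] / n) ** 2, 0.0)
    cost_one = n * np.log(var_one + _VAR_GUARD)
    best = np.argmin(cost, axis=1)
    return k[best] + 1, cost_one - cost[np.arange(b), best]


def _best_split_trend(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched two-line scan (segments of length >= 3)."""
    b, n = x.shape
    t = np.arange(n, dtype=float)
    s1 = np.concatenate([np.zeros((b, 1)), np.cumsum(x, axis=1)], axis=1)
    s2 = np.concatenate([np.zeros((b, 1)), np.cumsum(x * x, axis=1)], axis=1)
    st = np.concatenate([[0.0], np.cumsum(t)])
    st2 = np.concatenate([[0.0], np.cumsum(t * t)])
    sty = np.concatenate([np.zeros((b, 1)), np.cumsum(x * t, axis=1)], axis=1)
    ks = np.arange(3, n - 2)
    # left segments [0, k), right segments [k, n), vectorized over k
    sse_left = _sse_lines(s1, s2, st, st2, sty, 0, ks, b)
    sse_right = _sse_lines_right(s1, s2, st, st2, sty, ks, n, b)
    total = sse_left + sse_right
    sse_one = _sse_lines(s1, s2, st, st2, sty, 0, np.array([n]), b)[:, 0]
    best = np.argmin(total, axis=1)
    return ks[best] + 1, sse_one - total[np.arange(b), best]


def _sse_lines(s1, s2, st, st2, sty, a: int, stops: np.ndarray, b: int) -> np.ndarray:
    length = stops - a  # (K,)
    sy = s1[:, stops] - s1[:, a : a + 1]
    syy = s2[:, stops] - s2[:, a : a + 1]
    t1 = st[stops] - st[a]
    t2 = st2[stops] - st2[a]
    ty = sty[:, stops] - sty[:, a : a + 1]
    stt_c = t2 - t1 * t1 / length
    sty_c = ty - t1[None, :] * sy / length[None, :]
    syy_c = syy - sy * sy / length[None, :]
    return np.maximum(syy_c - sty_c**2 / stt_c[None, :], 0.0)


def _sse_lines_right(s1, s2, st, st2, sty, starts: np.ndarray, n: int, b: int):
    length = n - starts
    sy = s1[:, [n]] - s1[:, starts]
    syy = s2[:, [n]] - s2[:, starts]
    t1 = st[n] - st[starts]
    t2 = st2[n] - st2[starts]
    ty = sty[:, [n]] - sty[:, starts]
    stt_c = t2 - t1 * t1 / length
    sty_c = ty - t1[None, :] * sy / length[None, :]
    syy_c = syy - sy * sy / length[None, :]
    return np.maximum(syy_c - sty_c**2 / stt_c[None, :], 0.0)


_SCANNERS = {
    "mean": (_best_split_mean, 4),
    "variance": (_best_split_variance, 6),
    "trend": (_best_split_trend, 6),
}


def _scan(signal, kind_key: str, kind_label: str) -> ChangePoint:
    scanner, min_n = _SCANNERS[kind_key]
    x = _as_batch(signal, min_n)
    if x.shape[0] != 1:
        raise ValueError("pass a single signal; batches are internal")
    day, score = scanner(x)
    score_f = float(score[0])
    baseline = max(1.0, float(np.ptp(x)) ** 2)
    degenerate = bool(np.ptp(x) == 0.0 or score_f <= _DEGENERATE_RTOL * baseline)
    return ChangePoint(
        kind=kind_label,
        day=2 if degenerate and np.ptp(x) == 0.0 else int(day[0]),
        confidence=0.0,
        score=max(score_f, 0.0),
        degenerate=degenerate,
    )


def cp_mean(signal, kind: str = "mean") -> ChangePoint:
    """Best single change in mean (two-constant-segment least squares)."""
    return _scan(signal, "mean", kind)


def cp_variance(signal) -> ChangePoint:
    """Best single change in variance (two-segment Gaussian log-variance cost)."""
    return _scan(signal, "variance", "variance")


def cp_trend(signal) -> ChangePoint:
    """Best single change in linear trend (two independent line fits)."""
    return _scan(signal, "trend", "trend")


def cp_confidence(
    signal,
    point: ChangePoint,
    n_boot: int = 500,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation-bootstrap confidence of a detected change point.

    Confidence = (number of value-permuted surrogates whose best score is
    strictly below the observed score) / (n_boot + 1); the add-one
    denominator keeps it off the boundaries. Degenerate points get 0.
    """
    if point.degenerate:
        return 0.0
    kind_key = {"dc_mean": "mean", "rp_lines": "mean", "tfd_lines": "mean"}.get(
        point.kind, point.kind
    )
    scanner, min_n = _SCANNERS[kind_key]
    x = _as_batch(signal, min_n)[0]
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    # n_boot independent permutations in one shot
    perms = x[np.argsort(rng.random((n_boot, x.size)), axis=1)]
    _, scores = scanner(perms)
    return float(np.count_nonzero(scores < point.score) / (n_boot + 1))


def attach_confidence(
    signal, point: ChangePoint, n_boot: int = 500, seed=0
) -> ChangePoint:
    """Return the point with its bootstrap confidence filled in."""
    return replace(point, confidence=cp_confidence(signal, point, n_boot, seed))


def matrix_cp(
    matrix: np.ndarray,
    kind: str = "rp_lines",
    day_offset: int = 0,
    mode_tolerance: int = 3,
) -> ChangePoint:
    """Change point of a lines x days matrix by line-wise mean-CPA voting.

    The mean-change scan runs on every non-degenerate line; a bin-width-1
    histogram of the line-level days is built and its peak (earliest on
    ties) is the matrix change point. Confidence is the share of
    non-degenerate lines whose day lands within +/- ``mode_tolerance`` days
    of the peak. ``day_offset`` shifts reported days back onto the original
    day grid when leading undefined columns were stripped.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2:
        raise SeriesError("matrix needs at least 2 lines")
    if np.isnan(m).any():
        raise SeriesError("matrix contains NaN; strip undefined columns first")
    if m.shape[1] < 4:
        raise SeriesError("matrix needs at least 4 days per line")
    days, scores = _best_split_mean(m)
    spans = np.ptp(m, axis=1)
    baseline = np.maximum(1.0, spans**2)
    ok = (spans > 0) & (scores > _DEGENERATE_RTOL * baseline)
    if not ok.any():
        return ChangePoint(
            kind=kind, day=2 + day_offset, confidence=0.0, score=0.0, degenerate=True
        )
    voting = days[ok]
    counts = np.bincount(voting)
    mode = int(np.argmax(counts))  # first maximum -> earliest day
    conf = float(np.mean(np.abs(voting - mode) <= mode_tolerance))
    return ChangePoint(
        kind=kind,
        day=mode + day_offset,
        confidence=conf,
        score=float(scores[ok].mean()),
        degenerate=False,
    )
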