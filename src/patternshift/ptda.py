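"""Pattern Transition Detection Algorithm (PTDA).

A pattern transition — a discontinuous shift from one dynamic regime
(attractor) to another — rarely announces itself through a single
statistic. The PTDA therefore collects, per analyzed channel, six change
points: changes in the mean, the variance, and the linear trend of the raw
series, plus mean changes in three "second level" series — the dynamic
complexity profile, the lines of the recurrence plot, and the frequency
rows of the time-frequency distribution. The change points of all channels
are pooled into a confidence-weighted histogram of candidate days; the
weighted mode is the estimated transition day, and the transition
probability is the share of total evidence (all points, degenerate ones
included with zero weight) concentrated within a small window around it.
A shuffle-surrogate test attaches a p-value to the probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .change_points import (
    ChangePoint,
    _best_split_mean,
    attach_confidence,
    cp_mean,
    cp_trend,
    cp_variance,
    matrix_cp,
)
from .complexity import ComplexityParams, dc_profile
from .errors import DegenerateInputError, SeriesError
from .model import ProcessSeries, factor_scores
from .second_order import RecurrenceParams, delay_embed, recurrence_matrix, tfd_matrix

__all__ = [
    "PTDAConfig",
    "TransitionEstimate",
    "six_change_points",
    "pool_and_estimate",
    "ptda_surrogate_p",
    "run_ptda",
]

SIX_KINDS = ("mean", "variance", "trend", "dc_mean", "rp_lines", "tfd_lines")


@dataclass(frozen=True)
class PTDAConfig:
    """Analysis level, pooling rule, and surrogate/bootstrap sizes.

    mode_window_w is the half-width (days) of the window around the pooled
    mode that counts as "agreeing" evidence; n_surrogates drives the
    whole-algorithm surrogate test, n_boot the per-detector permutation
    confidence.
    """

    level: str = "factor"  # "factor" | "item"
    pooling: str = "case_level"  # "case_level" | "per_channel"
    mode_window_w: int = 3
    n_surrogates: int = 200
    n_boot: int = 200
    seed: int = 0
    complexity: ComplexityParams = field(default_factory=ComplexityParams)
    recurrence: RecurrenceParams = field(default_factory=RecurrenceParams)
    tfd_window: int = 7

    def __post_init__(self) -> None:
        if self.level not in ("factor", "item"):
            raise ValueError("level must be 'factor' or 'item'")
        if self.pooling not in ("case_level", "per_channel"):
            raise ValueError("pooling must be 'case_level' or 'per_channel'")
        if self.mode_window_w < 0:
            raise ValueError("mode_window_w must be >= 0")
        if self.n_surrogates < 100:
            raise ValueError("n_surrogates must be >= 100")
        if self.n_boot < 50:
            raise ValueError("n_boot must be >= 50")


@dataclass
class TransitionEstimate:
    """Pooled PTDA output for one case (or one channel)."""

    transition_day: int
    probability: float
    surrogate_p: float | None
    contributing_points: list[ChangePoint]
    pooled_histogram: dict[int, float]
    per_channel: dict[str, list[ChangePoint]] = field(default_factory=dict)
    per_channel_estimates: dict[str, "TransitionEstimate"] = field(
        default_factory=dict
    )


def six_change_points(
    channel: np.ndarray,
    config: PTDAConfig,
    rng: np.random.Generator | None = None,
    with_confidence: bool = True,
) -> list[ChangePoint]:
    """The six PTDA change points of a single imputed channel.

    Raw-series mean/variance/trend detectors carry a permutation-bootstrap
    confidence; the three matrix-derived detectors (DC profile, recurrence
    plot lines, TFD rows) carry a line-consensus or bootstrap confidence.
    Stages whose representation cannot be built on a short channel are
    returned as degenerate points so the count of six kinds is preserved.
    """
    x = np.asarray(channel, dtype=float)
    if x.ndim != 1:
        raise SeriesError("channel must be 1-D")
    if np.isnan(x).any():
        raise SeriesError("channel contains missing values; impute first")
    if x.size < 4 * config.complexity.window_m:
        raise SeriesError(
            f"channel of length {x.size} is too short for the PTDA "
            f"(needs >= {4 * config.complexity.window_m} days)"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cp = config.complexity
    points: list[ChangePoint] = []

    raw_detectors = {"mean": cp_mean, "variance": cp_variance, "trend": cp_trend}
    for kind, detector in raw_detectors.items():
        pt = detector(x)
        if with_confidence:
            pt = attach_confidence(x, pt, n_boot=config.n_boot, seed=rng)
        points.append(pt)

    # mean change of the dynamic-complexity profile (defined part)
    dc = dc_profile(x, cp.window_m, cp.scale_min, cp.scale_max)
    dc_def = dc[cp.window_m - 1 :]
    pt = cp_mean(dc_def, kind="dc_mean")
    pt = replace(pt, day=pt.day + cp.window_m - 1)
    if with_confidence and not pt.degenerate:
        pt = replace(
            pt,
            confidence=_perm_confidence_mean(dc_def, pt.score, config.n_boot, rng),
        )
    points.append(pt)

    # line-wise mean change of the recurrence plot
    vectors = delay_embed(x, config.recurrence)
    rp = recurrence_matrix(vectors, config.recurrence)
    if rp.degenerate:
        points.append(
            ChangePoint("rp_lines", day=2, confidence=0.0, score=0.0, degenerate=True)
        )
    else:
        points.append(matrix_cp(rp.matrix.astype(float), kind="rp_lines"))

    # line-wise mean change of the time-frequency distribution
    tfd = tfd_matrix(x, config.tfd_window)
    defined = tfd.defined_columns
    points.append(
        matrix_cp(
            tfd.power[:, defined], kind="tfd_lines", day_offset=config.tfd_window - 1
        )
    )

    assert tuple(p.kind for p in points) == SIX_KINDS
    return points


def _perm_confidence_mean(
    signal: np.ndarray, score: float, n_boot: int, rng: np.random.Generator
) -> float:
    perms = signal[np.argsort(rng.random((n_boot, signal.size)), axis=1)]
    _, scores = _best_split_mean(perms)
    return float(np.count_nonzero(scores < score) / (n_boot + 1))


def _smoothed_mode(hist: dict[int, float], w: int) -> int:
    """Weighted histogram mode after triangular smoothing of half-width w.

    Kernel weight for a vote at distance d is w + 1 - d (zero beyond w);
    w = 0 reduces to the raw weighted mode. Ties break to the earliest day.
    """
    days = np.array(sorted(hist))
    weights = np.array([hist[d] for d in days], dtype=float)
    grid = np.arange(days.min(), days.max() + 1)
    smooth = (
        weights[None, :] * np.clip(w + 1 - np.abs(grid[:, None] - days[None, :]), 0, None)
    ).sum(axis=1)
    return int(grid[np.argmax(smooth)])  # first maximum -> earliest day


def pool_and_estimate(
    points: list[ChangePoint], config: PTDAConfig
) -> TransitionEstimate:
    """Pool change points into a transition day and probability.

    Non-degenerate points vote for their day with weight = confidence. The
    transition day is the weighted mode of the histogram after smoothing
    with a triangular kernel of half-width mode_window_w (earliest day on
    ties): individual detectors jitter by a few days around a real
    transition, so neighbouring votes should reinforce rather than split.
    The probability is the summed confidence of points within
    +/- mode_window_w days of that day, divided by the total number of
    points — degenerate ones included, each capped at weight 1 — so scattered
    or absent evidence pulls the probability down.
    """
    if not points:
        raise DegenerateInputError("no change points to pool")
    active = [p for p in points if not p.degenerate]
    if not active:
        raise DegenerateInputError("all change points are degenerate")
    hist: dict[int, float] = {}
    for p in active:
        hist[p.day] = hist.get(p.day, 0.0) + min(p.confidence, 1.0)
    transition_day = _smoothed_mode(hist, config.mode_window_w)
    w = config.mode_window_w
    agreeing = sum(
        min(p.confidence, 1.0)
        for p in active
        if abs(p.day - transition_day) <= w
    )
    probability = agreeing / len(points)
    return TransitionEstimate(
        transition_day=int(transition_day),
        probability=float(probability),
        surrogate_p=None,
        contributing_points=list(points),
        pooled_histogram=hist,
    )


def _collect_points(
    values: np.ndarray,
    channels: tuple[str, ...],
    config: PTDAConfig,
    rng: np.random.Generator,
    with_confidence: bool = True,
) -> dict[str, list[ChangePoint]]:
    return {
        label: six_change_points(values[c], config, rng, with_confidence)
        for c, label in enumerate(channels)
    }


def _case_probability(
    values: np.ndarray, channels: tuple[str, ...], config: PTDAConfig, rng
) -> float:
    points = [
        p for pts in _collect_points(values, channels, config, rng).values() for p in pts
    ]
    try:
        return pool_and_estimate(points, config).probability
    except DegenerateInputError:
        return 0.0


def ptda_surrogate_p(
    series: ProcessSeries, estimate: TransitionEstimate, config: PTDAConfig
) -> float:
    """Whole-algorithm surrogate test of a transition estimate.

    Every channel is independently value-permuted; the full PTDA probability
    is recomputed on each surrogate case. p = (count of surrogates with
    probability >= observed + 1) / (n_surrogates + 1).
    """
    analyzed = _analysis_series(series, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    hits = 0
    values = analyzed.values
    for _ in range(config.n_surrogates):
        shuffled = np.take_along_axis(
            values, np.argsort(rng.random(values.shape), axis=1), axis=1
        )
        prob = _case_probability(shuffled, analyzed.channels, config, rng)
        if prob >= estimate.probability - 1e-12:
            hits += 1
    return (hits + 1) / (config.n_surrogates + 1)


def _analysis_series(series: ProcessSeries, config: PTDAConfig) -> ProcessSeries:
    if not series.is_imputed:
        raise SeriesError("PTDA expects an imputed series")
    if config.level == "factor" and series.level == "item":
        return factor_scores(series)
    if config.level == "item" and series.level == "factor":
        raise SeriesError("cannot recover item level from a factor-level series")
    return series


def run_ptda(
    series: ProcessSeries,
    config: PTDAConfig | None = None,
    compute_surrogate_p: bool = True,
) -> TransitionEstimate:
    """Run the full PTDA on an imputed series.

    With case-level pooling (the default) all channels' points enter one
    histogram, yielding a single per-case transition readout; per-channel
    pooling additionally records one estimate per channel in
    ``per_channel`` provenance while the top-level readout stays pooled.
    Set ``compute_surrogate_p=False`` to skip the (costly) whole-algorithm
    surrogate test, e.g. in large simulation studies of the day estimate.
    """
    config = config or PTDAConfig()
    analyzed = _analysis_series(series, config)
    if analyzed.n_days < 4 * config.complexity.window_m:
        raise SeriesError(
            f"series of {analyzed.n_days} days is too short for the PTDA"
        )
    rng = np.random.default_rng(config.seed)
    per_channel = _collect_points(analyzed.values, analyzed.channels, config, rng)
    all_points = [p for pts in per_channel.values() for p in pts]
    estimate = pool_and_estimate(all_points, config)
    estimate.per_channel = per_channel
    if config.pooling == "per_channel":
        # keep a per-channel readout alongside the case-level one
        estimate.per_channel_estimates = {
            ch: pool_and_estimate(pts, config)
            for ch, pts in per_channel.items()
            if any(not p.degenerate for p in pts)
        }
    if compute_surrogate_p:
        estimate.surrogate_p = ptda_surrogate_p(series, estimate, config)
    return estimate
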