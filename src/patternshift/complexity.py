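"""Dynamic complexity: fluctuation x distribution in a sliding window.

Dynamic complexity (DC) is an early-warning statistic for critical
instability in bounded daily self-rating series. It is the product of

* a fluctuation measure ``F`` — the normalized sum of slope magnitudes of
  the maximal monotone segments inside the window, sensitive to both the
  amplitude and the frequency of within-window oscillation, and
* a distribution measure ``D`` — one minus the normalized deficit of the
  sorted window values against a perfectly even spread over the scale
  range, sensitive to how broadly the values scatter across that range.

Both are in [0, 1]; both are 0 exactly for a constant window; their product
is the DC value attributed to the window's last day (right-aligned sliding
window). Significance is assessed against a shuffle-surrogate null: the
channel's own values in random order, which preserves the marginal
distribution and destroys temporal structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DegenerateInputError, SeriesError
from .model import ProcessSeries

__all__ = [
    "ComplexityParams",
    "ComplexityField",
    "SurrogateNull",
    "InstabilityPeriod",
    "fluctuation_intensity",
    "distribution_measure",
    "dynamic_complexity",
    "dc_profile",
    "dc_series",
    "surrogate_null",
    "build_crd",
    "instability_periods",
]


@dataclass(frozen=True)
class ComplexityParams:
    """Window width, scale bounds, surrogate count and significance levels."""

    window_m: int = 7
    scale_min: float = 0.0
    scale_max: float = 100.0
    n_surrogates: int = 1000
    alpha_gray: float = 0.05
    alpha_black: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_m < 3:
            raise ValueError("window_m must be >= 3")
        if not 0 < self.alpha_black < self.alpha_gray < 1:
            raise ValueError("need 0 < alpha_black < alpha_gray < 1")
        if self.n_surrogates < 100:
            raise ValueError("n_surrogates must be >= 100")
        if self.scale_min >= self.scale_max:
            raise ValueError("scale_min must be below scale_max")


def _check_windows(w: np.ndarray, m: int, lo: float, hi: float) -> None:
    if w.shape[-1] != m:
        raise ValueError(f"window length {w.shape[-1]} != window_m {m}")
    if np.isnan(w).any():
        raise ValueError("windows contain missing values; impute first")
    if w.min() < lo or w.max() > hi:
        raise ValueError(f"window values outside scale bounds [{lo}, {hi}]")


def _fluctuation_windows(w: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Vectorized F over a (k, m) stack of windows.

    The window is partitioned into maximal monotone segments; plateaus
    (zero steps) extend the running segment rather than ending it, and a
    leading plateau joins the first directed segment. F sums
    |x_end - x_start| / (end - start) over segments and normalizes by the
    maximum attainable value, (scale range) * (m - 1).
    """
    w = np.atleast_2d(np.asarray(w, dtype=float))
    k, m = w.shape
    d = np.diff(w, axis=1)
    s = np.sign(d)
    # forward-fill plateau signs, then backward-fill any leading plateau
    for j in range(1, m - 1):
        s[:, j] = np.where(s[:, j] == 0, s[:, j - 1], s[:, j])
    for j in range(m - 3, -1, -1):
        s[:, j] = np.where(s[:, j] == 0, s[:, j + 1], s[:, j])
    total = np.zeros(k)
    seg_start = np.zeros(k, dtype=int)
    for j in range(m - 1):
        boundary = (
            np.ones(k, dtype=bool)
            if j == m - 2
            else (s[:, j] != s[:, j + 1]) & (s[:, j] != 0)
        )
        end = j + 1
        amp = np.abs(w[np.arange(k), end] - w[np.arange(k), seg_start])
        length = end - seg_start
        total = np.where(boundary, total + amp / length, total)
        seg_start = np.where(boundary, end, seg_start)
    return total / ((hi - lo) * (m - 1))


def _distribution_windows(w: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Vectorized D over a (k, m) stack of windows.

    Sort the window ascending; against the ideal equidistant spread
    d = range/(m-1), accumulate over all pairs i<j the shortfall
    max(0, (j-i)*d - (y_j - y_i)) and return 1 minus its share of the total
    ideal pair spread.
    """
    w = np.atleast_2d(np.asarray(w, dtype=float))
    k, m = w.shape
    y = np.sort(w, axis=1)
    ideal_step = (hi - lo) / (m - 1)
    i, j = np.triu_indices(m, k=1)
    span = (j - i) * ideal_step  # ideal pair spread, shape (n_pairs,)
    gaps = y[:, j] - y[:, i]
    deficit = np.clip(span[None, :] - gaps, 0.0, None).sum(axis=1)
    return 1.0 - deficit / span.sum()


def fluctuation_intensity(
    window: Sequence[float], scale_min: float, scale_max: float
) -> float:
    """F of a single window; see module docstring for the definition."""
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size < 3:
        raise ValueError("window must be 1-D with at least 3 values")
    _check_windows(w, w.size, scale_min, scale_max)
    return float(_fluctuation_windows(w[None, :], scale_min, scale_max)[0])


def distribution_measure(
    window: Sequence[float], scale_min: float, scale_max: float
) -> float:
    """D of a single window; see module docstring for the definition."""
    w = np.asarray(window, dtype=float)
    if w.ndim != 1 or w.size < 3:
        raise ValueError("window must be 1-D with at least 3 values")
    _check_windows(w, w.size, scale_min, scale_max)
    return float(_distribution_windows(w[None, :], scale_min, scale_max)[0])


def dynamic_complexity(
    window: Sequence[float], scale_min: float, scale_max: float
) -> float:
    """DC = F * D of a single window."""
    return fluctuation_intensity(window, scale_min, scale_max) * distribution_measure(
        window, scale_min, scale_max
    )


def dc_profile(
    x: np.ndarray, window_m: int, scale_min: float, scale_max: float
) -> np.ndarray:
    """DC along one channel (or a stack of channels).

    Returns an array shaped like ``x`` whose entry at day t (0-based index
    t >= window_m - 1) is the DC of the window ending at t; the first
    window_m - 1 entries are NaN (undefined).
    """
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    x2 = np.atleast_2d(x)
    n = x2.shape[1]
    if n < window_m:
        raise SeriesError(f"series of length {n} shorter than window {window_m}")
    windows = sliding_window_view(x2, window_m, axis=1)  # (ch, n-m+1, m)
    flat = windows.reshape(-1, window_m)
    _check_windows(flat, window_m, scale_min, scale_max)
    f = _fluctuation_windows(flat, scale_min, scale_max)
    d = _distribution_windows(flat, scale_min, scale_max)
    dc = (f * d).reshape(x2.shape[0], n - window_m + 1)
    out = np.full(x2.shape, np.nan)
    out[:, window_m - 1 :] = dc
    return out[0] if squeeze else out


@dataclass
class ComplexityField:
    """Channels x days DC matrix plus surrogate-derived significance layers.

    ``dc`` holds NaN for the first window_m - 1 (undefined) days. ``z``,
    ``gray_mask``, ``black_mask`` and ``column_histogram`` are filled by
    :func:`build_crd`; the histogram counts gray-or-black cells per day
    (the exceedance trace drawn on top of a complexity resonance diagram).
    """

    channels: tuple[str, ...]
    days: np.ndarray
    dc: np.ndarray
    params: ComplexityParams
    z: np.ndarray | None = None
    gray_mask: np.ndarray | None = None
    black_mask: np.ndarray | None = None
    column_histogram: np.ndarray | None = None

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.dc)


@dataclass
class SurrogateNull:
    """Per-channel shuffle-surrogate null distribution of DC.

    ``draws`` has shape (n_surrogates, n_channels, n_days) with NaN on the
    undefined leading days, so day-resolved null statistics (e.g. for the
    channel-mean DC) remain available.
    """

    channels: tuple[str, ...]
    draws: np.ndarray
    q_gray: np.ndarray  # per-channel (1 - alpha_gray) quantile
    q_black: np.ndarray  # per-channel (1 - alpha_black) quantile
    mean: np.ndarray  # per-channel null mean
    sd: np.ndarray  # per-channel null sd
    params: ComplexityParams

    def pooled(self, channel_index: int) -> np.ndarray:
        d = self.draws[:, channel_index, :]
        return d[~np.isnan(d)]


def dc_series(series: ProcessSeries, params: ComplexityParams) -> ComplexityField:
    """Compute the DC matrix of an imputed series (DC values only)."""
    if not series.is_imputed:
        raise SeriesError("dc_series expects an imputed series")
    dc = dc_profile(series.values, params.window_m, params.scale_min, params.scale_max)
    return ComplexityField(
        channels=series.channels, days=series.days.copy(), dc=dc, params=params
    )


def surrogate_null(series: ProcessSeries, params: ComplexityParams) -> SurrogateNull:
    """Shuffle-surrogate null of DC, channel by channel.

    Each surrogate is an independent random permutation of the channel's own
    values; DC is recomputed on every surrogate and pooled across windows.
    """
    if not series.is_imputed:
        raise SeriesError("surrogate_null expects an imputed series")
    rng = np.random.default_rng(params.seed)
    n_ch, n_days = series.values.shape
    if n_days < params.window_m:
        raise SeriesError("series shorter than the DC window")
    draws = np.empty((params.n_surrogates, n_ch, n_days))
    for c in range(n_ch):
        vals = series.values[c]
        perms = vals[np.argsort(rng.random((params.n_surrogates, n_days)), axis=1)]
        draws[:, c, :] = dc_profile(
            perms, params.window_m, params.scale_min, params.scale_max
        )
    defined = ~np.isnan(draws[0, 0])
    flat = draws[:, :, defined]  # (n_sur, n_ch, n_def)
    pooled = flat.transpose(1, 0, 2).reshape(n_ch, -1)
    return SurrogateNull(
        channels=series.channels,
        draws=draws,
        q_gray=np.quantile(pooled, 1 - params.alpha_gray, axis=1),
        q_black=np.quantile(pooled, 1 - params.alpha_black, axis=1),
        mean=pooled.mean(axis=1),
        sd=pooled.std(axis=1),
        params=params,
    )


def build_crd(field: ComplexityField, null: SurrogateNull) -> ComplexityField:
    """Fill the significance layers of a complexity resonance diagram.

    z-values standardize each channel's DC against its surrogate null; the
    gray/black masks mark DC values above the per-channel empirical
    (1 - alpha_gray) / (1 - alpha_black) null quantiles, and the column
    histogram counts flagged cells per day.
    """
    if field.channels != null.channels:
        raise ValueError("field and null refer to different channels")
    dc = field.dc
    defined = field.defined
    sd = null.sd.copy()
    degenerate = sd == 0
    if np.any(degenerate):
        emp_var = np.nanstd(np.where(defined, dc, np.nan), axis=1)
        if np.any(emp_var[degenerate] > 0):
            raise DegenerateInputError(
                "surrogate null has zero spread for a non-constant channel"
            )
        sd[degenerate] = 1.0  # constant channel: z defined as 0
    z = (dc - null.mean[:, None]) / sd[:, None]
    gray = np.where(defined, dc > null.q_gray[:, None], False)
    black = np.where(defined, dc > null.q_black[:, None], False)
    gray |= black  # quantile ordering guarantees this; enforce structurally
    field.z = np.where(defined, z, np.nan)
    field.gray_mask = gray
    field.black_mask = black
    field.column_histogram = (gray | black).sum(axis=0)
    return field


@dataclass(frozen=True)
class InstabilityPeriod:
    """A run of days whose (mean) DC clears the surrogate null threshold."""

    channel_scope: str  # "case_mean" | "per_channel"
    start_day: int
    end_day: int
    mean_dc: float
    p_value: float
    channel: str | None = None

    def overlaps(self, start: int, end: int) -> bool:
        return self.start_day <= end and start <= self.end_day


def _merge_runs(flag_days: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    if flag_days.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = int(flag_days[0])
    for d in flag_days[1:]:
        d = int(d)
        if d - prev <= max_gap + 1:
            prev = d
        else:
            runs.append((start, prev))
            start = prev = d
    runs.append((start, prev))
    return runs


def _period_pvalue(
    mean_dc: float, null_series: np.ndarray, length: int
) -> float:
    """Monte-Carlo p: share of surrogates whose best same-length window
    mean-DC reaches the period's mean, with add-one correction."""
    n_sur = null_series.shape[0]
    kernel = np.ones(length) / length
    hits = 0
    for r in range(n_sur):
        row = null_series[r]
        row = row[~np.isnan(row)]
        if row.size < length:
            continue
        window_means = np.convolve(row, kernel, mode="valid")
        if window_means.max() >= mean_dc - 1e-12:
            hits += 1
    return (hits + 1) / (n_sur + 1)


def instability_periods(
    field: ComplexityField,
    null: SurrogateNull,
    scope: str = "case_mean",
    alpha: float = 0.05,
    max_gap: int = 1,
) -> list[InstabilityPeriod]:
    """Detect significant critical-instability periods.

    Days whose DC (channel-mean DC for ``scope="case_mean"``) exceeds the
    (1 - alpha) surrogate quantile are flagged; flagged runs with gaps of at
    most ``max_gap`` days are merged. Each period's p-value is the share of
    surrogates whose maximum same-length sliding-window mean DC reaches the
    period's observed mean (add-one corrected, so never exactly 0).
    """
    if scope not in ("case_mean", "per_channel"):
        raise ValueError("scope must be 'case_mean' or 'per_channel'")
    if field.dc.size == 0:
        raise SeriesError("empty complexity field")
    periods: list[InstabilityPeriod] = []

    def scan(emp: np.ndarray, null_series: np.ndarray, label: str | None) -> None:
        pool = null_series[~np.isnan(null_series)]
        thr = np.quantile(pool, 1 - alpha)
        with np.errstate(invalid="ignore"):
            flagged = np.flatnonzero(np.where(np.isnan(emp), False, emp > thr))
        for i0, i1 in _merge_runs(flagged, max_gap):
            seg = emp[i0 : i1 + 1]
            mean_dc = float(seg.mean())
            p = _period_pvalue(mean_dc, null_series, i1 - i0 + 1)
            periods.append(
                InstabilityPeriod(
                    channel_scope=scope,
                    start_day=int(field.days[i0]),
                    end_day=int(field.days[i1]),
                    mean_dc=mean_dc,
                    p_value=p,
                    channel=label,
                )
            )

    if scope == "case_mean":
        # undefined leading days stay NaN under a plain mean (same NaN
        # pattern on every channel), which is exactly what scan() expects
        scan(field.dc.mean(axis=0), null.draws.mean(axis=1), None)
    else:
        for c, label in enumerate(field.channels):
            scan(field.dc[c], null.draws[:, c, :], label)
    return periods
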