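"""Second-level representations of a channel: recurrence plots and TFDs.

The transition detector does not only scan the raw ratings; it also scans
how the *dynamics* change. Two standard state-space views are built here:

* a recurrence plot — the binary matrix of delay-embedded time points whose
  state vectors lie within a distance threshold epsilon of each other, with
  epsilon chosen to realize a fixed recurrence rate; and
* a time-frequency distribution P(t, omega) — the windowed periodogram of
  the mean-removed signal, right-aligned like the complexity window, showing
  how spectral energy migrates over time.

Downstream, mean-change detection is applied line-wise to both matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import pdist, squareform

from .errors import SeriesError

__all__ = [
    "RecurrenceParams",
    "RecurrenceMatrix",
    "TFDMatrix",
    "delay_embed",
    "recurrence_matrix",
    "tfd_matrix",
]


@dataclass(frozen=True)
class RecurrenceParams:
    """Delay-embedding and thresholding parameters for recurrence plots.

    embed_dim is the embedding dimension m (length of the snippet each state
    vector represents), delay_tau the lag between snippet entries in days.
    epsilon is not set directly: it is the target_rr quantile of all pairwise
    embedded distances, which fixes the recurrence rate across channels with
    different variances.
    """

    embed_dim: int = 3
    delay_tau: int = 1
    norm: str = "euclidean"
    epsilon_rule: str = "fixed_recurrence_rate"
    target_rr: float = 0.10

    def __post_init__(self) -> None:
        if self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if self.delay_tau < 1:
            raise ValueError("delay_tau must be >= 1")
        if not 0 < self.target_rr < 1:
            raise ValueError("target_rr must be in (0, 1)")
        if self.norm != "euclidean":
            raise ValueError("only the euclidean norm is supported")
        if self.epsilon_rule != "fixed_recurrence_rate":
            raise ValueError("only the fixed_recurrence_rate epsilon rule is supported")


def delay_embed(channel: np.ndarray, params: RecurrenceParams) -> np.ndarray:
    """Delay-embed a channel into state vectors.

    Vector t (0-based) is (x_t, x_{t+tau}, ..., x_{t+(m-1)tau}); there are
    n - (m - 1) * tau of them.
    """
    x = np.asarray(channel, dtype=float)
    if x.ndim != 1:
        raise ValueError("channel must be 1-D")
    m, tau = params.embed_dim, params.delay_tau
    span = (m - 1) * tau
    if x.size <= span:
        raise SeriesError(
            f"series of length {x.size} too short for embedding m={m}, tau={tau}"
        )
    if m == 1:
        return x[:, None].copy()
    idx = np.arange(x.size - span)[:, None] + np.arange(m)[None, :] * tau
    return x[idx]


@dataclass
class RecurrenceMatrix:
    """Binary recurrence matrix with the realized epsilon and rate."""

    matrix: np.ndarray  # (n, n) uint8, symmetric, unit diagonal
    epsilon: float
    recurrence_rate: float  # share of off-diagonal ones
    degenerate: bool = False  # all embedded points identical

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def recurrence_matrix(
    vectors: np.ndarray, params: RecurrenceParams
) -> RecurrenceMatrix:
    """Threshold pairwise embedded distances into a recurrence plot.

    epsilon is the target_rr empirical quantile of the pairwise distances,
    so roughly a target_rr share of point pairs recur. If every embedded
    point coincides the distance distribution is degenerate; an all-ones
    matrix is returned with the degenerate flag set.
    """
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise SeriesError("need at least 2 embedded vectors")
    n = v.shape[0]
    dists = pdist(v)
    if dists.max() == 0.0:
        return RecurrenceMatrix(
            matrix=np.ones((n, n), dtype=np.uint8),
            epsilon=0.0,
            recurrence_rate=1.0,
            degenerate=True,
        )
    eps = float(np.quantile(dists, params.target_rr))
    rec = (squareform(dists) <= eps).astype(np.uint8)
    np.fill_diagonal(rec, 1)
    off = rec.sum() - n
    return RecurrenceMatrix(
        matrix=rec,
        epsilon=eps,
        recurrence_rate=off / (n * (n - 1)),
        degenerate=False,
    )


@dataclass
class TFDMatrix:
    """Windowed spectral-energy matrix P(t, omega).

    Row k holds the squared DFT magnitude at frequency k / window_w
    cycles/day (k = 1 .. window_w // 2) of the mean-removed, right-aligned
    window ending at day t; the first window_w - 1 columns are undefined
    (NaN). Mean removal makes a constant window map to zero energy.
    """

    power: np.ndarray  # (n_freq, n_days), NaN on undefined columns
    frequencies: np.ndarray  # cycles per day
    window_w: int

    @property
    def defined_columns(self) -> np.ndarray:
        return ~np.isnan(self.power[0])


def tfd_matrix(channel: np.ndarray, window_w: int = 7) -> TFDMatrix:
    if window_w < 4:
        raise ValueError("window_w must be >= 4")
    x = np.asarray(channel, dtype=float)
    if x.ndim != 1:
        raise ValueError("channel must be 1-D")
    n = x.size
    if n < window_w:
        raise SeriesError(f"series of length {n} shorter than window {window_w}")
    windows = sliding_window_view(x, window_w)  # (n - w + 1, w)
    centered = windows - windows.mean(axis=1, keepdims=True)
    spectrum = np.fft.rfft(centered, axis=1)
    n_freq = window_w // 2
    power = np.abs(spectrum[:, 1 : n_freq + 1]) ** 2  # drop the DC bin
    out = np.full((n_freq, n), np.nan)
    out[:, window_w - 1 :] = power.T
    return TFDMatrix(
        power=out,
        frequencies=np.arange(1, n_freq + 1) / window_w,
        window_w=window_w,
    )
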