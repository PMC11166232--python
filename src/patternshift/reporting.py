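"""Figure rendering, diary/indicator alignment statistics, report bundles.

Every rendered figure gets a companion CSV holding exactly the plotted
values, so the figures are never the only record of a result.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .complexity import ComplexityField, InstabilityPeriod
from .errors import CategoryError, PatternShiftError
from .model import CATEGORY_GROUPS, NO_ENTRY, CategoryTimeline, ProcessSeries
from .ptda import TransitionEstimate

__all__ = [
    "AlignmentResult",
    "render_crd",
    "render_transition_band",
    "align_categories",
    "export_report",
    "CATEGORY_BAND_ORDER",
]

#: fixed row order of the diary-category band under a CRD
CATEGORY_BAND_ORDER = (
    "feeling_helpless",
    "noticing_attractor",
    "regaining_control",
    "moment_of_improvement",
    "lasting_improvement",
    "broadening_perspective",
    "critical_instability",
    "kairos",
)


def _companion_path(out: Path) -> Path:
    return out.with_suffix(".csv")


def render_crd(
    field: ComplexityField,
    timeline: CategoryTimeline | None = None,
    transition: TransitionEstimate | None = None,
    out: str | Path = "crd.png",
) -> Path:
    """Render a complexity resonance diagram.

    Channels x days heatmap of DC with gray (5%) and black (1%) surrogate
    exceedance overlays, the per-day exceedance histogram on top, an
    optional diary-category band below (white frames marking days without
    an entry), and an optional vertical transition marker. The plotted
    values are also written to a companion CSV next to the image.
    """
    if field.gray_mask is None or field.column_histogram is None:
        raise PatternShiftError("field has no significance layers; run build_crd first")
    out = Path(out)
    days = field.days
    n_rows = 3 if timeline is not None else 2
    heights = [1, 4] + ([1.6] if timeline is not None else [])
    fig, axes = plt.subplots(
        n_rows,
        1,
        figsize=(10, 2 + 0.08 * len(field.channels) + (2 if timeline else 0)),
        sharex=True,
        gridspec_kw={"height_ratios": heights},
    )
    ax_hist, ax_map = axes[0], axes[1]
    ax_hist.bar(days, field.column_histogram, color="0.4", width=1.0)
    ax_hist.set_ylabel("n sig.")
    shade = np.where(field.black_mask, 2, np.where(field.gray_mask, 1, 0)).astype(float)
    shade[~field.defined] = np.nan
    ax_map.imshow(
        shade,
        aspect="auto",
        interpolation="nearest",
        cmap=matplotlib.colors.ListedColormap(["white", "0.6", "black"]),
        vmin=0,
        vmax=2,
        extent=(days[0] - 0.5, days[-1] + 0.5, len(field.channels) - 0.5, -0.5),
    )
    ax_map.set_ylabel("channel")
    ax_map.set_yticks(range(len(field.channels)))
    ax_map.set_yticklabels(field.channels, fontsize=4)
    if timeline is not None:
        ax_band = axes[2]
        band = np.zeros((len(CATEGORY_BAND_ORDER), days.size))
        missing_days = np.zeros(days.size, dtype=bool)
        for j, day in enumerate(days):
            codes = timeline.entries.get(int(day), frozenset({NO_ENTRY}))
            if NO_ENTRY in codes:
                missing_days[j] = True
            for i, cat in enumerate(CATEGORY_BAND_ORDER):
                band[i, j] = 1.0 if cat in codes else 0.0
        ax_band.imshow(
            band,
            aspect="auto",
            interpolation="nearest",
            cmap="Blues",
            vmin=0,
            vmax=1,
            extent=(days[0] - 0.5, days[-1] + 0.5, len(CATEGORY_BAND_ORDER) - 0.5, -0.5),
        )
        for j in np.flatnonzero(missing_days):  # white frames: no diary entry
            ax_band.axvspan(
                days[j] - 0.5, days[j] + 0.5, fill=False, edgecolor="white", lw=1.2
            )
        ax_band.set_yticks(range(len(CATEGORY_BAND_ORDER)))
        ax_band.set_yticklabels(CATEGORY_BAND_ORDER, fontsize=5)
    if transition is not None:
        for ax in axes:
            ax.axvline(transition.transition_day, color="magenta", lw=1.5)
    axes[-1].set_xlabel("day")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)

    rows = []
    for c, label in enumerate(field.channels):
        for j, day in enumerate(days):
            if not field.defined[c, j]:
                continue
            rows.append(
                {
                    "channel": label,
                    "day": int(day),
                    "dc": field.dc[c, j],
                    "z": field.z[c, j] if field.z is not None else np.nan,
                    "gray": bool(field.gray_mask[c, j]),
                    "black": bool(field.black_mask[c, j]),
                }
            )
    table = pd.DataFrame(rows)
    hist = pd.DataFrame(
        {"channel": "__histogram__", "day": days, "dc": field.column_histogram}
    )
    pd.concat([table, hist], ignore_index=True).to_csv(
        _companion_path(out), index=False
    )
    return out


def transition_band(estimate: TransitionEstimate, n_days: int) -> np.ndarray:
    """Confidence-weighted change-point histogram smoothed with a triangular
    kernel of half-width mode_window_w-like radius, normalized to max 1."""
    radius = 3
    band = np.zeros(n_days)
    for day, weight in estimate.pooled_histogram.items():
        for d in range(max(1, day - radius), min(n_days, day + radius) + 1):
            band[d - 1] += weight * (radius + 1 - abs(d - day))
    top = band.max()
    return band / top if top > 0 else band


def render_transition_band(
    estimate: TransitionEstimate, n_days: int, out: str | Path = "band.png"
) -> Path:
    """Render the 1 x n_days pattern-transition probability band."""
    out = Path(out)
    band = transition_band(estimate, n_days)
    fig, ax = plt.subplots(figsize=(10, 1.4))
    ax.imshow(
        band[None, :],
        aspect="auto",
        interpolation="nearest",
        cmap="viridis",
        extent=(0.5, n_days + 0.5, 0, 1),
    )
    ax.axvline(estimate.transition_day, color="magenta", lw=1.5)
    ax.set_yticks([])
    ax.set_xlabel("day")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    pd.DataFrame({"day": np.arange(1, n_days + 1), "intensity": band}).to_csv(
        _companion_path(out), index=False
    )
    return out


@dataclass
class AlignmentResult:
    """Association of a diary-category group with quantitative indicators.

    For each group, the 2x2 day counts of (group present / absent) x
    (day inside / outside the indicator window), an odds ratio (Haldane
    corrected), and a circular-shift permutation p-value.
    """

    group: str
    n_days: int
    counts: dict[str, int]  # keys: in_in, in_out, out_in, out_out
    odds_ratio: float
    permutation_p: float


def align_categories(
    timeline: CategoryTimeline,
    periods: list[InstabilityPeriod] | None = None,
    estimate: TransitionEstimate | None = None,
    w: int = 3,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[AlignmentResult]:
    """Quantify diary/time-series correspondence per category group.

    The indicator set is the union of significant-DC period days and
    transition_day +/- w. The null preserves the timeline's run structure
    by circularly shifting the whole day sequence (rather than shuffling
    days independently); p-values are add-one corrected.
    """
    if periods is None and estimate is None:
        raise PatternShiftError("need at least one quantitative indicator")
    days = np.array(sorted(timeline.entries), dtype=int)
    n_days = days.size
    present_all = {
        d: codes for d, codes in timeline.entries.items() if NO_ENTRY not in codes
    }
    if not present_all:
        raise CategoryError("timeline consists only of no_entry days")

    indicator = np.zeros(n_days, dtype=bool)
    if periods:
        for p in periods:
            indicator |= (days >= p.start_day) & (days <= p.end_day)
    if estimate is not None:
        indicator |= np.abs(days - estimate.transition_day) <= w

    rng = np.random.default_rng(seed)
    shifts = rng.integers(1, n_days, size=n_perm)
    results = []
    for group, members in CATEGORY_GROUPS.items():
        present = np.array(
            [bool(timeline.entries[int(d)] & members) for d in days]
        )
        a = int(np.sum(present & indicator))
        b = int(np.sum(present & ~indicator))
        c = int(np.sum(~present & indicator))
        d = int(np.sum(~present & ~indicator))
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        hits = sum(
            int(np.sum(np.roll(present, int(s)) & indicator)) >= a for s in shifts
        )
        results.append(
            AlignmentResult(
                group=group,
                n_days=n_days,
                counts={"in_in": a, "in_out": b, "out_in": c, "out_out": d},
                odds_ratio=float(odds),
                permutation_p=(hits + 1) / (n_perm + 1),
            )
        )
    return results


def export_report(
    series: ProcessSeries,
    field: ComplexityField,
    estimate: TransitionEstimate,
    periods: list[InstabilityPeriod],
    alignment: list[AlignmentResult] | None = None,
    timeline: CategoryTimeline | None = None,
    out_dir: str | Path = "report",
    manifest: dict | None = None,
) -> Path:
    """Write the full report bundle for one analyzed case.

    The bundle holds summary.json (transition day, probability, surrogate
    p, instability periods, optional alignment), the CRD and transition
    band with their companion CSVs, a CSV of all pooled change points, and
    a manifest with the exact configuration and seeds used.
    """
    if series is None or field is None or estimate is None:
        raise PatternShiftError("series, field and estimate are all required")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    summary = {
        "case_id": series.case_id,
        "transition_day": estimate.transition_day,
        "probability": round(estimate.probability, 10),
        "surrogate_p": estimate.surrogate_p,
        "periods": [
            {
                "start_day": p.start_day,
                "end_day": p.end_day,
                "mean_dc": round(p.mean_dc, 10),
                "p_value": round(p.p_value, 10),
                "scope": p.channel_scope,
                "channel": p.channel,
            }
            for p in periods
        ],
    }
    if alignment is not None:
        summary["alignment"] = [asdict(a) for a in alignment]
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )

    pd.DataFrame(
        [
            {
                "channel": ch,
                "kind": p.kind,
                "day": p.day,
                "confidence": p.confidence,
                "score": p.score,
                "degenerate": p.degenerate,
            }
            for ch, pts in estimate.per_channel.items()
            for p in pts
        ]
    ).to_csv(out_dir / "change_points.csv", index=False)

    render_crd(field, timeline, estimate, out_dir / "crd.png")
    render_transition_band(estimate, series.n_days, out_dir / "transition_band.png")

    if manifest is not None:
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str)
        )
    return out_dir
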