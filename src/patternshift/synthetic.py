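"""Synthetic daily process data with planted regimes and diary codings.

Real inpatient monitoring data of this kind are privacy-restricted, so the
generator plants the minimal structure the analysis pipeline assumes: a
stable attractor regime (latent AR(1) around per-factor baseline means), an
optional window of critical instability (inflated innovation noise plus an
alternating high-frequency component, so that both the fluctuation and the
distribution side of dynamic complexity respond), an abrupt level shift at
a planted transition day on a subset of factors, an optional transient
relapse just before the shift, and completely-at-random missingness at the
rates typical of daily questionnaire and diary adherence (about 1.6% of
item values and about 15.2% of diary days).

A coupled category timeline is emitted alongside: stable-phase codes before
the transition, critical-instability codes inside the instability window,
an elevated chance of a Kairos code around the transition day, and
improvement codes afterwards. Every quantity that a recovery test needs is
returned in a :class:`SyntheticTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import PatternShiftError
from .model import (
    CATEGORY_VOCABULARY,
    NO_ENTRY,
    CategoryTimeline,
    ProcessSeries,
    QuestionnaireSchema,
    default_schema,
)

__all__ = ["SyntheticSpec", "SyntheticTruth", "simulate_process", "simulate_categories"]


@dataclass(frozen=True)
class Relapse:
    """Transient excursion back toward the old pattern before the shift."""

    day: int
    depth_sd: float = 2.0
    duration: int = 3


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth generating parameters, in baseline-noise-sd units.

    Defaults describe a 90-day monitored case whose pattern transition at
    day 60 shifts 70% of the factors by 1.5 noise-sd, preceded by a short
    burst of critical instability, observed through 43 items on a 0-100
    scale with 1.6% missing values.

    ``instability_window="auto"`` plants the window on the 3 days
    immediately preceding the transition day (none when no transition is
    planted), encoding the canonical sequence stable regime -> critical
    instability -> pattern shift; pass an explicit window or ``None`` to
    decouple the two.
    """

    n_days: int = 90
    schema: QuestionnaireSchema = field(default_factory=default_schema)
    transition_day: int | None = 60
    level_shift_sd: float = 1.5
    shifted_channel_fraction: float = 0.7
    instability_window: tuple[int, int] | str | None = "auto"
    instability_gain: float = 3.0
    ar_phi: float = 0.6
    noise_sd: float = 6.0
    missing_rate_values: float = 0.016
    missing_rate_entries: float = 0.152
    relapse: Relapse | None = None
    baseline_mean_range: tuple[float, float] = (35.0, 65.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days < 10:
            raise PatternShiftError("n_days must be >= 10")
        if self.transition_day is not None and not (
            1 < self.transition_day <= self.n_days
        ):
            raise PatternShiftError("transition_day must lie in (1, n_days]")
        if self.instability_window == "auto":
            window = None
            if self.transition_day is not None:
                start = max(1, self.transition_day - 3)
                end = self.transition_day - 1
                if start <= end:
                    window = (start, end)
            object.__setattr__(self, "instability_window", window)
        if self.instability_window is not None:
            a, b = self.instability_window
            if not (1 <= a <= b <= self.n_days):
                raise PatternShiftError("instability_window outside the day range")
        if not 0 <= self.shifted_channel_fraction <= 1:
            raise PatternShiftError("shifted_channel_fraction must be in [0, 1]")
        if not 0 <= self.ar_phi < 1:
            raise PatternShiftError("ar_phi must be in [0, 1)")
        if self.instability_gain < 1:
            raise PatternShiftError("instability_gain must be >= 1")
        for rate in (self.missing_rate_values, self.missing_rate_entries):
            if not 0 <= rate <= 1:
                raise PatternShiftError("missing rates must be in [0, 1]")
        if self.relapse is not None:
            if self.transition_day is None:
                raise PatternShiftError("relapse requires a transition_day")
            if self.relapse.day + self.relapse.duration - 1 >= self.transition_day:
                raise PatternShiftError("relapse must end before the transition day")


@dataclass
class SyntheticTruth:
    """Planted parameters, for recovery tests and report manifests."""

    pre_means: dict[str, float]
    post_means: dict[str, float]
    shifted_factors: tuple[str, ...]
    transition_day: int | None
    instability_window: tuple[int, int] | None
    relapse: Relapse | None
    category_emissions: dict[str, dict[str, float]]
    seed: int


# per-phase emission weights over the eight diary subcategories
_EMISSIONS: Mapping[str, Mapping[str, float]] = {
    "stable": {
        "feeling_helpless": 0.30,
        "noticing_attractor": 0.30,
        "regaining_control": 0.23,
        "broadening_perspective": 0.10,
        "moment_of_improvement": 0.05,
        "critical_instability": 0.02,
    },
    "instability": {
        "critical_instability": 0.60,
        "broadening_perspective": 0.20,
        "feeling_helpless": 0.10,
        "noticing_attractor": 0.05,
        "moment_of_improvement": 0.05,
    },
    "transition": {
        "kairos": 0.40,
        "critical_instability": 0.15,
        "broadening_perspective": 0.15,
        "moment_of_improvement": 0.20,
        "lasting_improvement": 0.10,
    },
    "post": {
        "moment_of_improvement": 0.35,
        "lasting_improvement": 0.35,
        "broadening_perspective": 0.15,
        "regaining_control": 0.10,
        "kairos": 0.05,
    },
}


def simulate_process(spec: SyntheticSpec) -> tuple[ProcessSeries, SyntheticTruth]:
    """Generate one case: item-level daily ratings plus its ground truth.

    Per factor a latent AR(1) path fluctuates around the regime mean (the
    pre-transition mean before the planted transition day, the shifted mean
    after it, for a seeded subset of factors; shift direction is random per
    factor). The latent path is parameterized by its stationary standard
    deviation: innovations have sd ``noise_sd * sqrt(1 - ar_phi**2)``, so
    ``noise_sd`` is the actual day-to-day dispersion of a factor around its
    regime mean and planted effect sizes in noise-sd units keep their face
    meaning. Item values are the factor latent plus independent noise of sd
    ``noise_sd``, clipped to the scale. Inside the instability window both
    the latent and the item innovations are inflated by
    ``instability_gain`` and an alternating +/- component is superimposed.
    Values are finally masked missing completely at random.
    """
    rng = np.random.default_rng(spec.seed)
    schema = spec.schema
    n_days = spec.n_days
    factors = schema.factors
    lo, hi = schema.scale_min, schema.scale_max
    sd = spec.noise_sd

    pre_means = {
        f: float(rng.uniform(*spec.baseline_mean_range)) for f in factors
    }
    n_shift = int(round(spec.shifted_channel_fraction * len(factors)))
    shifted = tuple(
        rng.choice(len(factors), size=n_shift, replace=False).tolist()
    )
    shifted_factors = tuple(factors[i] for i in sorted(shifted))
    signs = {f: float(rng.choice([-1.0, 1.0])) for f in shifted_factors}
    post_means = dict(pre_means)
    if spec.transition_day is not None:
        for f in shifted_factors:
            post_means[f] = pre_means[f] + signs[f] * spec.level_shift_sd * sd

    days = np.arange(1, n_days + 1)
    in_instab = np.zeros(n_days, dtype=bool)
    if spec.instability_window is not None:
        a, b = spec.instability_window
        in_instab[(days >= a) & (days <= b)] = True
    gain = np.where(in_instab, spec.instability_gain, 1.0)
    alternating = np.where(in_instab, (-1.0) ** days * spec.instability_gain * sd, 0.0)

    latent = np.empty((len(factors), n_days))
    for i, f in enumerate(factors):
        mean_path = np.full(n_days, pre_means[f])
        if spec.transition_day is not None:
            mean_path[days >= spec.transition_day] = post_means[f]
        if spec.relapse is not None and f in shifted_factors:
            r = spec.relapse
            sel = (days >= r.day) & (days < r.day + r.duration)
            # excursion away from the upcoming new regime
            mean_path[sel] = pre_means[f] - signs[f] * r.depth_sd * sd
        innov_sd = sd * np.sqrt(1.0 - spec.ar_phi**2)
        x = np.empty(n_days)
        x[0] = mean_path[0] + rng.normal(0.0, sd * gain[0])
        for t in range(1, n_days):
            x[t] = (
                mean_path[t]
                + spec.ar_phi * (x[t - 1] - mean_path[t - 1])
                + rng.normal(0.0, innov_sd * gain[t])
            )
        latent[i] = x + alternating

    values = np.empty((len(schema.items), n_days))
    for j, item in enumerate(schema.items):
        i = factors.index(schema.factor_of[item])
        values[j] = latent[i] + rng.normal(0.0, sd * gain, size=n_days)
    values = np.clip(values, lo, hi)

    mask = rng.random(values.shape) < spec.missing_rate_values
    fully_masked = mask.all(axis=1)
    mask[fully_masked, 0] = False  # keep LOCF feasible on every channel
    values_masked = np.where(mask, np.nan, values)

    series = ProcessSeries(
        case_id=f"synthetic-{spec.seed}",
        days=days,
        channels=tuple(schema.items),
        values=values_masked,
        missing_mask=mask,
        schema=schema,
        level="item",
    )
    truth = SyntheticTruth(
        pre_means=pre_means,
        post_means=post_means,
        shifted_factors=shifted_factors,
        transition_day=spec.transition_day,
        instability_window=spec.instability_window,
        relapse=spec.relapse,
        category_emissions={k: dict(v) for k, v in _EMISSIONS.items()},
        seed=spec.seed,
    )
    return series, truth


def _phase_of(day: int, truth: SyntheticTruth) -> str:
    t = truth.transition_day
    if t is not None and abs(day - t) <= 3:
        return "transition"
    if truth.instability_window is not None:
        a, b = truth.instability_window
        if a <= day <= b:
            return "instability"
    if t is not None and day > t:
        return "post"
    return "stable"


def simulate_categories(
    truth: SyntheticTruth, spec: SyntheticSpec
) -> CategoryTimeline:
    """Draw a diary-category timeline coupled to the planted dynamics.

    One subcategory is drawn per day from the phase's emission weights (a
    second, independent draw is added with probability 0.25, echoing days
    with several codable statements); the day is then replaced by
    ``no_entry`` with the diary missingness probability. With no planted
    transition and no instability window every day draws from the
    stationary stable-phase weights.
    """
    if truth is None:
        raise PatternShiftError("simulate_categories needs the truth object")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xD1A8]))
    entries: dict[int, frozenset[str]] = {}
    for day in range(1, spec.n_days + 1):
        if rng.random() < spec.missing_rate_entries:
            entries[day] = frozenset({NO_ENTRY})
            continue
        weights = truth.category_emissions[_phase_of(day, truth)]
        codes = list(weights)
        p = np.array([weights[c] for c in codes])
        p = p / p.sum()
        drawn = {str(rng.choice(codes, p=p))}
        if rng.random() < 0.25:
            drawn.add(str(rng.choice(codes, p=p)))
        assert drawn <= CATEGORY_VOCABULARY
        entries[day] = frozenset(drawn)
    return CategoryTimeline(case_id=f"synthetic-{spec.seed}", entries=entries)
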