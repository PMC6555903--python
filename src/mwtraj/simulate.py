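"""Synthetic experience-sampling cohorts with latent ultradian dynamics.

The generator emulates a two-week smartphone probing protocol: five probes
per day for 14 days plus one extra probe on the last day (71 per
participant), delivered at pseudo-random gaps of 10–144 minutes inside a
participant-chosen 12-h daily window starting at 9, 10, 11, or 12 o'clock.

Underneath the protocol run two latent processes per participant, sampled
at probe times:

* thought-generation intensity  ``lambda(t) = max(0, a0 + a1*sin(2*pi*t/P + phi) + eps)``
  with an ultradian period ``P`` of 4–6 h, and
* cognitive-control level       ``c(t) = clip(c0 + g*sin(2*pi*t/P + phi) + drops + eps, 0, 1)``,

where control drops arrive as a Poisson process and each drop subtracts
``drop_depth`` decaying linearly back to zero over ``drop_recovery_hours``.
A probe is a true mind-wandering event when thought generation is high
(``lambda >= mw_not_threshold``) while control has fallen
(``c <= mw_control_threshold``) — control dropping out of step with a still
-high thought cycle.

Observables: the number-of-thoughts report is Poisson(lambda) capped at the
dropdown's "10+" item; the five-level scene-closeness rating is "same"
unless a logistic function of control produces a non-default response, whose
magnitude (little/much) is a coin flip and whose direction leans "farther"
(a boundary-extension-like reporting bias), so stronger control yields more
— and more positive — non-same ratings.

Everything is a pure function of (params, master_seed); per-participant
streams are split with ``SeedSequence((master_seed, participant_index))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import ProbeTable, RATINGS, WINDOW_START_HOURS, WINDOW_HOURS, COLUMNS

#: fixed, arbitrary first day of the sampling fortnight (a Monday)
START_DATE = datetime(2017, 2, 6)


@dataclass
class SimParams:
    """Generator parameters; defaults reproduce the study protocol and are
    calibrated to its reported marginals (~36% mind-wandering incidence,
    ~25% non-same ratings)."""

    n_participants: int = 28
    days: int = 14
    probes_per_day: int = 5
    extra_last_day: int = 1
    gap_range_minutes: tuple[int, int] = (10, 144)
    window_start_hour: int | None = None  # None: drawn per participant

    # latent thought generation (thoughts on the mind)
    not_baseline: float = 1.2       # a0, mean thoughts
    not_amplitude: float = 0.9      # a1
    period_hours: float = 5.0       # P, ultradian cycle length
    phase: float | None = None      # radians; None: drawn per participant

    # latent cognitive control, in [0, 1]
    control_baseline: float = 0.62  # c0
    coordination_gain: float = 0.04 # coupling of control to the thought cycle
    drop_rate_per_day: float = 2.5  # expected control-drop events per day
    drop_depth: float = 0.6
    drop_recovery_hours: float = 2.0

    # mind-wandering trigger: high thought generation AND collapsed control
    mw_not_threshold: float = 1.0
    mw_control_threshold: float = 0.66
    mw_with_task_prob: float = 0.5

    # rating response model: P(non-same) = logistic(intercept + slope * c)
    nonsame_intercept: float = -7.6
    nonsame_slope: float = 10.0
    nonsame_much_prob: float = 0.5
    nonsame_farther_prob: float = 0.9

    not_noise_sd: float = 0.3
    control_noise_sd: float = 0.22

    # protocol imperfections
    decline_rate: float = 0.08
    alcohol_rate: float = 0.005
    display_problem_rate: float = 0.01

    master_seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1 or self.days < 1 or self.probes_per_day < 1:
            raise ParameterError("counts must be positive")
        lo, hi = self.gap_range_minutes
        if not (0 < lo <= hi):
            raise ParameterError("gap range must satisfy 0 < lo <= hi")
        if hi >= WINDOW_HOURS * 60:
            raise ParameterError("maximum gap exceeds the daily window")
        if (self.probes_per_day - 1) * lo >= WINDOW_HOURS * 60:
            raise ParameterError("probes_per_day x min gap cannot fit the daily window")
        if self.window_start_hour is not None and self.window_start_hour not in WINDOW_START_HOURS:
            raise ParameterError(f"window_start_hour must be in {WINDOW_START_HOURS}")
        for name in ("not_baseline", "not_amplitude", "drop_rate_per_day", "drop_recovery_hours",
                     "not_noise_sd", "control_noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if not 0 < self.drop_depth <= 1:
            raise ParameterError("drop_depth must be in (0, 1]")
        if not 0 <= self.control_baseline <= 1:
            raise ParameterError("control_baseline must be in [0, 1]")
        if self.period_hours <= 0:
            raise ParameterError("period_hours must be positive")

    def probes_per_participant(self) -> int:
        return self.days * self.probes_per_day + self.extra_last_day

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        d = dict(d)
        if "gap_range_minutes" in d:
            d["gap_range_minutes"] = tuple(d["gap_range_minutes"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gap_range_minutes"] = list(d["gap_range_minutes"])
        return d

    def with_tied_drops(self, **overrides) -> "SimParams":
        """Variant in which mind wandering is triggered purely by sharp
        control-drop events.

        Drops become frequent, deep, and fast-recovering; the control
        threshold tightens so essentially only in-drop probes qualify; the
        thought-generation gate and the control/thought-cycle coupling are
        switched off so drops are the sole event-locked structure; control
        noise shrinks; and non-same ratings are common (and mostly "much")
        outside drops, giving every participant a stable extreme-response
        floor.  This is the configuration used to validate that the
        event-locked control signal — the R-percentile minimum — localizes
        to the reference bin.
        """
        return replace(
            self,
            drop_rate_per_day=8.0,
            drop_depth=0.9,
            drop_recovery_hours=1.25,
            mw_control_threshold=0.35,
            mw_not_threshold=0.0,
            coordination_gain=0.0,
            control_noise_sd=0.12,
            nonsame_intercept=-6.2,
            nonsame_much_prob=0.8,
            **overrides,
        )


def participant_rng(master_seed: int, index: int) -> np.random.Generator:
    """Independent, reproducible stream for participant ``index``."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, index)))


# ----------------------------------------------------------------------
# probing schedule


def make_schedule(params: SimParams, rng: np.random.Generator,
                  window_start_hour: int) -> pd.DatetimeIndex:
    """Draw one participant's probe timestamps.

    Per day: a uniform integer start offset inside the 12-h window followed
    by cumulative integer gaps in ``gap_range_minutes``; any draw whose last
    probe would spill past the window end is rejected and redrawn wholesale.
    The final day carries ``extra_last_day`` additional probes.

    Gaps are a mixture of mostly long spreading gaps with occasional short
    follow-ups (85% uniform over the top of the gap range, 15% uniform
    below one hour).  This reproduces the coverage an experience-sampling
    schedule aims for — five probes spanning most of the 12-h window while
    adjacent-hour pairs still occur — whereas i.i.d. uniform gaps would
    clump the probes into a ~5-h stretch and starve the outer event-locked
    bins.
    """
    params.validate()
    lo, hi = params.gap_range_minutes
    window_min = WINDOW_HOURS * 60
    times: list[datetime] = []
    for day in range(params.days):
        n = params.probes_per_day + (params.extra_last_day if day == params.days - 1 else 0)
        if (n - 1) * lo >= window_min:
            raise ParameterError("daily probe count cannot fit the window at the minimum gap")
        short_hi = min(60, hi)
        long_lo = max(lo, hi - 44)
        for _attempt in range(10_000):
            start = int(rng.integers(0, window_min))
            short = rng.random(n - 1) < 0.15
            gaps = np.where(
                short,
                rng.integers(lo, short_hi + 1, size=n - 1),
                rng.integers(long_lo, hi + 1, size=n - 1),
            )
            offsets = start + np.concatenate([[0], np.cumsum(gaps)])
            if offsets[-1] < window_min:
                break
        else:  # pragma: no cover - reachable only with near-infeasible params
            raise ParameterError("could not place the daily probes inside the window")
        day_start = START_DATE + timedelta(days=day, hours=window_start_hour)
        times.extend(day_start + timedelta(minutes=int(m)) for m in offsets)
    return pd.DatetimeIndex(times)


# ----------------------------------------------------------------------
# latent processes


@dataclass
class LatentTrace:
    """Latent processes evaluated at a set of times."""

    times: pd.DatetimeIndex
    lam: np.ndarray        # thought-generation intensity, >= 0
    control: np.ndarray    # cognitive-control level, in [0, 1]
    phase: float
    drop_times: np.ndarray  # hours since START_DATE


def _hours_since_start(times: pd.DatetimeIndex) -> np.ndarray:
    return np.asarray((times - START_DATE).total_seconds(), dtype=float) / 3600.0


def simulate_latent(params: SimParams, times: pd.DatetimeIndex,
                    rng: np.random.Generator, *, phase: float | None = None,
                    drop_times: np.ndarray | None = None) -> LatentTrace:
    """Evaluate the latent thought-generation and control processes at ``times``.

    Control drops arrive as a homogeneous Poisson process over the whole
    sampling span; each subtracts ``drop_depth`` from control, decaying
    linearly to zero over ``drop_recovery_hours``.  ``drop_times`` (hours
    since the start of the fortnight) can be injected instead of drawn.
    """
    params.validate()
    if not times.is_monotonic_increasing:
        raise ParameterError("times must be sorted")
    t = _hours_since_start(times)
    if phase is None:
        phase = params.phase if params.phase is not None else float(rng.uniform(0, 2 * np.pi))

    if drop_times is None:
        span_hours = params.days * 24.0
        n_drops = rng.poisson(params.drop_rate_per_day * params.days)
        drop_times = np.sort(rng.uniform(0, span_hours, size=n_drops))
    else:
        drop_times = np.sort(np.asarray(drop_times, dtype=float))

    cyc = np.sin(2 * np.pi * t / params.period_hours + phase)
    lam = params.not_baseline + params.not_amplitude * cyc
    if params.not_noise_sd > 0:
        lam = lam + rng.normal(0, params.not_noise_sd, size=len(t))
    lam = np.maximum(lam, 0.0)

    control = params.control_baseline + params.coordination_gain * cyc
    if len(drop_times):
        dt = t[:, None] - drop_times[None, :]
        kern = np.where(
            (dt >= 0) & (dt < params.drop_recovery_hours),
            params.drop_depth * (1 - dt / params.drop_recovery_hours),
            0.0,
        )
        control = control - kern.sum(axis=1)
    if params.control_noise_sd > 0:
        control = control + rng.normal(0, params.control_noise_sd, size=len(t))
    control = np.clip(control, 0.0, 1.0)

    return LatentTrace(times=times, lam=lam, control=control, phase=phase,
                       drop_times=drop_times)


# ----------------------------------------------------------------------
# probe responses


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def emit_probe_responses(latent: LatentTrace, params: SimParams,
                         rng: np.random.Generator, participant_id: str,
                         window_start_hour: int) -> tuple[pd.DataFrame, dict]:
    """Turn latent values at probe times into observed probe records.

    Returns the records (dialect columns) and the per-probe ground truth.
    """
    n = len(latent.times)
    if len(latent.lam) != n or len(latent.control) != n:
        raise ParameterError("latent/schedule length mismatch")

    lam, c = latent.lam, latent.control
    true_mw = (lam >= params.mw_not_threshold) & (c <= params.mw_control_threshold)
    with_task = rng.random(n) < params.mw_with_task_prob
    state = np.where(true_mw, np.where(with_task, "mw_with_task", "mw_without_task"), "focused")

    not_report = np.minimum(rng.poisson(lam), 10)

    p_nonsame = _logistic(params.nonsame_intercept + params.nonsame_slope * c)
    nonsame = rng.random(n) < p_nonsame
    much = rng.random(n) < params.nonsame_much_prob
    farther = rng.random(n) < params.nonsame_farther_prob
    score = np.where(nonsame, np.where(much, 2, 1) * np.where(farther, 1, -1), 0)
    rating = np.array(RATINGS, dtype=object)[score + 2]

    declined = rng.random(n) < params.decline_rate
    alcohol = ~declined & (rng.random(n) < params.alcohol_rate)
    display = ~declined & (rng.random(n) < params.display_problem_rate)

    records = pd.DataFrame(
        {
            "participant_id": participant_id,
            "timestamp": latent.times,
            "state": np.where(declined, "declined", state),
            "not_report": pd.array(np.where(declined, -1, not_report), dtype="Int64"),
            "rating": pd.array(np.where(declined, None, rating), dtype="object"),
            "alcohol_flag": alcohol,
            "display_problem_flag": display,
            "window_start_hour": window_start_hour,
        }
    )
    records.loc[declined, "not_report"] = pd.NA
    records["rating"] = records["rating"].where(records["rating"].notna(), pd.NA)

    truth = {
        "participant_id": participant_id,
        "phase": latent.phase,
        "period_hours": params.period_hours,
        "drop_times_hours": latent.drop_times.tolist(),
        "probes": [
            {
                "timestamp": ts.isoformat(timespec="minutes"),
                "lambda": float(l),
                "control": float(cc),
                "true_mw": bool(m),
            }
            for ts, l, cc, m in zip(latent.times, lam, c, true_mw)
        ],
    }
    return records, truth


# ----------------------------------------------------------------------
# full cohort


@dataclass
class GroundTruth:
    """Latent values, true labels and event times for a simulated cohort."""

    params: SimParams
    participants: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {"params": self.params.to_dict(), "participants": self.participants}
        Path(path).write_text(json.dumps(payload, indent=2))


def simulate_cohort(params: SimParams) -> tuple[ProbeTable, GroundTruth]:
    """Generate a full cohort; a pure function of ``(params, master_seed)``."""
    params.validate()
    frames = []
    truth = GroundTruth(params=params)
    for i in range(params.n_participants):
        rng = participant_rng(params.master_seed, i)
        pid = f"P{i + 1:02d}"
        window = (
            params.window_start_hour
            if params.window_start_hour is not None
            else int(rng.choice(WINDOW_START_HOURS))
        )
        schedule = make_schedule(params, rng, window)
        latent = simulate_latent(params, schedule, rng)
        records, ptruth = emit_probe_responses(latent, params, rng, pid, window)
        frames.append(records)
        truth.participants.append(ptruth)
    records = pd.concat(frames, ignore_index=True)
    records = records.sort_values(["participant_id", "timestamp"]).reset_index(drop=True)
    return ProbeTable(records[COLUMNS]), truth
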