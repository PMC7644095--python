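"""Synthetic activity records and arbors with known ground truth.

Sleep/wake is generated as a two-state semi-Markov chain at 1-minute
resolution: an awake fly initiates a sleep bout with a phase-dependent
per-minute probability ``p_init`` (light vs dark), and an asleep fly wakes
with per-minute probability ``1 / bout_len_mean`` for the current phase, so
bout lengths are geometric (memoryless, hence tractable in closed form).
Awake minutes emit Poisson beam counts clamped to >= 1, so an awake minute
can never be misread as sleep; asleep minutes emit 0.

Starvation acts purely on sleep *initiation*: from the first light<->dark
transition after food deprivation begins, ``p_init`` is multiplied by
``starvation_init_multiplier`` in the starved arm.  This reproduces the
effect structure the analysis pipeline must detect — fewer sleep bouts after
the first LD shift with unchanged bout duration.  A duration-effect knob
exists but defaults off.

Arbors are star-shaped polylines rooted at the origin: each branch leaves at
the trunk angle plus Normal(0, spread_sigma) and accumulates per-step
angular noise, so the angular spread of ring crossings — and therefore the
defasciculation index — is controlled by a single known parameter.

All generators are deterministic given their seeds (numpy PCG64); cohorts
derive per-fly seeds from ``SeedSequence((master_seed, arm_index,
fly_index))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dam_io import ActivitySeries
from .errors import ValidationError
from .sleep import (
    DEFAULT_SLEEP_THRESHOLD_MIN,
    ExperimentDesign,
    MINUTES_PER_DAY,
    first_ld_shift,
)
from .sholl import Skeleton


@dataclass
class SleepSimParams:
    """Two-state sleep/wake generator parameters.

    Defaults give a wild-type-like LD pattern: stationary asleep fraction
    0.5 in the light (siesta-weighted) and 0.8 in the dark, ~20/40-min mean
    bouts, and a starvation factor that halves sleep initiation after the
    first post-starvation LD shift.
    """

    p_init_light: float = 0.05
    p_init_dark: float = 0.10
    bout_len_mean_light: float = 20.0
    bout_len_mean_dark: float = 40.0
    starvation_init_multiplier: float = 0.5
    starvation_duration_multiplier: float = 1.0  # scales bout_len_mean post-shift; off by default
    active_count_rate: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_init_light", "p_init_dark"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1)")
        for name in ("bout_len_mean_light", "bout_len_mean_dark"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1 minute")
        if not 0 < self.starvation_init_multiplier <= 1:
            raise ValidationError("starvation_init_multiplier must lie in (0, 1]")
        if self.starvation_duration_multiplier <= 0:
            raise ValidationError("starvation_duration_multiplier must be > 0")
        if self.active_count_rate <= 0:
            raise ValidationError("active_count_rate must be > 0")

    def phase_rates(self, light: bool) -> tuple[float, float]:
        """(p_init, p_exit) for a phase, before any starvation gating."""
        if light:
            return self.p_init_light, 1.0 / self.bout_len_mean_light
        return self.p_init_dark, 1.0 / self.bout_len_mean_dark


@dataclass
class ArborSimParams:
    """Star-shaped arbor generator; ``spread_sigma_deg`` is the ground truth."""

    n_branches: int = 6
    spread_sigma_deg: float = 15.0
    branch_len_um: float = 170.0
    wiggle_deg: float = 1.0
    step_um: float = 1.0
    trunk_angle_deg: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_branches < 1:
            raise ValidationError("n_branches must be >= 1")
        if self.spread_sigma_deg < 0 or self.wiggle_deg < 0:
            raise ValidationError("angular spreads must be >= 0")
        if self.branch_len_um <= 0 or self.step_um <= 0:
            raise ValidationError("lengths must be > 0")


def _minute_rates(
    params: SleepSimParams, design: ExperimentDesign, arm: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-minute (p_init, p_exit) arrays over the whole recording."""
    T = design.total_minutes
    minutes = np.arange(T)
    light = design.is_light(design.zt_of_minute(minutes))
    p = np.where(light, params.p_init_light, params.p_init_dark).astype(float)
    q = np.where(light, 1.0 / params.bout_len_mean_light,
                 1.0 / params.bout_len_mean_dark).astype(float)
    if arm == "starved":
        if design.starvation_start_zt is None:
            raise ValidationError("starved arm requires a starvation start in the design")
        shift = first_ld_shift(design)
        shift_min = design.starvation_start_min + int(round(shift.st_hours * 60))
        gate = minutes >= shift_min
        p = np.where(gate, p * params.starvation_init_multiplier, p)
        q = np.where(gate, q / params.starvation_duration_multiplier, q)
    elif arm != "fed":
        raise ValidationError(f"arm must be 'fed' or 'starved', got {arm!r}")
    return p, q


def simulate_fly(
    params: SleepSimParams,
    design: ExperimentDesign,
    arm: str = "fed",
    fly_id: str | None = None,
) -> ActivitySeries:
    """Simulate one fly's minute-resolution beam counts.

    The initial state is drawn from the stationary distribution of the
    minute-0 phase (fed rates).  Deterministic given ``params.seed``.
    """
    p, q = _minute_rates(params, design, arm)
    T = design.total_minutes
    rng = np.random.default_rng(params.seed)
    u = rng.random(T)
    # transition loop on plain Python lists: ~5x faster than indexing ndarrays
    pl, ql, ul = p.tolist(), q.tolist(), u.tolist()
    state = ul[0] < pl[0] / (pl[0] + ql[0])
    out = [state] * T
    for t in range(1, T):
        if state:
            if ul[t] < ql[t - 1]:
                state = False
        else:
            if ul[t] < pl[t - 1]:
                state = True
        out[t] = state
    asleep = np.array(out, dtype=bool)
    counts = np.where(asleep, 0, np.maximum(rng.poisson(params.active_count_rate, T), 1))
    start = pd.Timestamp("2021-01-01") + pd.Timedelta(
        hours=design.lights_on_clock.hour + design.recording_start_zt,
        minutes=design.lights_on_clock.minute,
    )
    if fly_id is None:
        fly_id = f"sim_{arm}_seed{params.seed}"
    return ActivitySeries(fly_id=fly_id, start_time=start, counts=counts)


def simulate_cohort(
    params: SleepSimParams,
    design: ExperimentDesign,
    n_per_arm: int,
    seed: int | None = None,
) -> dict[str, list[ActivitySeries]]:
    """Fed and starved arms of independent flies sharing all parameters.

    Per-fly seeds come from ``SeedSequence((seed, arm_index, fly_index))``
    with arm_index 0 = fed, 1 = starved, so the same master seed always
    reproduces the same cohort and arms are mutually independent.
    """
    if n_per_arm < 1:
        raise ValidationError("n_per_arm must be >= 1")
    master = params.seed if seed is None else seed
    out: dict[str, list[ActivitySeries]] = {}
    for arm_idx, arm in enumerate(("fed", "starved")):
        flies = []
        for i in range(n_per_arm):
            sub = int(np.random.SeedSequence((master, arm_idx, i)).generate_state(1)[0] % 2**31)
            flies.append(simulate_fly(
                replace(params, seed=sub), design, arm, fly_id=f"{arm}_{i:03d}"
            ))
        out[arm] = flies
    return out


def _scored_sleep_fraction(p: float, q: float, threshold_min: int) -> float:
    """Stationary fraction of minutes inside scored (>= threshold) sleep bouts.

    Bout lengths are geometric with success probability q, awake dwells
    geometric with probability p.  The per-minute rate of scored sleep is
    E[L * 1(L >= T)] / (E[L] + E[W]) with
    E[L * 1(L >= T)] = T x^(T-1) + x^T / q,  x = 1 - q.
    With T = 1 this reduces to the plain stationary fraction p / (p + q).
    """
    x = 1.0 - q
    T = threshold_min
    el_tail = T * x ** (T - 1) + x ** T / q
    return el_tail / (1.0 / q + 1.0 / p)


def expected_sleep_loss(
    params: SleepSimParams,
    design: ExperimentDesign | None = None,
    window_hours: float = 12.0,
    threshold_min: int = DEFAULT_SLEEP_THRESHOLD_MIN,
) -> float:
    """Closed-form expected loss%, over the post-shift window, from stationarity.

    Phase-weighted over the ``window_hours`` following the first LD shift:
    the fed expectation uses the phase rates as-is, the starved expectation
    applies the starvation multipliers.  The >= threshold scoring truncation
    is included; in a single-phase window with no duration effect it cancels
    from the ratio, recovering 100 * (1 - [p'/(p'+q)] / [p/(p+q)]).
    Edge effects (bouts clipped at window boundaries, relaxation from the
    fed stationary state just after the shift) are neglected.
    """
    design = design or ExperimentDesign(starvation_start_zt=12.0)
    shift = first_ld_shift(design)
    shift_zt = shift.shift_zt
    n_min = int(round(window_hours * 60))
    zts = (shift_zt + (np.arange(n_min) + 0.5) / 60.0) % 24.0
    light = design.is_light(zts)

    fed = np.empty(n_min)
    starved = np.empty(n_min)
    for phase in (True, False):
        m = light == phase
        if not m.any():
            continue
        p, q = params.phase_rates(phase)
        fed[m] = _scored_sleep_fraction(p, q, threshold_min)
        starved[m] = _scored_sleep_fraction(
            p * params.starvation_init_multiplier,
            q / params.starvation_duration_multiplier,
            threshold_min,
        )
    fed_mean = float(fed.mean())
    starved_mean = float(starved.mean())
    return 100.0 * (fed_mean - starved_mean) / fed_mean


def stationary_asleep_fraction(params: SleepSimParams, light: bool) -> float:
    """Plain (un-truncated) stationary asleep fraction p / (p + q) for a phase."""
    p, q = params.phase_rates(light)
    return p / (p + q)


def generate_arbor(params: ArborSimParams) -> Skeleton:
    """Star-shaped arbor rooted at the origin with known angular spread.

    Branch i leaves the root at ``trunk_angle + Normal(0, spread_sigma)``;
    each subsequent step of ``step_um`` adds ``Normal(0, wiggle)`` degrees.
    With zero spread and wiggle every branch is a straight ray of
    ``branch_len_um``, long enough (default 170 um) to cross all 15 default
    rings.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    n_steps = max(1, int(round(params.branch_len_um / params.step_um)))
    branches = []
    for _ in range(params.n_branches):
        theta0 = params.trunk_angle_deg + params.spread_sigma_deg * rng.standard_normal()
        steps = np.full(n_steps, theta0)
        if n_steps > 1:
            steps[1:] += np.cumsum(params.wiggle_deg * rng.standard_normal(n_steps - 1))
        rad = np.radians(steps)
        deltas = params.step_um * np.column_stack([np.cos(rad), np.sin(rad)])
        pts = np.vstack([[0.0, 0.0], np.cumsum(deltas, axis=0)])
        branches.append(pts)
    return Skeleton(root=np.zeros(2), branches=branches)
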