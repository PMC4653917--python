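"""Stochastic model worm for acidic-pH avoidance.

The model worm is a point moving at constant speed on a virtual plate with a
1-D acidic pH gradient (see :mod:`acidnav.gradient`).  It carries a pH
sensor ahead of its positional point, swung alternately left and right each
time step.  Two reorientation maneuvers — the gradual *curve* (klinotaxis)
and the abrupt *reversal* (klinokinesis) — fire stochastically as functions
of the sensed pH ``C``::

    p_curve(C)    = 1 / (1 + exp((C - beta_c) / alpha_c))
    p_reversal(C) = 1 / (1 + exp((C - beta_r) / alpha_r))

Each sigmoid encodes a soft pH threshold: ``beta`` is the center (the pH at
which the maneuver fires with per-step probability 1/2) and ``alpha`` the
width of the transition.  With ``beta_r < beta_c`` the curve threshold sits
in less acidic territory than the reversal threshold, which is the
two-distinct-threshold hypothesis this model embodies: a worm grazing the
acid at a shallow angle escapes by curving before it ever reaches the
reversal threshold, while a worm driving in head-on overshoots into reversal
territory.

A trial ends when a reorientation leaves the worm heading away from the acid;
the maneuver that achieved this, the heading just before it, and the signed
border distance at that moment are the observables every downstream statistic
is built on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

from .gradient import GradientField

__all__ = [
    "DecisionParams",
    "SimConfig",
    "WormState",
    "TrialResult",
    "PUBLISHED_OPTIMUM",
    "p_curve",
    "p_reversal",
    "sample_initial_direction",
    "initial_direction_cdf",
    "sensor_position",
    "decide",
    "apply_reorientation",
    "run_trial",
    "run_cohort",
]

Maneuver = Literal["curve", "reversal"]
Side = Literal["left", "right"]

# Exponent clip keeping exp() finite; sigmoid saturates to 0/1 beyond.
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class DecisionParams:
    """Parameters of the two sigmoid decision functions.

    ``alpha_c``/``beta_c`` are the width and center (pH units) of the curve
    probability, ``alpha_r``/``beta_r`` those of the reversal probability.
    ``phi_c``/``dphi_c`` are the mean and SD (degrees) of the curve
    reorientation magnitude.
    """

    alpha_c: float
    beta_c: float
    alpha_r: float
    beta_r: float
    phi_c: float
    dphi_c: float

    def __post_init__(self) -> None:
        if self.alpha_c <= 0:
            raise ValueError(f"alpha_c must be > 0, got {self.alpha_c}")
        if self.alpha_r <= 0:
            raise ValueError(f"alpha_r must be > 0, got {self.alpha_r}")
        if self.dphi_c < 0:
            raise ValueError(f"dphi_c must be >= 0, got {self.dphi_c}")
        if self.beta_r >= self.beta_c:
            warnings.warn(
                "beta_r >= beta_c: the reversal threshold is not more acidic "
                "than the curve threshold; the two-threshold ordering is "
                "inverted",
                stacklevel=2,
            )


#: The optimal parameter set selected by the published grid search: alpha_c 0.5,
#: beta_c 4.3, alpha_r 0.5, beta_r = beta_c - 1.6, phi_c 30, dphi_c 10.
PUBLISHED_OPTIMUM = DecisionParams(
    alpha_c=0.5, beta_c=4.3, alpha_r=0.5, beta_r=2.7, phi_c=30.0, dphi_c=10.0
)


@dataclass(frozen=True)
class SimConfig:
    """Kinematic constants and per-trial protocol settings.

    Defaults are the measured worm constants: speed 0.15 mm/s, a 0.8 s update
    interval, and a pH sensor 0.51 mm ahead of the positional point.  The
    sensor swings alternately ±``sensor_swing_deg`` off the heading each step
    (amplitude is a modeling knob; the alternation is what lets a curve pick
    its turning side by comparing the two most recent samples).  Reversals
    reorient by Normal(137°, 8°); initial x is uniform on
    ``[init_x_min, init_x_max)`` on the less acidic side.
    """

    speed: float = 0.15
    dt: float = 0.8
    sensor_offset: float = 0.51
    sensor_swing_deg: float = 30.0
    reversal_mean_deg: float = 137.0
    reversal_sd_deg: float = 8.0
    init_x_max: float = -2.0
    init_x_min: Optional[float] = None
    max_steps: int = 10000
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.sensor_offset < 0:
            raise ValueError("sensor_offset must be >= 0")
        if self.max_steps <= 0:
            raise ValueError("max_steps must be > 0")
        if self.init_x_max >= 0:
            raise ValueError("init_x_max must be < 0 (less acidic side)")
        if self.init_x_min is None:
            object.__setattr__(self, "init_x_min", self.init_x_max - 1.0)
        if self.init_x_min >= self.init_x_max:
            raise ValueError("init_x_min must be < init_x_max")


@dataclass
class WormState:
    """Instantaneous state: position (mm), heading (degrees), sensor side.

    Heading is measured from the border normal; 0° points straight into the
    acid (+x), normalized to (−180°, 180°].
    """

    x: float = 0.0
    y: float = 0.0
    heading_deg: float = 0.0
    step_index: int = 0
    swing_side: Side = "left"
    last_sample: Optional[float] = None


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one trial: the terminal maneuver and where/how it happened.

    ``signed_distance`` is the x coordinate (border distance) immediately
    before the terminal reorientation; ``heading_before`` the heading then.
    ``terminated`` is "escaped" for a successful avoidance, "step_cap" if the
    step budget ran out first.
    """

    maneuver: Optional[Maneuver]
    final_position: tuple[float, float]
    heading_before: float
    signed_distance: float
    elapsed_s: float
    steps: int
    path_length_mm: float
    terminated: Literal["escaped", "step_cap"]


def _sigmoid(c: float, alpha: float, beta: float) -> float:
    z = (c - beta) / alpha
    if z > _EXP_CLIP:
        return 0.0
    if z < -_EXP_CLIP:
        return 1.0
    return 1.0 / (1.0 + math.exp(z))


def p_curve(C: float, params: DecisionParams) -> float:
    """Per-step curve probability at sensed pH ``C`` (decreasing sigmoid)."""
    return _sigmoid(C, params.alpha_c, params.beta_c)


def p_reversal(C: float, params: DecisionParams) -> float:
    """Per-step reversal probability at sensed pH ``C`` (decreasing sigmoid)."""
    return _sigmoid(C, params.alpha_r, params.beta_r)


def normalize_heading(deg: float) -> float:
    """Wrap a heading into (−180°, 180°]."""
    r = deg % 360.0
    return r - 360.0 if r > 180.0 else r


def sample_initial_direction(rng: np.random.Generator) -> float:
    """Draw the initial heading θ₀ in (−90°, 90°] with density ∝ 1 − |sin θ|.

    The density is maximal head-on (θ = 0) and vanishes for border-parallel
    headings, emulating the encounter-angle frequencies of worms crossing a
    straight border.  Rejection sampling against the uniform envelope on
    (−90°, 90°]; the 1 − |sin| density is bounded by 1 so acceptance is
    (π − 2)/π ≈ 0.36.
    """
    while True:
        theta = rng.uniform(-90.0, 90.0)
        if rng.random() < 1.0 - abs(math.sin(math.radians(theta))):
            return theta if theta != -90.0 else 90.0


def initial_direction_cdf(theta_deg):
    """Analytic CDF of the normalized 1 − |sin θ| density on (−90°, 90°].

    Vectorized over ``theta_deg``; used as the goodness-of-fit reference for
    :func:`sample_initial_direction`.
    """
    t = np.radians(np.asarray(theta_deg, dtype=float))
    t = np.clip(t, -np.pi / 2, np.pi / 2)
    half = np.pi / 2 - 1.0  # integral of 1-|sin| over one half-range
    tail = np.abs(t) - (1.0 - np.cos(t))  # integral from 0 to |t|
    return (half + np.sign(t) * tail) / (np.pi - 2.0)


def sensor_position(state: WormState, cfg: SimConfig) -> tuple[float, float]:
    """Plate position of the pH sensor for the current swing side.

    The sensor sits ``sensor_offset`` mm from the positional point along the
    heading rotated by +swing (left) or −swing (right); right is toward −y
    when heading along +x.
    """
    swing = cfg.sensor_swing_deg if state.swing_side == "left" else -cfg.sensor_swing_deg
    ang = math.radians(state.heading_deg + swing)
    return (
        state.x + cfg.sensor_offset * math.cos(ang),
        state.y + cfg.sensor_offset * math.sin(ang),
    )


def decide(
    C: float, params: DecisionParams, rng: np.random.Generator
) -> Optional[Maneuver]:
    """One decision step: two independent Bernoulli draws, reversal wins ties.

    Returns "reversal" with probability p_r, "curve" with probability
    p_c·(1 − p_r), else None.
    """
    if rng.random() < p_reversal(C, params):
        return "reversal"
    if rng.random() < p_curve(C, params):
        return "curve"
    return None


def apply_reorientation(
    state: WormState,
    kind: Maneuver,
    params: DecisionParams,
    cfg: SimConfig,
    rng: np.random.Generator,
    side_hint: Optional[Side] = None,
) -> WormState:
    """Rotate the heading in place for one reorientation maneuver.

    Reversal magnitude ~ Normal(reversal_mean_deg, reversal_sd_deg) with the
    side chosen uniformly at random; curve magnitude ~ Normal(phi_c, dphi_c)
    toward ``side_hint`` (the less acidic side, supplied by the caller).
    Position does not change: reorientations are instantaneous.
    """
    if kind == "reversal":
        mag = rng.normal(cfg.reversal_mean_deg, cfg.reversal_sd_deg)
        side: Side = "left" if rng.random() < 0.5 else "right"
    else:
        mag = rng.normal(params.phi_c, params.dphi_c)
        if side_hint is None:
            side = "left" if rng.random() < 0.5 else "right"
        else:
            side = side_hint
    delta = mag if side == "left" else -mag
    state.heading_deg = normalize_heading(state.heading_deg + delta)
    return state


def _other(side: Side) -> Side:
    return "right" if side == "left" else "left"


def run_trial(
    field: GradientField,
    params: DecisionParams,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> TrialResult:
    """Run one model worm until it reorients away from the acid.

    Protocol: start at x ~ U[init_x_min, init_x_max), y = 0, heading from the
    1 − |sin θ| density.  Each step the worm advances speed·dt along its
    heading, the sensor swings to the other side, the sensed pH feeds
    :func:`decide`.  A curve turns toward the side whose sample among the two
    most recent (this step vs the previous, i.e. opposite swing sides) was
    less acidic; ties and first-step curves pick a side uniformly.  After any
    reorientation, the trial ends if the new heading points away from the
    acid (cos(heading) < 0).  Hitting ``max_steps`` flags the trial as
    step-capped rather than dropping it.
    """
    speed_dt = cfg.speed * cfg.dt
    state = WormState(
        x=rng.uniform(cfg.init_x_min, cfg.init_x_max),
        y=0.0,
        heading_deg=sample_initial_direction(rng),
        swing_side="left" if rng.random() < 0.5 else "right",
    )
    path = 0.0
    prev_C: Optional[float] = None
    for step in range(1, cfg.max_steps + 1):
        h = math.radians(state.heading_deg)
        dx = speed_dt * math.cos(h)
        dy = speed_dt * math.sin(h)
        state.x += dx
        state.y += dy
        path += math.hypot(dx, dy)
        state.step_index = step
        state.swing_side = _other(state.swing_side)
        sx, _sy = sensor_position(state, cfg)
        C = field.ph_at_distance(sx)
        outcome = decide(C, params, rng)
        if outcome is not None:
            side_hint: Optional[Side] = None
            if outcome == "curve" and prev_C is not None and C != prev_C:
                # sensor alternates sides, so "this sample vs the previous"
                # is "this side vs the other"; turn toward the higher pH
                side_hint = state.swing_side if C > prev_C else _other(state.swing_side)
            heading_before = state.heading_deg
            x_before, y_before = state.x, state.y
            apply_reorientation(state, outcome, params, cfg, rng, side_hint)
            if math.cos(math.radians(state.heading_deg)) < 0.0:
                return TrialResult(
                    maneuver=outcome,
                    final_position=(x_before, y_before),
                    heading_before=heading_before,
                    signed_distance=x_before,
                    elapsed_s=step * cfg.dt,
                    steps=step,
                    path_length_mm=path,
                    terminated="escaped",
                )
        state.last_sample = C
        prev_C = C
    return TrialResult(
        maneuver=None,
        final_position=(state.x, state.y),
        heading_before=state.heading_deg,
        signed_distance=state.x,
        elapsed_s=cfg.max_steps * cfg.dt,
        steps=cfg.max_steps,
        path_length_mm=path,
        terminated="step_cap",
    )


def encounter_angle(heading_before_deg: float) -> float:
    """Acute angle (degrees, [0, 90]) between a heading and the border line.

    0° is border-parallel, 90° a head-on, perpendicular encounter.
    """
    a = abs(normalize_heading(heading_before_deg))
    if a > 90.0:
        a = 180.0 - a  # fold headings pointing away from the acid
    return 90.0 - a


def run_cohort(
    n: int,
    field: GradientField,
    params: DecisionParams,
    cfg: SimConfig,
    seed: int,
) -> pd.DataFrame:
    """Run ``n`` independent trials and tabulate one avoidance event each.

    Each trial gets its own random stream derived from ``(seed, trial
    index)``, so cohorts are reproducible and order-independent.  The table
    has columns trial_id, maneuver, angle_deg (encounter angle), distance_mm
    (signed border distance), elapsed_s and terminated; step-capped trials
    appear with maneuver "none" and terminated "step_cap" and are excluded
    from statistics by default.  ``df.attrs["n_step_capped"]`` records the
    cap count.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rows = []
    n_capped = 0
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        res = run_trial(field, params, cfg, rng)
        if res.terminated == "step_cap":
            n_capped += 1
        rows.append(
            (
                i,
                res.maneuver if res.maneuver is not None else "none",
                encounter_angle(res.heading_before),
                res.signed_distance,
                res.elapsed_s,
                res.terminated,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=["trial_id", "maneuver", "angle_deg", "distance_mm", "elapsed_s", "terminated"],
    )
    df.attrs["n_step_capped"] = n_capped
    return df
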