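"""Synthetic inputs for the full pipeline.

The original behavioral recordings are not deposited, so testing the
statistics pipeline end to end needs stand-ins with the same structure:

* measured-style gradient profiles — six 1-mm agar strips spanning −3 to
  +3 mm around the acidic border, pH 4.0 on the border, configurable
  steepness, small measurement jitter that never breaks monotonicity;
* real-worm-style avoidance event tables — encounter angles with the
  flux-weighted frequency of border crossings, an angle-dependent logistic
  choice between reversal and curve, maneuver-specific signed distances
  (curve firing in less acidic territory than reversal), and
  serial-avoidance runs with geometric length.

All generated tables are synthetic: they emulate the statistical structure
the analysis assumes, not any particular recorded worm.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd

from .gradient import GradientProfile
from .simulate import sample_initial_direction

__all__ = ["SyntheticEventModel", "generate_gradient_profile", "generate_event_table"]

_STRIP_CENTERS = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)


def generate_gradient_profile(
    steepness: float,
    seed: int = 0,
    noise: float = 0.05,
    border_ph: float = 4.0,
    label: str = "",
) -> GradientProfile:
    """Emulate six measured agar strips around the acidic border.

    Strip centers sit at −2.5 … +2.5 mm (six 1-mm strips spanning −3 to
    +3 mm); the underlying profile is linear with the given ``steepness``
    (pH per mm) anchored at ``border_ph`` on the border, plus uniform
    measurement jitter of ±``noise`` pH units.  Monotonicity is re-enforced
    after jittering (pH sorted non-increasing), so the profile always feeds
    :func:`acidnav.gradient.fit_gradient` without error.
    """
    if steepness <= 0:
        raise ValueError("steepness must be > 0")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    d = np.array(_STRIP_CENTERS)
    ph = border_ph - steepness * d + rng.uniform(-noise, noise, size=d.size)
    ph = np.sort(ph)[::-1]  # jitter must not break monotone decrease
    return GradientProfile(tuple(zip(d.tolist(), ph.tolist())), label=label)


@dataclass(frozen=True)
class SyntheticEventModel:
    """Generative model for real-worm-style avoidance event tables.

    ``n_events`` counts serial-avoidance runs (first occurrences); each run
    continues with probability ``serial_p`` per extra event, so the table may
    be longer.  P(reversal | angle) = logistic(intercept + slope·angle_deg).
    Signed distances are Normal(mu, sigma) per maneuver, truncated to
    ±``span`` mm; ``mu_curve < mu_rev`` encodes that curves fire in less
    acidic territory than reversals.
    """

    n_events: int = 500
    intercept: float = -4.0
    slope: float = 0.08  # logit per degree: ratio ~0.02 at 0deg, ~0.95 at 90deg
    mu_rev: float = 0.4
    mu_curve: float = -0.6
    sigma: float = 0.3
    serial_p: float = 0.2
    span: float = 3.0
    n_worms: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        if not self.mu_curve < self.mu_rev:
            raise ValueError("mu_curve must be < mu_rev (distance ordering)")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 <= self.serial_p < 1.0:
            raise ValueError("serial_p must be in [0, 1)")
        if self.span <= 0:
            raise ValueError("span must be > 0")


def _truncated_normal(
    rng: np.random.Generator, mu: float, sigma: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = rng.normal(mu, sigma)
        if lo <= x <= hi:
            return x
    return float(np.clip(mu, lo, hi))


def generate_event_table(model: SyntheticEventModel) -> pd.DataFrame:
    """Draw a synthetic avoidance-event table from the generative model.

    Columns: worm_id, time_s, angle_deg, distance_mm, maneuver (fine labels:
    long/short reversal, gradual/deep curve), sequence_index.  Encounter
    angles are 90° − |θ| with θ drawn from the 1 − |sin θ| heading density —
    the flux-weighted frequency with which headings cross a straight border.
    Fully determined by ``model.seed``.
    """
    rng = np.random.default_rng(model.seed)
    rows = []
    t = 0.0
    for run in range(model.n_events):
        worm = f"w{run % model.n_worms}"
        seq = 1
        while True:
            theta = sample_initial_direction(rng)
            angle = 90.0 - abs(theta)
            logit = model.intercept + model.slope * angle
            p_rev = 1.0 / (1.0 + np.exp(-logit))
            if rng.random() < p_rev:
                maneuver = "long_reversal" if rng.random() < 0.5 else "short_reversal"
                mu = model.mu_rev
            else:
                maneuver = "gradual_curve" if rng.random() < 0.9 else "deep_curve"
                mu = model.mu_curve
            dist = _truncated_normal(rng, mu, model.sigma, -model.span, model.span)
            t += rng.uniform(1.0, 30.0)
            rows.append((worm, t, angle, dist, maneuver, seq))
            if rng.random() >= model.serial_p:
                break
            seq += 1
    return pd.DataFrame(
        rows,
        columns=[
            "worm_id",
            "time_s",
            "angle_deg",
            "distance_mm",
            "maneuver",
            "sequence_index",
        ],
    )
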