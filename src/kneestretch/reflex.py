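"""The spasticity model: a delayed, purely velocity-dependent stretch-reflex
controller.

Whenever the target muscle's fiber lengthening velocity exceeded the
threshold T a delay t_d earlier, the controller imposes a muscle excitation
proportional to that (delayed) velocity:

    E(t) = G * v(t - t_d)   if v(t - t_d) > T,   else 0

clamped into [0, 1] because excitation is a normalised neural drive.  The
delay (default 30 ms) represents the shortest stretch-reflex loop time; the
gain G grades reflex severity and is swept over {0, 1, 2, 4} per subject.
Velocities are in m/s, lengthening positive (with a rigid tendon, fiber
velocity equals muscle-tendon velocity, matching how T is estimated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = ["ReflexParams", "reflex_excitation", "reflex_excitation_delayed",
           "gain_grid", "GAIN_GRID"]

logger = logging.getLogger(__name__)

GAIN_GRID = (0.0, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class ReflexParams:
    """Gain G (s/m), threshold T (m/s), delay t_d (s)."""

    G: float
    T: float
    t_d: float = 0.030
    target_muscle: str = "HAM"
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.G < 0:
            raise ValueError("gain must be non-negative")
        if self.t_d < 0:
            raise ValueError("delay must be non-negative")
        if not np.isfinite(self.T):
            raise ValueError("threshold must be finite")


def reflex_excitation(v_delayed: float, params: ReflexParams) -> float:
    """Excitation from the (already delayed) fiber velocity sample.

    Zero at or below threshold — the piecewise law is a strict inequality —
    otherwise ``G*v`` clamped into [0, 1].
    """
    if not params.enabled or v_delayed <= params.T:
        return 0.0
    return float(np.clip(params.G * v_delayed, 0.0, 1.0))


def reflex_excitation_delayed(t_history, v_history, t: float,
                              params: ReflexParams) -> float:
    """Excitation at time ``t`` from a recorded velocity history.

    The velocity at ``t - t_d`` is linearly interpolated from the history;
    while the history is shorter than the delay the controller is in its
    warm-up and outputs 0.
    """
    th = np.asarray(t_history, dtype=float)
    if not params.enabled or params.G == 0.0:
        return 0.0
    t_eval = t - params.t_d
    if len(th) == 0 or t_eval < th[0]:
        logger.debug("reflex warm-up at t=%.4f s: history starts %.4f s",
                     t, th[0] if len(th) else np.nan)
        return 0.0
    v = float(np.interp(t_eval, th, np.asarray(v_history, dtype=float)))
    return reflex_excitation(v, params)


def gain_grid(base: ReflexParams,
              gains: Sequence[float] = GAIN_GRID) -> list[ReflexParams]:
    """The per-subject gain sweep: copies of ``base`` differing only in G.

    G = 0 is equivalent to the controller being disabled (no spasticity).
    """
    return [replace(base, G=float(g)) for g in gains]
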