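"""Piecewise linear spline basis with subject-specific knots and a periodicity
constraint.

Time is measured in half-hour units since 12:00 noon, so a full 24-h record
spans ``t in [0, 48]``.  The day is split into five segments by four interior
knots: two common clock-time knots (default 18:00 and 04:00, i.e. t=12 and
t=32) and two subject-specific knots taken from the diary (sleep onset,
between the common knots, and wake time, after the second common knot).

Each segment ``k`` contributes a "broken stick" regressor

    s_k(t) = clamp(t - left_boundary_k, 0, w_k)

which is zero before the segment, grows linearly at unit rate inside it, and
saturates at the segment width ``w_k`` afterwards.  A mean curve
``b0 + sum_k beta_k s_k(t)`` is then continuous and piecewise linear with
slope ``beta_k`` (units: mmHg per 30 min) on segment k.

The periodicity constraint requires the modelled change over the full cycle
to vanish, ``sum_k w_k beta_k = 0``.  Solving for the first-segment slope,

    beta_1 = -(sum_{k>=2} w_k beta_k) / w_1,

and substituting back yields the transformed basis

    s*_k(t) = s_k(t) - (w_k / w_1) s_1(t),   k = 2..5,

in which every column vanishes at both t=0 and t=48, so any coefficient
vector produces a curve that closes on itself over 24 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KnotSet",
    "make_knots",
    "eval_splines",
    "constrain",
    "derive_first_slope",
    "design_rows",
]

#: default common knots: 18:00 and 04:00 in half-hours since noon
DEFAULT_COMMON_KNOTS = (12.0, 32.0)

T_START = 0.0
T_END = 48.0


@dataclass(frozen=True)
class KnotSet:
    """Ordered segment boundaries for one subject.

    ``boundaries`` is ``[0, common1, sleep, common2, wake, 48]`` and
    ``widths[k] = boundaries[k+1] - boundaries[k]`` for the five segments
    12:00->18:00, 18:00->sleep, sleep->04:00, 04:00->wake, wake->12:00.
    """

    boundaries: tuple[float, ...]
    widths: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        b = np.asarray(self.boundaries, dtype=float)
        if b.ndim != 1 or b.size < 3:
            raise ValueError("need at least one interior knot")
        if b[0] != T_START or b[-1] != T_END:
            raise ValueError(f"boundaries must span [{T_START}, {T_END}]")
        if np.any(np.diff(b) <= 0):
            raise ValueError(f"knot ordering violated: {self.boundaries}")
        object.__setattr__(self, "widths", tuple(np.diff(b)))

    @property
    def n_segments(self) -> int:
        return len(self.widths)

    @property
    def sleep_time(self) -> float:
        return self.boundaries[2]

    @property
    def wake_time(self) -> float:
        return self.boundaries[4]


def make_knots(
    wake_time: float,
    sleep_time: float,
    common_knots: tuple[float, float] = DEFAULT_COMMON_KNOTS,
) -> KnotSet:
    """Build a subject's five-segment knot set from diary times.

    Enforces the ordering ``common1 < sleep < common2 < wake < 48``;
    violations raise rather than silently re-ordering, because re-ordering
    would change what each segment (and its reported slope) means.
    """
    c1, c2 = common_knots
    if not (T_START < c1 < c2 < T_END):
        raise ValueError(f"common knots {common_knots} must lie inside (0, 48) in order")
    if not (c1 < sleep_time < c2):
        raise ValueError(
            f"knot ordering violated: sleep_time={sleep_time} not in ({c1}, {c2})"
        )
    if not (c2 < wake_time < T_END):
        raise ValueError(
            f"knot ordering violated: wake_time={wake_time} not in ({c2}, {T_END})"
        )
    return KnotSet((T_START, c1, float(sleep_time), c2, float(wake_time), T_END))


def eval_splines(t: float | np.ndarray, knots: KnotSet) -> np.ndarray:
    """Evaluate s_1..s_n at time(s) ``t`` (half-hour units in [0, 48]).

    Returns shape ``(n_segments,)`` for scalar ``t`` or ``(len(t), n_segments)``
    for an array.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < T_START) or np.any(t_arr > T_END):
        raise ValueError(f"time outside [{T_START}, {T_END}]: {t}")
    left = np.asarray(knots.boundaries[:-1])
    w = np.asarray(knots.widths)
    s = np.clip(t_arr[..., None] - left, 0.0, w)
    return s


def constrain(s: np.ndarray, knots: KnotSet) -> np.ndarray:
    """Transform basis rows to the periodicity-constrained basis.

    ``s*_k = s_k - (w_k/w_1) s_1`` for k = 2..n; the first column is
    eliminated.  At t=48 each s_k equals w_k, so every s*_k is exactly zero
    there: predictions close on themselves for any coefficients.
    """
    s = np.asarray(s, dtype=float)
    w = np.asarray(knots.widths)
    if w[0] == 0:
        raise ValueError("first segment has zero width; cannot eliminate it")
    ratios = w[1:] / w[0]
    return s[..., 1:] - ratios * s[..., :1]


def derive_first_slope(betas_rest: np.ndarray, knots: KnotSet) -> float:
    """First-segment slope implied by the periodicity constraint.

    ``beta_1 = -(sum_{k>=2} w_k beta_k)/w_1``, so that
    ``sum_k w_k beta_k = 0`` holds exactly.
    """
    w = np.asarray(knots.widths)
    betas_rest = np.asarray(betas_rest, dtype=float)
    if betas_rest.shape[-1] != len(w) - 1:
        raise ValueError(f"expected {len(w) - 1} slopes, got {betas_rest.shape[-1]}")
    return float(-(w[1:] @ betas_rest) / w[0])


def design_rows(profile, constrained: bool, common_knots=DEFAULT_COMMON_KNOTS) -> np.ndarray:
    """Basis matrix for one profile: intercept column plus spline columns.

    Uses the subject's own diary knots.  Shape ``(n_readings, 1+5)``
    unconstrained or ``(n_readings, 1+4)`` constrained.
    """
    knots = make_knots(profile.wake_time, profile.sleep_time, common_knots)
    s = eval_splines(np.asarray(profile.slots, dtype=float), knots)
    if constrained:
        s = constrain(s, knots)
    return np.column_stack([np.ones(s.shape[0]), s])
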