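"""Two-objective fitness of a candidate index on two-stage fragments.

A good index traces a step function over the 238 epochs of a fragment:
one plateau for wakefulness, another for stage-1 sleep, separated by a
transition window of about 30 epochs (~1 min) whose position may drift
around the labelled boundary.  Two objectives, both minimized:

O1 — penalized inverse absolute difference between the plateau means.  The
     transition window is located by scanning all admissible start epochs
     and keeping the one maximizing |mean(right) - mean(left)|.  The
     difference is made relative by measuring from a "moved zero" just
     below the series minimum, then mapped through a graded penalty:
     bigger separation -> smaller O1, with tier jumps of 10x.

O2 — graded oscillation penalty: adjacent-epoch relative changes outside
     the transition window are binned into four severity tiers
     (>=5, >=1, >=0.5, >=0.25) contributing 1000/100/10/1 each.

The admissible window starts are epochs [30, n-60]; the window itself is
excluded from both objectives.  The published scan pseudocode carries two
defects (an accumulator reset inside the loop that makes the comparison
vacuous, and a reference point that rises above the minimum for negative
series); the defaults here fix both, and ``compat_printed_scan`` /
``compat_printed_moved_zero`` reproduce the literal pseudocode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .band_features import FeatureTable
from .ratio_indices import IndexSpec, clamp_values, eval_multichannel_index

__all__ = [
    "WIN_SIZE",
    "TransitionWindow",
    "ObjectiveValues",
    "moved_zero",
    "iad_calc",
    "iad_penalty",
    "oscillation_calc",
    "oscillation_weight",
    "evaluate_solution",
]

#: Transition window length in epochs (~1 minute at 2.5 s epoch step).
WIN_SIZE = 30

#: Severity thresholds shared by both gradations (relative differences).
IAD_TIERS = (5.0, 1.0, 0.5)          # >=5 -> 1/x, >=1 -> 10/x, >=0.5 -> 100/x
IAD_FLOOR_PENALTY = 1000.0           # below the lowest tier
OSC_TIERS = (0.25, 0.5, 1.0, 5.0)    # ascending thresholds
OSC_WEIGHTS = (0.0, 1.0, 10.0, 100.0, 1000.0)

_EPS = 1e-12


@dataclass
class TransitionWindow:
    """Located transition window: [start, start + win_size) epochs excluded."""

    window_start: int
    win_size: int = WIN_SIZE


@dataclass
class ObjectiveValues:
    """(O1, O2) for one candidate: means of per-fragment scores."""

    O1: float
    O2: float
    per_fragment: list[tuple[float, float, int]] = field(default_factory=list)

    def astuple(self) -> tuple[float, float]:
        return (self.O1, self.O2)


def moved_zero(values: np.ndarray, compat_printed: bool = False) -> float:
    """Reference point just below the series minimum.

    Default: ``min - 0.01*|min|`` (and ``-0.01`` when min == 0), which is
    strictly below the minimum for any sign.  ``compat_printed`` uses the
    literal ``min - 0.01*min``, which rises above the minimum when it is
    negative.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    lowest = float(np.min(values))
    if compat_printed:
        return lowest - 0.01 * lowest
    if lowest == 0.0:
        return -0.01
    return lowest - 0.01 * abs(lowest)


def _window_scan(values: np.ndarray, win_size: int,
                 compat_printed_scan: bool) -> tuple[float, float, int]:
    """Scan admissible window starts; return (avg_left, avg_right, start).

    Arg-max of |mean(right) - mean(left)| with last-wins ties.  With
    ``compat_printed_scan`` the accumulator resets every iteration, so the
    last admissible start always wins regardless of its difference.
    """
    n = values.size
    j_lo, j_hi = 30, n - 60  # inclusive
    cum = np.concatenate(([0.0], np.cumsum(values)))
    total = cum[-1]
    js = np.arange(j_lo, j_hi + 1)
    avg_left = cum[js] / js
    n_right = n - (js + win_size)
    avg_right = (total - cum[js + win_size]) / n_right
    diffs = np.abs(avg_right - avg_left)
    if compat_printed_scan:
        k = len(js) - 1
    else:
        k = int(np.flatnonzero(diffs >= diffs.max() - 0.0)[-1])
    return float(avg_left[k]), float(avg_right[k]), int(js[k])


def iad_calc(
    index_values: np.ndarray,
    win_size: int = WIN_SIZE,
    compat_printed_scan: bool = False,
    compat_printed_moved_zero: bool = False,
) -> tuple[float, int]:
    """Penalized inverse absolute difference and the located window start.

    Returns ``(invAbsDiff, window_start)``.  The relative plateau
    separation is ``|right - left| / min(left - z, right - z)`` with ``z``
    the moved zero; the graded penalty is 1/x, 10/x, 100/x for separations
    >= 5, >= 1, >= 0.5, and a flat 1000 below that.
    """
    values = np.asarray(index_values, dtype=float)
    n = values.size
    if n < 30 + win_size + 60:
        raise ValueError(
            f"series of {n} epochs too short for the window search "
            f"(needs >= {30 + win_size + 60})"
        )
    left, right, window_start = _window_scan(values, win_size,
                                             compat_printed_scan)
    z = moved_zero(values, compat_printed_moved_zero)
    denom = min(left - z, right - z)
    if denom < _EPS:
        denom = _EPS
    abs_diff = abs(right - left) / denom
    return iad_penalty(abs_diff), window_start


def iad_penalty(abs_diff: float) -> float:
    """Graded inverse of the relative plateau separation.

    Non-increasing in ``abs_diff``: 1000 below 0.5, then 100/x, 10/x, 1/x
    on [0.5, 1), [1, 5), [5, inf).
    """
    if abs_diff >= IAD_TIERS[0]:
        return 1.0 / abs_diff
    if abs_diff >= IAD_TIERS[1]:
        return 10.0 / abs_diff
    if abs_diff >= IAD_TIERS[2]:
        return 100.0 / abs_diff
    return IAD_FLOOR_PENALTY


def oscillation_weight(rel_diff: float) -> float:
    """Penalty one adjacent-epoch relative change contributes to O2."""
    return OSC_WEIGHTS[int(np.searchsorted(OSC_TIERS, rel_diff,
                                           side="right"))]


def oscillation_calc(
    index_values: np.ndarray,
    window_start: int,
    win_size: int = WIN_SIZE,
    compat_printed_moved_zero: bool = False,
) -> float:
    """Graded oscillation penalty over pairs outside the transition window.

    For each adjacent pair (e-1, e) with e in [1, window_start-1] or
    [window_start + win_size, n-1], the relative change
    ``|(x_e - x_{e-1}) / (x_{e-1} - z)|`` contributes 1000, 100, 10 or 1
    for changes >= 5, 1, 0.5, 0.25, and nothing below 0.25.
    """
    values = np.asarray(index_values, dtype=float)
    n = values.size
    if not (0 < window_start and window_start + win_size <= n):
        raise ValueError("transition window outside the series")
    z = moved_zero(values, compat_printed_moved_zero)
    denom = values[:-1] - z
    denom = np.where(np.abs(denom) < _EPS, _EPS, denom)
    rel = np.abs(np.diff(values) / denom)  # rel[e-1] is the pair (e-1, e)
    e = np.arange(1, n)
    keep = (e <= window_start - 1) | (e >= window_start + win_size)
    tiers = np.searchsorted(OSC_TIERS, rel[keep], side="right")
    return float(np.sum(np.take(OSC_WEIGHTS, tiers)))


def evaluate_solution(
    spec: IndexSpec,
    fragments: list[FeatureTable],
    win_size: int = WIN_SIZE,
    clamp: bool = True,
    zero_denominator: str = "epsilon",
    compat_printed_scan: bool = False,
    compat_printed_moved_zero: bool = False,
) -> ObjectiveValues:
    """Score one coefficient set on a list of fragments.

    Per fragment: evaluate the index, apply the 10 % adjacent-epoch clamp
    (``clamp=False`` scores the raw series instead), locate the transition
    window via :func:`iad_calc`, then score oscillations outside that same
    window.  O1 and O2 are the across-fragment means.
    """
    if not fragments:
        raise ValueError("need at least one fragment")
    per_fragment = []
    for table in fragments:
        series = eval_multichannel_index(table, spec, zero_denominator)
        vals = series.values
        if clamp:
            vals = clamp_values(vals)
        inv, wstart = iad_calc(vals, win_size, compat_printed_scan,
                               compat_printed_moved_zero)
        osc = oscillation_calc(vals, wstart, win_size,
                               compat_printed_moved_zero)
        per_fragment.append((inv, osc, wstart))
    o1 = float(np.mean([p[0] for p in per_fragment]))
    o2 = float(np.mean([p[1] for p in per_fragment]))
    return ObjectiveValues(O1=o1, O2=o2, per_fragment=per_fragment)
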