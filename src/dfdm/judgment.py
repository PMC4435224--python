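"""Fault judgment from the relative position of prediction, interval, reading.

A suspected reading y is judged against two geometries: the fuzzy prediction
Y~ = (a, b, l, r) and the physiological normal interval (low, high).  The
trapezoid contributes four breakpoints -- the support bounds a-l and b+r and
the lambda-level cuts a_lam = a - (1-lam)l and b_lam = b + (1-lam)r, the
readings whose membership equals the similarity degree lambda (0.5 < lambda
< 1) -- which partition the reading axis into five regions:

    0: y < a-l            (below the support)
    1: a-l <= y < a_lam   (lower shoulder)
    2: a_lam <= y <= b_lam (lambda-core)
    3: b_lam < y <= b+r   (upper shoulder)
    4: y > b+r            (above the support)

Interleaving the interval endpoints with these breakpoints yields exactly 15
distinct cases (each endpoint falls in one of the five regions with
low <= high), and in every case the verdict reduces to:

* lambda-core (region 2)           -> good
* shoulders (regions 1 and 3)      -> undecided
* below the support (region 0)     -> fault, unless y > high (then undecided)
* above the support (region 4)     -> fault, unless y < low (then undecided)

So a reading the model endorses is good; a reading outside the fuzzy support
on its "far" side -- or outside the support while the normal interval agrees
it should have been covered -- is faulty; everything else is deferred,
because physiological attributes change out of sync and the prediction may
simply lag.  A sensor whose undecided state persists for a configured number
of consecutive rounds is promoted to faulty.

Boundary equalities are resolved fault-aversely: a breakpoint belongs to the
neighbouring region with the less severe verdict (good over undecided,
undecided over fault), and interval bounds are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .fuzzy_regression import TrapezoidalFuzzyNumber

__all__ = [
    "NormalInterval",
    "JudgmentConfig",
    "JudgmentResult",
    "GOOD", "FAULT", "UNDECIDED",
    "classify_position",
    "judge",
    "resolve_undecided",
]

GOOD = "good"
FAULT = "fault"
UNDECIDED = "undecided"

#: Table rows keyed by (region of low, region of high), in table order.
_CASE_IDS = {
    (0, 0): 1, (0, 1): 2, (1, 1): 3,
    (0, 2): 4, (1, 2): 5, (2, 2): 6,
    (0, 3): 7, (1, 3): 8, (2, 3): 9, (3, 3): 10,
    (0, 4): 11, (1, 4): 12, (2, 4): 13, (3, 4): 14, (4, 4): 15,
}


@dataclass(frozen=True)
class NormalInterval:
    """Physiological normal interval of one attribute."""

    low: float
    high: float
    attribute: str = ""

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"need low < high, got ({self.low}, {self.high})")

    def contains(self, y: float) -> bool:
        return self.low <= y <= self.high


@dataclass(frozen=True)
class JudgmentConfig:
    """Similarity level and undecided persistence."""

    lambda_level: float = 0.8
    persistence: int = 3

    def __post_init__(self):
        if not 0.5 < self.lambda_level < 1:
            raise ValueError("lambda_level must lie in (0.5, 1)")
        if self.persistence < 1:
            raise ValueError("persistence must be a positive integer")


@dataclass(frozen=True)
class JudgmentResult:
    """Verdict for one suspected reading plus the geometry that produced it."""

    state: str
    case_id: int
    breakpoints: dict


def _breakpoints(fn: TrapezoidalFuzzyNumber, lam: float):
    a_l, b_r = fn.support
    a_lam, b_lam = fn.level_cut(lam)
    return a_l, a_lam, b_lam, b_r


def _region(y: float, a_l: float, a_lam: float, b_lam: float, b_r: float) -> int:
    """Region index 0..4 with fault-averse boundary membership."""
    if y < a_l:
        return 0
    if y < a_lam:          # a_l itself lands in the shoulder (undecided)
        return 1
    if y <= b_lam:         # level cuts belong to the core (good)
        return 2
    if y <= b_r:           # b_r lands in the shoulder (undecided)
        return 3
    return 4


def classify_position(fn: TrapezoidalFuzzyNumber, interval: NormalInterval,
                      cfg: JudgmentConfig) -> int:
    """Table row (1..15) for the interleaving of trapezoid and interval."""
    bp = _breakpoints(fn, cfg.lambda_level)
    r_low = _region(interval.low, *bp)
    r_high = _region(interval.high, *bp)
    return _CASE_IDS[(r_low, r_high)]


def judge(fn: TrapezoidalFuzzyNumber, y: float, interval: NormalInterval,
          cfg: JudgmentConfig) -> JudgmentResult:
    """Good / fault / undecided verdict for reading ``y``."""
    bp = _breakpoints(fn, cfg.lambda_level)
    a_l, a_lam, b_lam, b_r = bp
    case_id = classify_position(fn, interval, cfg)
    region = _region(y, *bp)
    if region == 2:
        state = GOOD
    elif region in (1, 3):
        state = UNDECIDED
    elif region == 0:
        state = UNDECIDED if y > interval.high else FAULT
    else:  # region 4
        state = UNDECIDED if y < interval.low else FAULT
    return JudgmentResult(
        state=state, case_id=case_id,
        breakpoints={"a_minus_l": a_l, "a_lambda": a_lam,
                     "b_lambda": b_lam, "b_plus_r": b_r,
                     "low": interval.low, "high": interval.high})


def resolve_undecided(history: Sequence[JudgmentResult | str],
                      cfg: JudgmentConfig) -> str:
    """Promote a persistent undecided streak to fault.

    ``history`` is the per-sensor sequence of verdicts, oldest first; entries
    may be :class:`JudgmentResult` or bare state strings.  Fault if the last
    ``cfg.persistence`` consecutive verdicts are all undecided; otherwise the
    latest verdict (any good or fault resets the streak).  Empty history is
    undecided.
    """
    states = [h.state if isinstance(h, JudgmentResult) else h for h in history]
    if not states:
        return UNDECIDED
    streak = 0
    for s in reversed(states):
        if s == UNDECIDED:
            streak += 1
        else:
            break
    if streak >= cfg.persistence:
        return FAULT
    return states[-1]
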