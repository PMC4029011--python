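"""Coherence intervals of mental probability logic for conditional inferences.

Given the elicited probability of the conditional ``c`` (playing the role of
P(q|p) under the conditional-probability reading of "if p then q") and the
minor-premise probability ``m``, the probability of the conclusion is only
partially constrained: unknown quantities (chiefly the probability of
alternatives P(q|not-p)) may range over [0, 1].  The set of conclusion
probabilities consistent with *some* coherent joint distribution over p, q and
their complements forms a closed interval:

* MP (m = P(p), conclusion q):      [c*m, c*m + (1 - m)]
* MT (m = P(not-q), conclusion not-p):
      [max((1-c-m)/(1-c), (c+m-1)/c), 1]   (terms with zero denominator dropped)
* AC (m = P(q), conclusion p):      [0, min(m/c, (1-m)/(1-c))]   (ditto)
* DA (m = P(not-p), conclusion not-q):  [1 - m - c*(1-m), 1 - c*(1-m)]

All bounds are clipped to [0, 1].  A brute-force sweep over the unknown
quantities (:func:`oracle_interval`) provides an independent check of the
closed forms.

A response is scored against its interval as ``inside - chance`` where
``chance`` is the interval width: the probability that a uniformly random
response lands inside by luck alone.  Intervals may be extended symmetrically
by 0.05 or 0.1 to tolerate near-miss responses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset_io import INFERENCES, ExperimentDataset

__all__ = [
    "CoherenceInterval",
    "CoherenceResult",
    "interval",
    "oracle_interval",
    "coherence_score",
    "coherence_table",
]

#: Membership tolerance for the closed-interval test.
MEMBERSHIP_TOL = 1e-9


@dataclass(frozen=True)
class CoherenceInterval:
    """Closed [lower, upper] bound on the conclusion probability."""

    lower: float
    upper: float
    inference: str
    extension: float = 0.0
    empty: bool = False

    def __post_init__(self) -> None:
        if not self.empty and self.lower > self.upper + 1e-12:
            raise ValueError(
                f"lower {self.lower} exceeds upper {self.upper} for {self.inference}"
            )

    @property
    def width(self) -> float:
        return 0.0 if self.empty else self.upper - self.lower

    def extended(self, extension: float) -> "CoherenceInterval":
        """Interval widened by ``extension`` on both sides, clipped to [0, 1]."""
        if extension < 0:
            raise ValueError("extension must be nonnegative")
        return CoherenceInterval(
            lower=max(self.lower - extension, 0.0),
            upper=min(self.upper + extension, 1.0),
            inference=self.inference,
            extension=extension,
            empty=self.empty,
        )


@dataclass(frozen=True)
class CoherenceResult:
    """Membership indicator, chance level, and chance-corrected score."""

    inside: int
    chance: float
    score: float


def _check_unit(name: str, x: float) -> None:
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"{name} = {x} outside [0, 1]")


def interval(inference: str, c: float, m: float) -> CoherenceInterval:
    """Coherence interval for the conclusion probability.

    Parameters
    ----------
    inference
        One of MP, MT, AC, DA.
    c
        Elicited probability of the conditional, used as P(q|p).
    m
        Minor-premise probability: P(p), P(not-q), P(q), P(not-p) for
        MP, MT, AC, DA respectively.

    Terms whose denominator vanishes (c = 0 or c = 1) are dropped from the
    max/min; if every term is undefined the bound defaults to 0 (lower) or
    1 (upper).  Bounds are clipped to [0, 1].
    """
    _check_unit("c", c)
    _check_unit("m", m)
    if inference == "MP":
        lo, hi = c * m, c * m + (1.0 - m)
    elif inference == "MT":
        terms = []
        if c < 1.0:
            terms.append((1.0 - c - m) / (1.0 - c))
        if c > 0.0:
            terms.append((c + m - 1.0) / c)
        lo = max(terms) if terms else 0.0
        hi = 1.0
    elif inference == "AC":
        terms = []
        if c > 0.0:
            terms.append(m / c)
        if c < 1.0:
            terms.append((1.0 - m) / (1.0 - c))
        lo = 0.0
        hi = min(terms) if terms else 1.0
    elif inference == "DA":
        lo = 1.0 - m - c * (1.0 - m)
        hi = 1.0 - c * (1.0 - m)
    else:
        raise ValueError(f"unknown inference {inference!r}")
    lo = min(max(lo, 0.0), 1.0)
    hi = min(max(hi, 0.0), 1.0)
    return CoherenceInterval(lower=lo, upper=hi, inference=inference)


def oracle_interval(inference: str, c: float, m: float, grid_n: int = 1001) -> CoherenceInterval:
    """Brute-force coherence interval by sweeping the unknown quantities.

    For MP and DA the single unknown is the probability of alternatives
    b = P(q|not-p); the conclusion probability follows from the law of total
    probability and the sweep takes its min/max.  For MT and AC the conclusion
    marginal a = P(p) itself is swept and a value is feasible when the premise
    constraint P(q) = c*a + b*(1-a) can be met by some b in [0, 1].

    Converges to :func:`interval` as ``grid_n`` grows; endpoint error is at
    most one grid step.  If no coherent joint matches the premises the result
    is flagged ``empty`` (cannot occur for premise pairs on [0, 1]^2, but the
    flag keeps the contract explicit).
    """
    _check_unit("c", c)
    _check_unit("m", m)
    if grid_n < 2:
        raise ValueError("grid_n must be at least 2")
    grid = np.linspace(0.0, 1.0, grid_n)

    if inference in ("MP", "DA"):
        b = grid
        if inference == "MP":
            # m = P(p); conclusion P(q) = c*m + b*(1-m)
            values = c * m + b * (1.0 - m)
        else:
            # m = P(not-p); conclusion P(not-q) = 1 - (c*(1-m) + b*m)
            values = 1.0 - (c * (1.0 - m) + b * m)
    elif inference in ("MT", "AC"):
        # target marginal P(q): 1-m for MT (m = P(not-q)), m for AC (m = P(q))
        target = 1.0 - m if inference == "MT" else m
        a = grid[:-1]  # P(p) < 1; a = 1 handled separately
        b = (target - c * a) / (1.0 - a)
        feasible = (b >= -1e-12) & (b <= 1.0 + 1e-12)
        a_ok = a[feasible]
        if abs(c - target) <= 1e-12:  # P(p) = 1 leaves no not-p mass; needs c == target
            a_ok = np.append(a_ok, 1.0)
        if a_ok.size == 0:
            return CoherenceInterval(0.0, 1.0, inference, empty=True)
        values = 1.0 - a_ok if inference == "MT" else a_ok
    else:
        raise ValueError(f"unknown inference {inference!r}")

    lo = float(np.clip(values.min(), 0.0, 1.0))
    hi = float(np.clip(values.max(), 0.0, 1.0))
    return CoherenceInterval(lower=lo, upper=hi, inference=inference)


def coherence_score(
    response: float, interval: CoherenceInterval, extension: float = 0.0
) -> CoherenceResult:
    """Score a conclusion response against its (possibly extended) interval.

    ``inside`` is 1 when the response lies in the closed extended interval
    (tolerance 1e-9); ``chance`` is the extended width after clipping to
    [0, 1] — the probability a uniform random response lands inside; the
    chance-corrected score is their difference, in [-1, 1].
    """
    _check_unit("response", response)
    ext = interval.extended(extension)
    inside = int(ext.lower - MEMBERSHIP_TOL <= response <= ext.upper + MEMBERSHIP_TOL)
    chance = ext.width
    return CoherenceResult(inside=inside, chance=chance, score=inside - chance)


def coherence_table(
    dataset: ExperimentDataset,
    extensions: Sequence[float] = (0.0, 0.05, 0.1),
) -> pd.DataFrame:
    """Per-record coherence analysis at each interval extension.

    One row per inference record per extension with the extended interval
    bounds, membership indicator, chance level, and chance-corrected score.
    """
    rows = []
    for rec in dataset.inference_records:
        base = interval(rec.inference, rec.c, rec.m)
        for extension in extensions:
            ext = base.extended(extension)
            res = coherence_score(rec.response, base, extension)
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "conditional_id": rec.conditional_id,
                    "inference": rec.inference,
                    "extension": extension,
                    "lower": ext.lower,
                    "upper": ext.upper,
                    "response": rec.response,
                    "inside": res.inside,
                    "chance": res.chance,
                    "score": res.score,
                }
            )
    return pd.DataFrame(rows)
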