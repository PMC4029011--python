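"""p-validity (Adams) with chance correction for conditional inferences.

An inference is probabilistically valid when the uncertainty of its
conclusion, U = 1 - P, cannot exceed the summed uncertainties of its
premises.  Only MP and MT are p-valid forms; AC and DA carry no such
restriction, but their indicators are still computed descriptively because
responses to them mirror the MP/MT pattern.

The summed premise uncertainty, truncated at 1, doubles as the chance level:
under a uniform random response the probability of satisfying the inequality
equals exactly that truncated sum (at a sum of 1 every response is p-valid).
The chance-corrected score is ``valid - chance``.  Slack variants relax the
validity inequality by 0.05 or 0.1 to tolerate near-miss responses; the
chance level is left untouched so that the slack analyses stay comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset_io import ExperimentDataset, InferenceRecord

__all__ = [
    "PValidityResult",
    "p_validity",
    "p_validity_record",
    "chance_level_pvalid",
    "pvalidity_table",
    "summarize_pvalidity",
]

#: Forms restricted by p-validity; AC/DA results are descriptive only.
NORMATIVE_FORMS = frozenset({"MP", "MT"})

_TOL = 1e-9


@dataclass(frozen=True)
class PValidityResult:
    """Chance-corrected p-validity of one conclusion response."""

    usum: float            # truncated summed premise uncertainty, in [0, 1]
    u_conclusion: float    # 1 - response
    valid: int             # 1 iff u_conclusion <= usum + slack
    chance: float          # = usum
    score: float           # valid - chance
    slack: float
    inference: str
    normative: bool        # True for MP/MT only


def p_validity(
    c: float, m: float, response: float, inference: str, slack: float = 0.0
) -> PValidityResult:
    """Score one response for p-validity.

    Parameters
    ----------
    c, m
        Probabilities of the conditional and the minor premise.
    response
        Conclusion estimate on [0, 1].
    inference
        MP, MT, AC or DA; only MP/MT are flagged normative.
    slack
        Amount by which the validity inequality is relaxed (0, 0.05, 0.1).
    """
    for name, x in (("c", c), ("m", m), ("response", response)):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"{name} = {x} outside [0, 1]")
    if slack < 0:
        raise ValueError("slack must be nonnegative")
    usum = min((1.0 - c) + (1.0 - m), 1.0)
    u_conclusion = 1.0 - response
    valid = int(u_conclusion <= usum + slack + _TOL)
    chance = usum
    return PValidityResult(
        usum=usum,
        u_conclusion=u_conclusion,
        valid=valid,
        chance=chance,
        score=valid - chance,
        slack=slack,
        inference=inference,
        normative=inference in NORMATIVE_FORMS,
    )


def p_validity_record(record: InferenceRecord, slack: float = 0.0) -> PValidityResult:
    """p-validity of one inference record (premises + conclusion response)."""
    return p_validity(record.c, record.m, record.response, record.inference, slack)


def chance_level_pvalid(usum: float) -> float:
    """Probability that a uniform random response is p-valid.

    A uniform response r on [0, 1] has conclusion uncertainty 1 - r, itself
    uniform, so P(1 - r <= usum) = usum.  At usum = 1 every possible response
    is p-valid and the chance level is exactly 1.
    """
    if not 0.0 <= usum <= 1.0:
        raise ValueError(f"usum = {usum} outside [0, 1]")
    return usum


def pvalidity_table(
    dataset: ExperimentDataset,
    slacks: Sequence[float] = (0.0, 0.05, 0.1),
) -> pd.DataFrame:
    """Per-record p-validity analysis at each slack level."""
    rows = []
    for rec in dataset.inference_records:
        for slack in slacks:
            res = p_validity_record(rec, slack)
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "conditional_id": rec.conditional_id,
                    "inference": rec.inference,
                    "slack": slack,
                    "usum": res.usum,
                    "u_conclusion": res.u_conclusion,
                    "valid": res.valid,
                    "chance": res.chance,
                    "score": res.score,
                    "normative": res.normative,
                }
            )
    return pd.DataFrame(rows)


def summarize_pvalidity(
    table: pd.DataFrame,
    inference: str,
    slack: float = 0.0,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict[str, float]:
    """Mean chance-corrected score for one inference with a bootstrap CI.

    Scores are first averaged within participant, then the mean over
    participants is bootstrapped (``n_boot`` resamples of participants,
    percentile 95% interval).  This participant-level resampling respects the
    nesting of responses within participants; it deliberately replaces any
    model-based inference.

    Deterministic for a fixed ``seed``.
    """
    sub = table[(table["inference"] == inference) & (table["slack"] == slack)]
    per_participant = sub.groupby("participant_id")["score"].mean()
    if len(per_participant) < 2:
        raise ValueError(
            f"need at least 2 participants for {inference}, got {len(per_participant)}"
        )
    values = per_participant.to_numpy()
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    boot_means = values[idx].mean(axis=1)
    lo, hi = np.percentile(boot_means, [2.5, 97.5])
    return {
        "inference": inference,
        "slack": slack,
        "mean_score": float(values.mean()),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_participants": int(len(values)),
        "n_boot": int(n_boot),
    }
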