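"""Descriptive statistics for the conditional-probability hypothesis.

Four accounts compete to explain what the elicited probability of a
conditional "if p then q" tracks: the conditional probability P(q|p) (the
Equation), the conjunction P(p and q), the material conditional
P(not-p or q), and — via the delta-p rule — the probability of alternatives
P(q|not-p).  This module pools all item-by-participant responses into a
predictor matrix and reports pairwise correlations plus a simultaneous
least-squares regression of P(if p then q) on the four candidates.

Responses are nested within participants and conditionals; the pooled
statistics ignore that nesting and every output says so.  Model-based
(mixed-effects) inference is deliberately not provided here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset_io import ExperimentDataset

__all__ = [
    "NESTING_CAVEAT",
    "SingularDesignError",
    "predictor_matrix",
    "correlation_table",
    "pooled_regression",
]

NESTING_CAVEAT = (
    "pooled across item-by-participant responses; responses are nested within "
    "participants and conditionals, which these statistics ignore"
)

PREDICTORS = ("q_given_p", "conj", "material", "q_given_notp")
OUTCOME = "conditional"


class SingularDesignError(ValueError):
    """The regression design matrix is rank deficient."""


@dataclass(frozen=True)
class CorrelationTable:
    """Pairwise Pearson correlations with per-column means and SDs."""

    corr: pd.DataFrame
    mean: pd.Series
    sd: pd.Series
    n: int
    note: str = NESTING_CAVEAT


@dataclass(frozen=True)
class RegressionResult:
    """Pooled least-squares fit of the conditional on the four predictors."""

    params: pd.Series
    bse: pd.Series          # naive standard errors (ignore nesting)
    nobs: int
    rsquared: float
    note: str = NESTING_CAVEAT


def predictor_matrix(dataset: ExperimentDataset) -> pd.DataFrame:
    """One row per inference record: the conditional and its four candidate
    predictors, all on [0, 1], with identifying metadata columns.

    Records missing any of the five items are dropped (listwise-complete).
    """
    rows = []
    for rec in dataset.inference_records:
        try:
            rows.append(
                {
                    "participant_id": rec.participant_id,
                    "conditional_id": rec.conditional_id,
                    "inference": rec.inference,
                    OUTCOME: rec.value("conditional"),
                    "q_given_p": rec.value("q_given_p"),
                    "conj": rec.value("conj"),
                    "material": rec.value("material"),
                    "q_given_notp": rec.value("q_given_notp"),
                }
            )
        except KeyError:
            continue  # listwise-complete: drop records lacking an item
    return pd.DataFrame(rows)


def correlation_table(matrix: pd.DataFrame) -> CorrelationTable:
    """Pairwise Pearson correlations among the conditional and its predictors.

    Zero-variance columns yield undefined (NaN) correlations, never 0.
    """
    cols = [OUTCOME, *PREDICTORS]
    data = matrix[cols]
    if len(data) < 3:
        raise ValueError(f"need at least 3 rows for correlations, got {len(data)}")
    return CorrelationTable(
        corr=data.corr(),  # pandas leaves zero-variance correlations NaN
        mean=data.mean(),
        sd=data.std(ddof=1),
        n=len(data),
    )


def pooled_regression(matrix: pd.DataFrame) -> RegressionResult:
    """Least squares of P(if p then q) on the four predictors plus intercept.

    Raises :class:`SingularDesignError` naming the offending columns when the
    design is rank deficient (a constant predictor, or an exact linear
    dependency among predictors).
    """
    if len(matrix) < 6:
        raise ValueError(f"need at least 6 rows for the regression, got {len(matrix)}")
    y = matrix[OUTCOME].to_numpy(dtype=float)
    X = matrix[list(PREDICTORS)].to_numpy(dtype=float)

    constant = [p for p, col in zip(PREDICTORS, X.T) if np.ptp(col) == 0.0]
    design = sm.add_constant(X, has_constant="add")
    if constant or np.linalg.matrix_rank(design) < design.shape[1]:
        if not constant:
            # name the smallest dependent subset by checking each predictor
            # against the span of the others
            constant = [
                p
                for i, p in enumerate(PREDICTORS)
                if np.linalg.matrix_rank(np.delete(design, i + 1, axis=1))
                == np.linalg.matrix_rank(design)
            ]
        raise SingularDesignError(
            "singular design; collinear or constant column(s): " + ", ".join(constant)
        )

    fit = sm.OLS(y, design).fit()
    names = ["intercept", *PREDICTORS]
    return RegressionResult(
        params=pd.Series(fit.params, index=names),
        bse=pd.Series(fit.bse, index=names),
        nobs=int(fit.nobs),
        rsquared=float(fit.rsquared),
    )
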