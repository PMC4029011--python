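"""Dual-source model of probabilistic conditional inference, with baselines.

The model holds that a reasoner blends two sources when judging a conclusion:

* a *knowledge-based* component xi — the point estimate of the conclusion
  probability implied by a coherent joint distribution over p, q and their
  complements, computed by the law of total probability from three elicited
  quantities: the conditional c = P(if p then q) (read as P(q|p)), the minor
  premise m, and the probability of alternatives b = P(q|not-p);
* a *form-based* component tau — the reasoner's endorsement of the inference
  form itself, estimated from a separate deductive task with abstract content
  (mean over the two abstract conditionals, no free parameters).

The blended prediction is a mixture with weight lambda in [0, 1]:

    prediction = lambda * (tau + (1 - tau) * xi) + (1 - lambda) * xi
               = xi + lambda * tau * (1 - xi)

Three models are fitted per participant to the four conclusion responses by
minimizing the root mean squared deviation (RMSD):

* BL      — xi alone; no free parameter.
* BL*     — xi with b replaced by clip(s * b, 0, 1); one scaling parameter
            s >= 0, absorbing possible bias in the b estimates (which are
            elicited after the inference was already made).
* DS      — the dual-source mixture; one weighting parameter lambda in [0, 1].

xi is undefined for MT/AC when c = b (the law of total probability degenerates
to a zero denominator); such participants are excluded from fitting, as no
baseline prediction exists for them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset_io import INFERENCES, DeductiveRecord, ExperimentDataset, InferenceRecord

__all__ = [
    "KnowledgeEstimate",
    "ModelFit",
    "knowledge_estimate",
    "ds_predict",
    "form_estimates",
    "fit_participant",
    "fit_dataset",
    "compare_models",
]

MODELS = ("BL", "BL_star", "DS")

#: Denominators smaller than this count as zero: no prediction exists.
_DENOM_TOL = 1e-12

#: Default upper bound of the BL* scaling-parameter search.
DEFAULT_S_MAX = 20.0

#: Default grid step of the deterministic parameter search.
DEFAULT_GRID_STEP = 0.001


@dataclass(frozen=True)
class KnowledgeEstimate:
    """Point estimate xi of the conclusion probability from total probability."""

    xi: float
    inference: str
    defined: bool
    clipped: bool


@dataclass(frozen=True)
class ModelFit:
    """One model fitted to one participant's four conclusion responses."""

    model: str
    participant_id: str
    predictions: dict[str, float] | None  # inference -> predicted probability
    rmsd: float                           # NaN when excluded
    parameter: float | None               # lambda (DS), s (BL*), None (BL)
    excluded: bool


def knowledge_estimate(inference: str, c: float, m: float, b: float) -> KnowledgeEstimate:
    """Knowledge-based point estimate of the conclusion probability.

    Solves the law of total probability P(q) = P(q|p)P(p) + P(q|not-p)P(not-p)
    for the conclusion marginal of each form:

    * MP (m = P(p), conclusion q):        xi = c*m + b*(1-m)
    * DA (m = P(not-p), conclusion not-q): xi = 1 - c*(1-m) - b*m
    * MT (m = P(not-q), conclusion not-p): xi = 1 - (1-m-b)/(c-b)
    * AC (m = P(q), conclusion p):         xi = (m-b)/(c-b)

    For MT and AC the solution requires dividing by c - b; when that
    denominator vanishes no prediction exists and ``defined`` is False (the
    participant is later excluded from all model fits).
    Estimates from incoherent elicitations can leave [0, 1]; they are clipped
    with ``clipped`` set.
    """
    for name, x in (("c", c), ("m", m), ("b", b)):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"{name} = {x} outside [0, 1]")
    if inference == "MP":
        xi = c * m + b * (1.0 - m)
    elif inference == "DA":
        xi = 1.0 - c * (1.0 - m) - b * m
    elif inference in ("MT", "AC"):
        denom = c - b
        if abs(denom) < _DENOM_TOL:
            return KnowledgeEstimate(xi=float("nan"), inference=inference,
                                     defined=False, clipped=False)
        x = (m - b) / denom if inference == "AC" else (1.0 - m - b) / denom
        xi = x if inference == "AC" else 1.0 - x
    else:
        raise ValueError(f"unknown inference {inference!r}")
    clipped = xi < 0.0 or xi > 1.0
    xi = min(max(xi, 0.0), 1.0)
    return KnowledgeEstimate(xi=xi, inference=inference, defined=True, clipped=clipped)


def ds_predict(xi: float, tau: float, lam: float) -> float:
    """Dual-source prediction: lam*(tau + (1-tau)*xi) + (1-lam)*xi.

    Algebraically equal to xi + lam*tau*(1-xi); nondecreasing in lam and tau
    and never below xi.
    """
    for name, x in (("xi", xi), ("tau", tau), ("lam", lam)):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"{name} = {x} outside [0, 1]")
    return lam * (tau + (1.0 - tau) * xi) + (1.0 - lam) * xi


def form_estimates(
    deductive_records: Iterable[DeductiveRecord],
    participant_id: str | None = None,
) -> dict[str, float]:
    """Form-based component tau per inference: mean endorsement across the
    two abstract conditionals of the deductive task."""
    sums: dict[str, list[float]] = {}
    for rec in deductive_records:
        if participant_id is not None and rec.participant_id != participant_id:
            continue
        sums.setdefault(rec.inference, []).append(rec.endorsement)
    missing = [inf for inf in INFERENCES if inf not in sums]
    if missing:
        raise ValueError(f"no deductive endorsements for inference(s): {', '.join(missing)}")
    return {inf: float(np.mean(vals)) for inf, vals in sums.items()}


def _rmsd(predictions: Mapping[str, float], observed: Mapping[str, float]) -> float:
    diffs = [predictions[inf] - observed[inf] for inf in observed]
    return float(np.sqrt(np.mean(np.square(diffs))))


def _golden_refine(
    f: Callable[[float], float], lo: float, hi: float, tol: float = 1e-7
) -> float:
    """Deterministic golden-section minimizer on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c_ = b - invphi * (b - a)
    d_ = a + invphi * (b - a)
    fc, fd = f(c_), f(d_)
    while b - a > tol:
        if fc <= fd:
            b, d_, fd = d_, c_, fc
            c_ = b - invphi * (b - a)
            fc = f(c_)
        else:
            a, c_, fc = c_, d_, fd
            d_ = a + invphi * (b - a)
            fd = f(d_)
    return (a + b) / 2.0


def _minimize_on_grid(
    f: Callable[[float], float], grid: np.ndarray
) -> tuple[float, float]:
    """Grid scan plus golden-section refinement between the neighbours of the
    best grid point.  Ties break toward the smaller parameter: any grid value
    within 1e-12 of the minimum counts as tied (a flat or numerically-flat
    objective must not pick an arbitrary parameter), and the refined value is
    kept only when it improves the objective by more than that tolerance."""
    values = np.array([f(x) for x in grid])
    fmin = float(values.min())
    i = int(np.argmax(values <= fmin + 1e-12))  # first tied index = smallest parameter
    best_x, best_f = float(grid[i]), float(values[i])
    lo = float(grid[max(i - 1, 0)])
    hi = float(grid[min(i + 1, len(grid) - 1)])
    if hi > lo:
        refined = _golden_refine(f, lo, hi)
        f_ref = f(refined)
        if f_ref < best_f - 1e-12:
            best_x, best_f = refined, f_ref
    return best_x, best_f


def _observed_and_inputs(
    records: Sequence[InferenceRecord],
) -> tuple[dict[str, float], dict[str, tuple[float, float, float]]]:
    if len(records) != 4 or {r.inference for r in records} != set(INFERENCES):
        raise ValueError("fit_participant needs exactly one record per inference form")
    observed = {r.inference: r.response for r in records}
    inputs = {r.inference: (r.c, r.m, r.b) for r in records}
    return observed, inputs


def _excluded_fit(model: str, participant_id: str, parameter: float | None = None) -> ModelFit:
    return ModelFit(model=model, participant_id=participant_id, predictions=None,
                    rmsd=float("nan"), parameter=parameter, excluded=True)


def fit_participant(
    records: Sequence[InferenceRecord],
    tau: Mapping[str, float] | None = None,
    model: str = "DS",
    s_max: float = DEFAULT_S_MAX,
    grid_step: float = DEFAULT_GRID_STEP,
) -> ModelFit:
    """Fit one model to one participant's four conclusion responses by RMSD.

    Parameters are searched on a deterministic grid (step ``grid_step``;
    BL* additionally covers (1, s_max] with 500 log-spaced points) followed
    by golden-section refinement; ties break toward the smaller parameter.

    A participant whose baseline xi is undefined for any form (c = b for
    MT/AC) is returned as excluded for every model: no baseline prediction
    exists to compare against.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    observed, inputs = _observed_and_inputs(records)
    pid = records[0].participant_id

    baseline = {inf: knowledge_estimate(inf, *inputs[inf]) for inf in INFERENCES}
    if not all(k.defined for k in baseline.values()):
        return _excluded_fit(model, pid)

    if model == "BL":
        preds = {inf: baseline[inf].xi for inf in INFERENCES}
        return ModelFit(model="BL", participant_id=pid, predictions=preds,
                        rmsd=_rmsd(preds, observed), parameter=None, excluded=False)

    if model == "BL_star":
        def predictions_at(s: float) -> dict[str, float] | None:
            preds = {}
            for inf in INFERENCES:
                c, m, b = inputs[inf]
                k = knowledge_estimate(inf, c, m, min(max(s * b, 0.0), 1.0))
                if not k.defined:
                    return None  # this s hits a zero denominator; no prediction
                preds[inf] = k.xi
            return preds

        def objective(s: float) -> float:
            preds = predictions_at(s)
            return float("inf") if preds is None else _rmsd(preds, observed)

        n_lin = int(round(1.0 / grid_step)) + 1
        grid = np.linspace(0.0, 1.0, n_lin)
        if s_max > 1.0:
            grid = np.concatenate([grid, np.geomspace(1.0, s_max, 500)[1:]])
        s_hat, rmsd = _minimize_on_grid(objective, grid)
        preds = predictions_at(s_hat)
        return ModelFit(model="BL_star", participant_id=pid, predictions=preds,
                        rmsd=rmsd, parameter=s_hat, excluded=False)

    # DS
    if tau is None:
        raise ValueError("DS fit requires form estimates tau from the deductive task")
    missing = [inf for inf in INFERENCES if inf not in tau]
    if missing:
        raise ValueError(f"tau missing inference(s): {', '.join(missing)}")

    def objective(lam: float) -> float:
        preds = {inf: ds_predict(baseline[inf].xi, tau[inf], lam) for inf in INFERENCES}
        return _rmsd(preds, observed)

    n_lin = int(round(1.0 / grid_step)) + 1
    grid = np.linspace(0.0, 1.0, n_lin)
    lam_hat, rmsd = _minimize_on_grid(objective, grid)
    preds = {inf: ds_predict(baseline[inf].xi, tau[inf], lam_hat) for inf in INFERENCES}
    return ModelFit(model="DS", participant_id=pid, predictions=preds,
                    rmsd=rmsd, parameter=lam_hat, excluded=False)


def fit_dataset(
    dataset: ExperimentDataset,
    models: Sequence[str] = MODELS,
    s_max: float = DEFAULT_S_MAX,
    grid_step: float = DEFAULT_GRID_STEP,
) -> list[ModelFit]:
    """Fit the requested models to every participant of a dataset.

    Participants lacking deductive records are an error when DS is requested;
    participants with undefined baseline predictions come back excluded.
    """
    fits: list[ModelFit] = []
    need_tau = "DS" in models
    for pid in dataset.participants:
        records = dataset.records_for(pid)
        tau = None
        if need_tau:
            ded = dataset.deductive_for(pid)
            if not ded:
                raise ValueError(f"participant {pid}: DS requested but no deductive records")
            tau = form_estimates(ded)
        for model in models:
            fits.append(fit_participant(records, tau=tau, model=model,
                                        s_max=s_max, grid_step=grid_step))
    return fits


def fits_frame(fits: Iterable[ModelFit]) -> pd.DataFrame:
    """Fits as a tidy DataFrame (one row per participant x model)."""
    rows = []
    for fit in fits:
        row: dict[str, object] = {
            "participant_id": fit.participant_id,
            "model": fit.model,
            "parameter": fit.parameter,
            "rmsd": fit.rmsd,
            "excluded": fit.excluded,
        }
        for inf in INFERENCES:
            row[f"pred_{inf}"] = None if fit.predictions is None else fit.predictions[inf]
        rows.append(row)
    return pd.DataFrame(rows)


def compare_models(fits: Sequence[ModelFit]) -> pd.DataFrame:
    """Model comparison table over the non-excluded participants.

    One row per model with the mean RMSD, its mean difference to BL per
    participant, and summary statistics of the free parameter (share of
    participants with lambda > 0 for DS; quartiles of s for BL*).
    """
    usable = [f for f in fits if not f.excluded]
    if not usable:
        raise ValueError("no non-excluded fits to compare")
    df = fits_frame(usable)
    bl = df[df["model"] == "BL"].set_index("participant_id")["rmsd"]
    rows = []
    for model in MODELS:
        sub = df[df["model"] == model]
        if sub.empty:
            continue
        rmsds = sub.set_index("participant_id")["rmsd"]
        row: dict[str, object] = {
            "model": model,
            "n_participants": len(sub),
            "mean_rmsd": float(rmsds.mean()),
            "mean_rmsd_vs_BL": (
                float((rmsds - bl.reindex(rmsds.index)).mean()) if len(bl) else float("nan")
            ),
        }
        params = sub["parameter"].dropna().astype(float)
        if model == "DS" and len(params):
            row["share_param_positive"] = float((params > 1e-6).mean())
            row["param_mean"] = float(params.mean())
            row["param_median"] = float(params.median())
        elif model == "BL_star" and len(params):
            row["share_param_below_1"] = float((params < 1.0).mean())
            row["param_mean"] = float(params.mean())
            row["param_median"] = float(params.median())
        rows.append(row)
    return pd.DataFrame(rows)
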