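"""Synthetic probabilized conditional-inference experiments.

Raw data from probabilized-task experiments are rarely shared, so every
pipeline stage is exercised against generated datasets that share the statistical structure the analyses
assume:

* each participant x conditional carries a latent *coherent* joint
  distribution over (p and q, p and not-q, not-p and q, not-p and not-q),
  drawn from a Dirichlet whose pq pseudo-count is raised by a believability
  boost — the task uses highly believable conditionals, i.e. P(q|p) high;
* every elicited item is the corresponding derived probability of that joint
  (with P(if p then q) = P(q|p), the conditional-probability reading), plus
  truncated Gaussian response noise on the probability scale;
* the conclusion response follows the dual-source mixture: the knowledge
  component xi is the conclusion marginal of the *noiseless* joint, blended
  with a form profile tau by the participant's latent weight lambda;
* the deductive task returns the tau profile plus noise.

All latent values (joints, lambda, tau, xi) are returned alongside the
dataset so that recovery of the fitted parameters can be checked against
ground truth.

Noisy responses are discretized to the instrument's 0-100 integer grid.
With ``noise_sd = 0`` the generator instead emits exact probabilities: the
noiseless mode is the idealized coherent reasoner used for theorem checks
(interval membership, p-validity), which hold in exact arithmetic but can be
broken by rounding premises and conclusion to the grid independently.  Pass
``discretize`` explicitly to override either default.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .dataset_io import (
    INFERENCES,
    MINOR_EVENT,
    ROLES,
    DeductiveRecord,
    ExperimentDataset,
    InferenceRecord,
    ProbEstimate,
)
from .dual_source import ds_predict

__all__ = [
    "JointDistribution",
    "SyntheticConfig",
    "ConfigError",
    "DegenerateJointError",
    "sample_joint",
    "derive_estimates",
    "role_values",
    "generate_dataset",
]

#: Pool of everyday-conditional identifiers a participant's four are drawn from.
_N_CONDITIONAL_POOL = 16

#: The two abstract conditionals of the deductive task.
_ABSTRACT_CONDITIONALS = ("A1", "A2")


class ConfigError(ValueError):
    """A generator configuration violates its invariants."""


class DegenerateJointError(ValueError):
    """A joint distribution has a zero marginal where a conditional
    probability is required."""


@dataclass(frozen=True)
class JointDistribution:
    """Coherent joint over p, q and their complements: four cells on the simplex."""

    pq: float
    p_nq: float
    np_q: float
    np_nq: float

    def __post_init__(self) -> None:
        cells = (self.pq, self.p_nq, self.np_q, self.np_nq)
        if any(c < 0 for c in cells):
            raise ValueError(f"negative cell in joint {cells}")
        if abs(sum(cells) - 1.0) > 1e-12:
            raise ValueError(f"joint cells {cells} do not sum to 1")

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.pq, self.p_nq, self.np_q, self.np_nq)

    @property
    def p(self) -> float:
        return self.pq + self.p_nq

    @property
    def q(self) -> float:
        return self.pq + self.np_q


def _lambda_sampler(spec: tuple, rng: np.random.Generator) -> float:
    kind = spec[0]
    if kind == "point":
        return float(spec[1])
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if kind == "beta":
        return float(rng.beta(spec[1], spec[2]))
    raise ConfigError(f"unknown lambda_dist kind {kind!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    Defaults emulate a typical deployment of the task: 30 participants,
    four blocks each,
    highly believable everyday conditionals — joint priors chosen so that
    P(q|p) ~ Beta(1.6, 1) (mean 0.62, sd 0.26) and P(q|not-p) ~ Beta(0.8, 2.2)
    (mean 0.27, sd 0.22), matching the response profile such materials elicit —
    a form-endorsement profile MP > MT > AC = DA, latent mixture weights
    lambda ~ uniform(0, 0.7), and response noise sd 0.05 on the probability
    scale.
    """

    n_participants: int = 30
    conditionals_per_participant: int = 4
    joint_prior_weights: tuple[float, float, float, float] = (1.0, 1.0, 0.8, 2.2)
    believability_boost: float = 0.6
    lambda_dist: tuple = ("uniform", 0.0, 0.7)
    tau_profile: Mapping[str, float] = field(
        default_factory=lambda: {"MP": 0.95, "MT": 0.75, "AC": 0.55, "DA": 0.55}
    )
    noise_sd: float = 0.05
    seed: int = 0
    discretize: bool | None = None  # None: discretize iff noise_sd > 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if not 1 <= self.conditionals_per_participant <= len(INFERENCES):
            raise ConfigError(
                f"conditionals_per_participant must be in [1, {len(INFERENCES)}] "
                "(one inference form per block)"
            )
        if len(self.joint_prior_weights) != 4 or any(
            w <= 0 for w in self.joint_prior_weights
        ):
            raise ConfigError("joint_prior_weights must be four positive pseudo-counts")
        if self.believability_boost < 0:
            raise ConfigError("believability_boost must be nonnegative")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        missing = [inf for inf in INFERENCES if inf not in self.tau_profile]
        if missing:
            raise ConfigError(f"tau_profile missing inference(s): {', '.join(missing)}")
        for inf in INFERENCES:
            t = self.tau_profile[inf]
            if not 0.0 <= t <= 1.0:
                raise ConfigError(f"tau_profile[{inf}] = {t} outside [0, 1]")
        kind = self.lambda_dist[0]
        if kind == "point":
            if not 0.0 <= self.lambda_dist[1] <= 1.0:
                raise ConfigError("point lambda outside [0, 1]")
        elif kind == "uniform":
            lo, hi = self.lambda_dist[1], self.lambda_dist[2]
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigError("uniform lambda bounds must satisfy 0 <= lo <= hi <= 1")
        elif kind == "beta":
            if self.lambda_dist[1] <= 0 or self.lambda_dist[2] <= 0:
                raise ConfigError("beta lambda shapes must be positive")
        else:
            raise ConfigError(f"unknown lambda_dist kind {kind!r}")

    @property
    def effective_discretize(self) -> bool:
        return self.noise_sd > 0 if self.discretize is None else self.discretize

    def digest(self) -> str:
        """Short stable hash of the configuration, for provenance stamps."""
        payload = yaml.safe_dump(
            {**asdict(self), "tau_profile": dict(self.tau_profile),
             "lambda_dist": list(self.lambda_dist),
             "joint_prior_weights": list(self.joint_prior_weights)},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def sample_joint(rng: np.random.Generator, config: SyntheticConfig) -> JointDistribution:
    """Draw one coherent joint distribution.

    A Dirichlet draw over the four cells whose pq pseudo-count is raised by
    the believability boost, tilting P(q|p) = pq/(pq + p_nq) upward: under a
    Dirichlet, P(q|p) ~ Beta(w_pq + boost, w_p_nq) independently of the
    remaining cells, so any positive boost makes high-believability
    conditionals stochastically dominant.
    """
    config.validate()
    weights = np.asarray(config.joint_prior_weights, dtype=float).copy()
    weights[0] += config.believability_boost
    cells = rng.dirichlet(weights)
    # renormalize away float drift so the simplex invariant holds at 1e-12
    cells = cells / cells.sum()
    return JointDistribution(*map(float, cells))


def derive_estimates(joint: JointDistribution) -> dict[str, float]:
    """All probabilities an ideal participant would report for one joint.

    Conditional-probability reading throughout: the ``conditional`` item
    equals P(q|p).  Raises :class:`DegenerateJointError` when a marginal
    needed for a conditional probability is zero.
    """
    p, q = joint.p, joint.q
    if p <= 0.0 or p >= 1.0:
        raise DegenerateJointError(
            f"P(p) = {p}: conditional probabilities P(q|p)/P(q|not-p) undefined"
        )
    q_given_p = joint.pq / p
    q_given_notp = joint.np_q / (1.0 - p)
    return {
        "conditional": q_given_p,
        "q_given_p": q_given_p,
        "q_given_notp": q_given_notp,
        "conj": joint.pq,
        "material": 1.0 - joint.p_nq,
        "p": p,
        "q": q,
        "not_p": 1.0 - p,
        "not_q": 1.0 - q,
    }


def role_values(joint: JointDistribution, inference: str) -> dict[str, float]:
    """The seven non-conclusion item values for one inference block."""
    est = derive_estimates(joint)
    minor_event, conclusion_event = MINOR_EVENT[inference]
    return {
        "conditional": est["conditional"],
        "minor": est[minor_event],
        "q_given_p": est["q_given_p"],
        "conj": est["conj"],
        "material": est["material"],
        "q_given_notp": est["q_given_notp"],
        "event": est[conclusion_event],
    }


def _respond(
    value: float, rng: np.random.Generator, noise_sd: float, discretize: bool
) -> tuple[float, float]:
    """(probability, raw) response: noise, clip to bounds, optional 1% grid."""
    if noise_sd > 0:
        value = value + rng.normal(0.0, noise_sd)
    value = min(max(value, 0.0), 1.0)
    if discretize:
        raw = float(round(value * 100.0))
        value = raw / 100.0
    else:
        raw = value * 100.0
    return value, raw


def generate_dataset(config: SyntheticConfig) -> tuple[ExperimentDataset, pd.DataFrame]:
    """Generate one experiment plus its latent truth table.

    Returns the dataset and a truth DataFrame with one row per generated
    inference block: participant, conditional, inference, the participant's
    lambda, the block's tau and xi, and the four joint cells.  Bit-for-bit
    reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    discretize = config.effective_discretize

    inference_records: list[InferenceRecord] = []
    deductive_records: list[DeductiveRecord] = []
    truth_rows: list[dict[str, object]] = []

    for i in range(config.n_participants):
        pid = f"P{i + 1:03d}"
        lam = _lambda_sampler(config.lambda_dist, rng)

        # one conditional per inference form, drawn without replacement from
        # the pool and assigned to the forms in randomized order
        conditionals = rng.choice(
            _N_CONDITIONAL_POOL, size=config.conditionals_per_participant, replace=False
        )
        forms = list(rng.permutation(INFERENCES)[: config.conditionals_per_participant])

        for cond_idx, inference in zip(conditionals, forms):
            cid = f"C{int(cond_idx) + 1:02d}"
            # reject the (probability-zero under a continuous Dirichlet, but
            # float-possible) degenerate joints with an empty p or not-p margin
            while True:
                joint = sample_joint(rng, config)
                if 0.0 < joint.p < 1.0:
                    break
            values = role_values(joint, inference)

            tau = float(config.tau_profile[inference])
            _, conclusion_event = MINOR_EVENT[inference]
            xi = derive_estimates(joint)[conclusion_event]  # noiseless knowledge estimate
            conclusion = ds_predict(xi, tau, lam)

            estimates: dict[str, ProbEstimate] = {}
            for role in ROLES:
                latent = conclusion if role == "conclusion" else values[role]
                value, raw = _respond(latent, rng, config.noise_sd, discretize)
                estimates[role] = ProbEstimate(value=value, raw=raw, role=role)

            inference_records.append(
                InferenceRecord(
                    participant_id=pid,
                    conditional_id=cid,
                    inference=inference,
                    estimates=estimates,
                )
            )
            truth_rows.append(
                {
                    "participant_id": pid,
                    "conditional_id": cid,
                    "inference": inference,
                    "lambda": lam,
                    "tau": tau,
                    "xi": xi,
                    "pq": joint.pq,
                    "p_nq": joint.p_nq,
                    "np_q": joint.np_q,
                    "np_nq": joint.np_nq,
                }
            )

        for acid in _ABSTRACT_CONDITIONALS:
            for inference in INFERENCES:
                value, _ = _respond(
                    float(config.tau_profile[inference]), rng, config.noise_sd, discretize
                )
                deductive_records.append(
                    DeductiveRecord(
                        participant_id=pid,
                        abstract_conditional_id=acid,
                        inference=inference,
                        endorsement=value,
                    )
                )

    dataset = ExperimentDataset(
        inference_records=inference_records,
        deductive_records=deductive_records,
        provenance=f"synthetic seed={config.seed} config={config.digest()}",
    )
    truth = pd.DataFrame(truth_rows)
    return dataset, truth
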