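"""Data model and tidy tabular I/O for the probabilized conditional inference task.

Two tables make up a dataset:

* the *probabilized* table — one row per elicited item, long format, columns
  ``participant_id, conditional_id, inference, role, response_raw`` — holding the
  eight items of each conditional x inference block;
* the *deductive* table — one row per abstract-conditional x inference, columns
  ``participant_id, abstract_conditional_id, inference, response_raw`` — holding
  the form-endorsement task (4 inferences x 2 abstract conditionals).

Responses are elicited on a 0-100 scale; files carry that raw scale, while all
in-memory probabilities live on [0, 1] (``value = raw / 100``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "ROLES",
    "INFERENCES",
    "MINOR_EVENT",
    "ProbEstimate",
    "InferenceRecord",
    "DeductiveRecord",
    "ExperimentDataset",
    "SchemaError",
    "load_dataset",
    "write_dataset",
    "validate_dataset",
]

#: The four conditional inference forms: modus ponens, modus tollens,
#: affirmation of the consequent, denial of the antecedent.
INFERENCES: tuple[str, ...] = ("MP", "MT", "AC", "DA")

#: The eight item roles elicited per block, in presentation order.
ROLES: tuple[str, ...] = (
    "conditional",    # P(if p then q)
    "minor",          # P(p) / P(not-q) / P(q) / P(not-p) for MP/MT/AC/DA
    "conclusion",     # the conditional-inference response
    "q_given_p",      # P(q|p)
    "conj",           # P(p and q)
    "material",       # P(not-p or q)
    "q_given_notp",   # P(q|not-p), the probability of alternatives
    "event",          # conclusion event without premises (not analyzed)
)

#: Which marginal the minor premise and the conclusion event refer to,
#: per inference form.
MINOR_EVENT: dict[str, tuple[str, str]] = {
    "MP": ("p", "q"),
    "MT": ("not_q", "not_p"),
    "AC": ("q", "p"),
    "DA": ("not_p", "not_q"),
}

_PROB_COLUMNS = ["participant_id", "conditional_id", "inference", "role", "response_raw"]
_DED_COLUMNS = ["participant_id", "abstract_conditional_id", "inference", "response_raw"]

#: Roles a record can lack with only a warning; all analyses ignore ``event``.
_OPTIONAL_ROLES = frozenset({"event"})


class SchemaError(ValueError):
    """A file does not conform to the documented tidy schema."""


@dataclass(frozen=True)
class ProbEstimate:
    """A single elicited probability.

    ``value`` is the probability on [0, 1]; ``raw`` the original 0-100
    response; ``role`` one of :data:`ROLES`.
    """

    value: float
    raw: float
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown item role {self.role!r}")
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"probability {self.value} outside [0, 1] for role {self.role}")

    @classmethod
    def from_raw(cls, raw: float, role: str) -> "ProbEstimate":
        if not 0.0 <= raw <= 100.0:
            raise ValueError(f"raw response {raw} outside [0, 100] for role {role}")
        return cls(value=raw / 100.0, raw=raw, role=role)


@dataclass(frozen=True)
class InferenceRecord:
    """One conditional x inference block of the probabilized task."""

    participant_id: str
    conditional_id: str
    inference: str
    estimates: Mapping[str, ProbEstimate]

    def __post_init__(self) -> None:
        if self.inference not in INFERENCES:
            raise ValueError(f"unknown inference {self.inference!r}")

    def value(self, role: str) -> float:
        """Probability of the item with the given role."""
        try:
            return self.estimates[role].value
        except KeyError:
            raise KeyError(
                f"record {self.participant_id}/{self.conditional_id}/{self.inference} "
                f"has no {role!r} item"
            ) from None

    # Shorthands used throughout the analyses.
    @property
    def c(self) -> float:
        """Elicited probability of the conditional, P(if p then q)."""
        return self.value("conditional")

    @property
    def m(self) -> float:
        """Probability of the minor premise (role depends on inference)."""
        return self.value("minor")

    @property
    def b(self) -> float:
        """Probability of alternatives, P(q|not-p)."""
        return self.value("q_given_notp")

    @property
    def response(self) -> float:
        """Conclusion estimate for the conditional inference."""
        return self.value("conclusion")


@dataclass(frozen=True)
class DeductiveRecord:
    """One abstract-conditional x inference endorsement from the deductive task."""

    participant_id: str
    abstract_conditional_id: str
    inference: str
    endorsement: float

    def __post_init__(self) -> None:
        if self.inference not in INFERENCES:
            raise ValueError(f"unknown inference {self.inference!r}")
        if not 0.0 <= self.endorsement <= 1.0:
            raise ValueError(f"endorsement {self.endorsement} outside [0, 1]")


@dataclass
class ExperimentDataset:
    """A full experiment: probabilized blocks plus the deductive task."""

    inference_records: list[InferenceRecord] = field(default_factory=list)
    deductive_records: list[DeductiveRecord] = field(default_factory=list)
    provenance: str = ""

    @property
    def participants(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.inference_records:
            seen.setdefault(rec.participant_id, None)
        return list(seen)

    def records_for(self, participant_id: str) -> list[InferenceRecord]:
        return [r for r in self.inference_records if r.participant_id == participant_id]

    def deductive_for(self, participant_id: str) -> list[DeductiveRecord]:
        return [r for r in self.deductive_records if r.participant_id == participant_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExperimentDataset):
            return NotImplemented
        return (
            self.inference_records == other.inference_records
            and self.deductive_records == other.deductive_records
        )


def _require_columns(df: pd.DataFrame, expected: list[str], what: str) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file is missing required column(s): {', '.join(missing)}")


def _check_raw(df: pd.DataFrame, what: str) -> None:
    raw = pd.to_numeric(df["response_raw"], errors="coerce")
    bad = df.index[raw.isna() | (raw < 0) | (raw > 100)]
    if len(bad):
        row = int(bad[0])
        raise ValueError(
            f"{what} file: response_raw {df.loc[row, 'response_raw']!r} outside "
            f"[0, 100] at row {row}"
        )


def load_dataset(
    probabilized_path: str | Path,
    deductive_path: str | Path | None = None,
    dialect: str = "csv",
) -> ExperimentDataset:
    """Read a dataset from its tidy file(s).

    Parameters
    ----------
    probabilized_path
        Long-format file of the probabilized task.
    deductive_path
        Optional file of the deductive task; required downstream only for
        dual-source fits.
    dialect
        ``"csv"`` or ``"tsv"``.

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValueError
        If a raw response lies outside [0, 100] (the offending row is named).
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")

    prob = pd.read_csv(probabilized_path, sep=sep, comment="#", dtype={"response_raw": float})
    _require_columns(prob, _PROB_COLUMNS, "probabilized")
    _check_raw(prob, "probabilized")

    records: list[InferenceRecord] = []
    for (pid, cid, inf), grp in prob.groupby(
        ["participant_id", "conditional_id", "inference"], sort=False
    ):
        estimates: dict[str, ProbEstimate] = {}
        for _, row in grp.iterrows():
            role = str(row["role"])
            if role not in ROLES:
                raise SchemaError(f"unknown role {role!r} for participant {pid}")
            estimates[role] = ProbEstimate.from_raw(float(row["response_raw"]), role)
        missing = [r for r in ROLES if r not in estimates]
        hard = [r for r in missing if r not in _OPTIONAL_ROLES]
        if hard:
            raise SchemaError(
                f"participant {pid}, conditional {cid}, {inf}: missing role(s) "
                f"{', '.join(hard)}"
            )
        if missing:
            warnings.warn(
                f"participant {pid}, conditional {cid}, {inf}: optional role(s) "
                f"{', '.join(missing)} absent",
                stacklevel=2,
            )
        records.append(
            InferenceRecord(
                participant_id=str(pid),
                conditional_id=str(cid),
                inference=str(inf),
                estimates=estimates,
            )
        )

    deductive: list[DeductiveRecord] = []
    if deductive_path is not None:
        ded = pd.read_csv(deductive_path, sep=sep, comment="#", dtype={"response_raw": float})
        _require_columns(ded, _DED_COLUMNS, "deductive")
        _check_raw(ded, "deductive")
        for _, row in ded.iterrows():
            deductive.append(
                DeductiveRecord(
                    participant_id=str(row["participant_id"]),
                    abstract_conditional_id=str(row["abstract_conditional_id"]),
                    inference=str(row["inference"]),
                    endorsement=float(row["response_raw"]) / 100.0,
                )
            )

    provenance = str(probabilized_path)
    if deductive_path is not None:
        provenance += f" + {deductive_path}"
    return ExperimentDataset(records, deductive, provenance=provenance)


def dataset_frames(dataset: ExperimentDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dataset as (probabilized, deductive) DataFrames on the raw 0-100 scale."""
    prob_rows = [
        {
            "participant_id": rec.participant_id,
            "conditional_id": rec.conditional_id,
            "inference": rec.inference,
            "role": role,
            "response_raw": rec.estimates[role].raw,
        }
        for rec in dataset.inference_records
        for role in ROLES
        if role in rec.estimates
    ]
    ded_rows = [
        {
            "participant_id": rec.participant_id,
            "abstract_conditional_id": rec.abstract_conditional_id,
            "inference": rec.inference,
            "response_raw": rec.endorsement * 100.0,
        }
        for rec in dataset.deductive_records
    ]
    prob = pd.DataFrame(prob_rows, columns=_PROB_COLUMNS)
    ded = pd.DataFrame(ded_rows, columns=_DED_COLUMNS)
    return prob, ded


def write_dataset(
    dataset: ExperimentDataset,
    probabilized_path: str | Path,
    deductive_path: str | Path | None = None,
    dialect: str = "csv",
) -> tuple[Path, Path | None]:
    """Write a dataset back to its tidy file(s) on the raw 0-100 scale.

    The output re-loads to an equal dataset and is byte-identical across
    repeated writes of the same dataset.
    """
    sep = {"csv": ",", "tsv": "\t"}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    prob, ded = dataset_frames(dataset)
    prob_path = Path(probabilized_path)
    prob.to_csv(prob_path, sep=sep, index=False, float_format="%.12g")
    ded_path: Path | None = None
    if deductive_path is not None:
        ded_path = Path(deductive_path)
        ded.to_csv(ded_path, sep=sep, index=False, float_format="%.12g")
    return prob_path, ded_path


def validate_dataset(dataset: ExperimentDataset, require_deductive: bool = False) -> list[str]:
    """Collect invariant violations as human-readable issue strings.

    An empty list means the dataset satisfies all structural invariants.
    Issues are data, not exceptions: a survey of a questionable file should
    not abort on the first problem.
    """
    issues: list[str] = []

    seen_blocks: set[tuple[str, str]] = set()
    for rec in dataset.inference_records:
        key = (rec.participant_id, rec.inference)
        if key in seen_blocks:
            issues.append(
                f"participant {rec.participant_id}: duplicate inference block {rec.inference}"
            )
        seen_blocks.add(key)
        for role in ROLES:
            if role in _OPTIONAL_ROLES:
                continue
            if role not in rec.estimates:
                issues.append(
                    f"participant {rec.participant_id}, conditional {rec.conditional_id}, "
                    f"{rec.inference}: missing role {role}"
                )

    ded_counts: dict[str, int] = {}
    for rec in dataset.deductive_records:
        ded_counts[rec.participant_id] = ded_counts.get(rec.participant_id, 0) + 1
    for pid, n in ded_counts.items():
        if n != 8:
            issues.append(f"participant {pid}: {n} deductive records, expected 8 (4 x 2)")

    if require_deductive:
        for pid in dataset.participants:
            if pid not in ded_counts:
                issues.append(
                    f"participant {pid}: no deductive records but a dual-source fit "
                    "was requested"
                )

    return issues
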