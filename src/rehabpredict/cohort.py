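"""Clinical cohort container: per-dataset records, readers/writers, summaries.

A *dataset* is one (participant, tested side) pair with scores at both
timepoints. Participants may contribute one or two sides. Demographic
summaries are computed per participant so that two-sided participants are
never double-counted; score summaries are computed per dataset.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, fields
from importlib import resources
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import CohortValidationError, SchemaError

SIDES = ("left", "right")
SEXES = ("F", "M")
MS_TYPES = ("RR", "PP", "SP")
INTERVENTION_GROUPS = (1, 2, 3)

#: Mandatory columns of the wide one-row-per-dataset CSV layout.
REQUIRED_COLUMNS = (
    "participant_id", "side", "age", "sex", "ms_type", "chronicity",
    "intervention_group", "edss", "arat_pre", "arat_post",
    "bbt_pre", "bbt_post", "nhpt_pre", "nhpt_post",
)

#: Optional columns: the disability stratum used for block randomization and
#: the conventional body-function scales. Neither is printed in the source
#: cohort; only synthetic cohorts can populate them.
OPTIONAL_COLUMNS = (
    "disability_group", "motricity", "static_fatigue_index",
    "monofilament_index", "sdmt", "fahn_tremor",
)


@dataclass(frozen=True)
class ParticipantRecord:
    """One person-side dataset: demographics plus pre/post clinical scores.

    ARAT is an integer 0-57 (higher = better), BBT is blocks per minute
    (higher = better), NHPT is seconds (lower = better), EDSS is ordinal
    0-10 in 0.5 steps.
    """

    participant_id: str
    side: str
    age: float
    sex: str
    ms_type: str
    chronicity: float
    intervention_group: int
    edss: float
    arat_pre: int
    arat_post: int
    bbt_pre: float
    bbt_post: float
    nhpt_pre: float
    nhpt_post: float
    disability_group: float | None = None
    motricity: float | None = None
    static_fatigue_index: float | None = None
    monofilament_index: float | None = None
    sdmt: float | None = None
    fahn_tremor: float | None = None

    def __post_init__(self) -> None:
        ctx = f"dataset ({self.participant_id}, {self.side})"
        if self.side not in SIDES:
            raise CohortValidationError(f"{ctx}: side must be one of {SIDES}")
        if self.sex not in SEXES:
            raise CohortValidationError(f"{ctx}: sex must be one of {SEXES}")
        if self.ms_type not in MS_TYPES:
            raise CohortValidationError(f"{ctx}: ms_type must be one of {MS_TYPES}")
        if self.intervention_group not in INTERVENTION_GROUPS:
            raise CohortValidationError(
                f"{ctx}: intervention_group must be in {INTERVENTION_GROUPS}")
        if not self.age > 0:
            raise CohortValidationError(f"{ctx}: age must be positive")
        if self.chronicity < 0:
            raise CohortValidationError(f"{ctx}: chronicity must be non-negative")
        if not (0 <= self.edss <= 10) or (2 * self.edss) % 1 != 0:
            raise CohortValidationError(
                f"{ctx}: edss must lie in [0, 10] in steps of 0.5")
        for name in ("arat_pre", "arat_post"):
            v = getattr(self, name)
            if not (0 <= v <= 57) or v != int(v):
                raise CohortValidationError(
                    f"{ctx}: {name}={v} outside integer range [0, 57]")
        for name in ("bbt_pre", "bbt_post"):
            if getattr(self, name) < 0:
                raise CohortValidationError(f"{ctx}: {name} must be >= 0")
        for name in ("nhpt_pre", "nhpt_post"):
            if not getattr(self, name) > 0:
                raise CohortValidationError(f"{ctx}: {name} must be > 0")

    @property
    def dataset_id(self) -> str:
        return f"{self.participant_id}-{self.side}"


@dataclass
class Cohort:
    """Ordered collection of :class:`ParticipantRecord` with provenance."""

    records: list[ParticipantRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            key = (rec.participant_id, rec.side)
            if key in seen:
                raise CohortValidationError(f"duplicate dataset {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ParticipantRecord]:
        return iter(self.records)

    @property
    def participant_ids(self) -> list[str]:
        """Unique participant ids in order of first appearance."""
        out: list[str] = []
        for rec in self.records:
            if rec.participant_id not in out:
                out.append(rec.participant_id)
        return out

    @property
    def dataset_ids(self) -> list[str]:
        return [rec.dataset_id for rec in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Wide one-row-per-dataset table, indexed by dataset id."""
        cols = [f.name for f in fields(ParticipantRecord)]
        df = pd.DataFrame(
            [{c: getattr(r, c) for c in cols} for r in self.records],
            index=pd.Index(self.dataset_ids, name="dataset_id"),
        )
        return df

    def write_csv(self, path) -> None:
        self.to_frame().reset_index(drop=True).to_csv(path, index=False)


def _records_from_frame(df: pd.DataFrame) -> list[ParticipantRecord]:
    records = []
    for i, row in df.iterrows():
        kwargs = {c: row[c] for c in REQUIRED_COLUMNS}
        kwargs["participant_id"] = str(kwargs["participant_id"])
        kwargs["side"] = str(kwargs["side"]).lower()
        kwargs["sex"] = str(kwargs["sex"])
        kwargs["ms_type"] = str(kwargs["ms_type"])
        try:
            kwargs["intervention_group"] = int(kwargs["intervention_group"])
            kwargs["arat_pre"] = int(kwargs["arat_pre"])
            kwargs["arat_post"] = int(kwargs["arat_post"])
        except (TypeError, ValueError) as exc:
            raise CohortValidationError(f"row {i}: non-numeric score ({exc})")
        for c in OPTIONAL_COLUMNS:
            if c in df.columns and pd.notna(row[c]):
                kwargs[c] = float(row[c])
        try:
            records.append(ParticipantRecord(**kwargs))
        except CohortValidationError as exc:
            raise CohortValidationError(f"row {i}: {exc}") from exc
    return records


def load_cohort(path, provenance: str | None = None) -> Cohort:
    """Read a wide one-row-per-dataset CSV into a validated :class:`Cohort`.

    Raises :class:`SchemaError` for an empty file or missing mandatory
    columns and :class:`CohortValidationError` (naming the row) for
    out-of-range values.
    """
    try:
        df = pd.read_csv(path, dtype={"participant_id": str})
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"{path}: not a readable delimited table ({exc})")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    if df.empty:
        raise SchemaError(f"{path}: table has no rows")
    return Cohort(_records_from_frame(df), provenance or str(path))


def load_study_cohort() -> Cohort:
    """The bundled study cohort: 20 datasets from 11 persons with MS.

    Nine participants contributed both sides; participants 02 and 06
    contributed a single side each.
    """
    text = resources.files("rehabpredict.data").joinpath(
        "study_cohort.csv").read_text(encoding="utf-8")
    df = pd.read_csv(io.StringIO(text), dtype={"participant_id": str})
    return Cohort(_records_from_frame(df), provenance="bundled study cohort")


def summarize_cohort(cohort: Cohort) -> dict:
    """Descriptive statistics of a cohort.

    Demographics (age, EDSS, sex, MS type) are summarized over unique
    participants; clinical scores over datasets. Standard deviations use the
    sample (n-1) convention and are reported as NaN for a single observation.
    """
    if len(cohort) == 0:
        raise CohortValidationError("cannot summarize an empty cohort")
    df = cohort.to_frame()
    per_part = df.groupby("participant_id").first()

    def _ms(s: pd.Series) -> dict:
        return {"mean": float(s.mean()),
                "sd": float(s.std(ddof=1)) if len(s) > 1 else float("nan")}

    summary: dict = {
        "n_participants": int(per_part.shape[0]),
        "n_datasets": int(df.shape[0]),
        "age": _ms(per_part["age"]),
        "edss": _ms(per_part["edss"]),
        "sex_counts": per_part["sex"].value_counts().to_dict(),
        "ms_type_counts": per_part["ms_type"].value_counts().to_dict(),
        "scores": {},
    }
    for score in ("arat", "bbt", "nhpt"):
        summary["scores"][score] = {
            "pre": _ms(df[f"{score}_pre"]),
            "post": _ms(df[f"{score}_post"]),
        }
    return summary
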