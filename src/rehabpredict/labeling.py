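"""Smallest-real-difference (SRD) responder labeling of clinical changes.

A change in ARAT, BBT or NHPT counts as a *considerable improvement* only
when it strictly exceeds the scale's smallest real difference — the
magnitude below which a test-retest difference cannot be distinguished from
measurement noise. ARAT and BBT improve upward, NHPT (a timed test)
improves downward; changes are reported improvement-positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import Cohort
from .errors import LabelingError, ParameterError

SCALES = ("arat", "bbt", "nhpt")

#: Scales on which a *decrease* of the raw score is an improvement.
LOWER_IS_BETTER = frozenset({"nhpt"})


@dataclass(frozen=True)
class SRDThresholds:
    """Published smallest real differences for neurological subjects.

    ARAT in points, BBT in blocks/min, NHPT in seconds; all on the raw
    scale of the assessment.
    """

    arat: float = 5.27
    bbt: float = 8.11
    nhpt: float = 5.32

    def __post_init__(self) -> None:
        for scale in SCALES:
            if not getattr(self, scale) > 0:
                raise ParameterError(f"SRD for {scale} must be positive")

    def __getitem__(self, scale: str) -> float:
        return getattr(self, scale)


DEFAULT_SRD = SRDThresholds()


def improvement_change(pre: float, post: float, scale: str) -> float:
    """Signed pre-to-post change, positive in the direction of improvement."""
    if scale not in SCALES:
        raise ParameterError(f"unknown scale {scale!r}; expected one of {SCALES}")
    if pre is None or post is None or pd.isna(pre) or pd.isna(post):
        raise LabelingError(f"{scale}: both timepoints required for labeling")
    return float(pre - post) if scale in LOWER_IS_BETTER else float(post - pre)


def is_responder(change: float, srd: float) -> bool:
    """True iff the improvement strictly exceeds the smallest real difference."""
    if not srd > 0:
        raise ParameterError("SRD threshold must be positive")
    return change > srd


def label_cohort(cohort: Cohort,
                 thresholds: SRDThresholds = DEFAULT_SRD) -> pd.DataFrame:
    """Per-dataset responder labels for all three activity scales.

    Returns a table indexed by dataset id with, per scale, the
    improvement-positive change (``<scale>_change``) and the boolean label
    (``<scale>_improved``). Use :func:`responder_counts` for the per-scale
    totals.
    """
    rows = []
    for rec in cohort:
        row: dict = {"participant_id": rec.participant_id, "side": rec.side}
        for scale in SCALES:
            change = improvement_change(
                getattr(rec, f"{scale}_pre"), getattr(rec, f"{scale}_post"), scale)
            row[f"{scale}_change"] = change
            row[f"{scale}_improved"] = is_responder(change, thresholds[scale])
        rows.append(row)
    return pd.DataFrame(rows, index=pd.Index(cohort.dataset_ids, name="dataset_id"))


def responder_counts(labels: pd.DataFrame) -> dict[str, int]:
    """Number of considerably improved datasets per scale."""
    return {scale: int(labels[f"{scale}_improved"].sum()) for scale in SCALES}
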