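"""Metrics against reference label sets.

The same ratio (TP + TN) / (P + N) carries two names depending on the
reference: it is the *accuracy* when scored against germination outcomes
from the sowing experiment, and the *recognition rate* when scored
against a human expert's visual ratings.  Labels are encoded
germinating = 1, non-germinating = 0 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .discrimination import ConfusionCounts, accuracy
from .errors import AlignmentError


@dataclass(frozen=True)
class ReferenceSet:
    """Binary reference labels: germination outcomes or one expert."""

    source: str                      # "germination" or e.g. "expert_1"
    table: pd.DataFrame              # columns: sequence_id, label

    def __post_init__(self) -> None:
        ids = self.table["sequence_id"]
        if ids.duplicated().any():
            raise ValueError("reference sequence_ids must be unique")
        if not self.table["label"].isin([0, 1]).all():
            raise ValueError("reference labels must be binary 0/1")


@dataclass(frozen=True)
class EvaluationReport:
    source: str
    counts: ConfusionCounts
    metric_name: str                 # "accuracy" or "recognition_rate"
    metric_value: float
    classifier: str = ""


def evaluate(predictions: pd.DataFrame, reference: ReferenceSet,
             classifier: str = "") -> EvaluationReport:
    """Join predictions to the reference on sequence_id and score them.

    ``predictions`` needs columns ``sequence_id`` and ``prediction``
    (0/1).  Mismatched id sets raise ``AlignmentError`` listing the
    missing ids.
    """
    pred_ids = set(predictions["sequence_id"])
    ref_ids = set(reference.table["sequence_id"])
    if pred_ids != ref_ids:
        raise AlignmentError(missing_in_predictions=ref_ids - pred_ids,
                             missing_in_reference=pred_ids - ref_ids)
    merged = predictions.merge(reference.table, on="sequence_id")
    pred = merged["prediction"].to_numpy(dtype=int)
    lab = merged["label"].to_numpy(dtype=int)
    counts = ConfusionCounts(
        tp=int(((pred == 1) & (lab == 1)).sum()),
        fp=int(((pred == 1) & (lab == 0)).sum()),
        tn=int(((pred == 0) & (lab == 0)).sum()),
        fn=int(((pred == 0) & (lab == 1)).sum()),
    )
    name = "accuracy" if reference.source == "germination" else "recognition_rate"
    return EvaluationReport(source=reference.source, counts=counts,
                            metric_name=name, metric_value=accuracy(counts),
                            classifier=classifier)


def report_row(report: EvaluationReport) -> dict:
    c = report.counts
    return {
        "source": report.source, "classifier": report.classifier,
        "metric": report.metric_name, "value": report.metric_value,
        "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn,
    }
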