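"""Evaluating predicted falls against manually annotated ground truth.

Predicted and ground-truth fall timestamps are matched one-to-one: a
prediction is accurate when it lies within ±1 second of a ground-truth
timestamp.  Matching is maximum-cardinality, realized by a two-pointer
sweep over the sorted lists (optimal for a symmetric tolerance on sorted
timestamps; ties resolve to the earliest pairing).  Unmatched
predictions are false positives, unmatched truths false negatives.

Both the false-positive and false-negative percentages use the number
of *predicted* falls as denominator.  The more conventional choice for
false negatives would be the ground-truth count; the predicted-fall
denominator is used here so hourly reports and their totals share one
consistent scale, and it is stated explicitly wherever rates appear.

The module also provides Cohen's kappa for annotator-reliability
screening: recordings whose inter-annotator kappa falls below 0.75 are
excluded (exactly 0.75 is kept — only "less than" fails).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .core import FlyfallError, ValidationError

DEFAULT_TOLERANCE_S = 1.0
KAPPA_CUTOFF = 0.75


@dataclass
class MatchResult:
    """Outcome of predicted-vs-truth timestamp matching."""

    true_positives: list[tuple[float, float]] = field(default_factory=list)
    false_positives: list[float] = field(default_factory=list)
    false_negatives: list[float] = field(default_factory=list)

    @property
    def n_predicted(self) -> int:
        return len(self.true_positives) + len(self.false_positives)

    @property
    def n_truth(self) -> int:
        return len(self.true_positives) + len(self.false_negatives)

    @property
    def fp_rate(self) -> float:
        """False positives as a percent of predicted falls."""
        if self.n_predicted == 0:
            return 0.0
        return 100.0 * len(self.false_positives) / self.n_predicted

    @property
    def fn_rate(self) -> float:
        """False negatives as a percent of predicted falls (see module note)."""
        if self.n_predicted == 0:
            return 0.0
        return 100.0 * len(self.false_negatives) / self.n_predicted

    @property
    def recall(self) -> float:
        return 1.0 if self.n_truth == 0 else len(self.true_positives) / self.n_truth

    @property
    def precision(self) -> float:
        return (
            1.0
            if self.n_predicted == 0
            else len(self.true_positives) / self.n_predicted
        )


def match_events(
    predicted: Sequence[float],
    truth: Sequence[float],
    tolerance_s: float = DEFAULT_TOLERANCE_S,
) -> MatchResult:
    """Match predicted to ground-truth timestamps under the ±tolerance rule.

    Both lists must be sorted ascending.  The greedy earliest-first
    sweep achieves maximum-cardinality one-to-one matching for a
    symmetric tolerance on sorted lists.
    """
    if tolerance_s < 0:
        raise ValidationError(f"tolerance_s must be >= 0, got {tolerance_s}")
    for name, seq in (("predicted", predicted), ("truth", truth)):
        if any(b < a for a, b in zip(seq, seq[1:])):
            raise ValidationError(f"{name} timestamps must be sorted ascending")
    result = MatchResult()
    i = j = 0
    while i < len(predicted) and j < len(truth):
        p, t = predicted[i], truth[j]
        if abs(p - t) <= tolerance_s:
            result.true_positives.append((p, t))
            i += 1
            j += 1
        elif p < t - tolerance_s:
            result.false_positives.append(p)
            i += 1
        else:
            result.false_negatives.append(t)
            j += 1
    result.false_positives.extend(predicted[i:])
    result.false_negatives.extend(truth[j:])
    return result


TABLE_COLUMNS = ["hour", "predicted", "ground_truth", "potential_fp", "actual_fp", "fn"]


def aggregate_table(rows: pd.DataFrame) -> dict[str, float]:
    """Sum per-hour fall accounting and compute rates.

    ``rows`` needs columns ``predicted, ground_truth, potential_fp,
    actual_fp, fn`` (one row per analyzed hour).  All three rates are
    percentages of total predicted falls, rounded to one decimal.
    """
    rows = pd.DataFrame(rows)
    missing = [c for c in TABLE_COLUMNS[1:] if c not in rows.columns]
    if missing:
        raise ValidationError(f"aggregate_table: missing columns {missing}")
    if (rows[TABLE_COLUMNS[1:]] < 0).any().any():
        raise ValidationError("aggregate_table: counts must be >= 0")
    totals = rows[TABLE_COLUMNS[1:]].sum()
    n_pred = int(totals["predicted"])
    if n_pred == 0 and (totals["potential_fp"] > 0 or totals["actual_fp"] > 0):
        raise FlyfallError("false positives reported with zero total predictions")

    def rate(count: float) -> float:
        return 0.0 if n_pred == 0 else float(round(100.0 * count / n_pred, 1))

    return {
        "predicted_total": n_pred,
        "ground_truth_total": int(totals["ground_truth"]),
        "potential_fp_total": int(totals["potential_fp"]),
        "actual_fp_total": int(totals["actual_fp"]),
        "fn_total": int(totals["fn"]),
        "potential_fp_rate_pct": rate(totals["potential_fp"]),
        "actual_fp_rate_pct": rate(totals["actual_fp"]),
        "fn_rate_pct": rate(totals["fn"]),
    }


def load_reference_table() -> pd.DataFrame:
    """Load the packaged per-hour fall accounting for the reference
    test recording (FLYID#05-26-19): predicted vs ground-truth falls for
    the seven manually annotated hours."""
    with resources.files("flyfall.data").joinpath(
        "table1_ground_truth_vs_predicted.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa: chance-corrected agreement between two annotators.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o and
    chance agreement p_e from the marginal label frequencies.  When both
    sequences are identical and constant the 0/0 form is resolved to 1.0
    (perfect agreement).
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValidationError(f"label sequences differ in length: {len(a)} vs {len(b)}")
    if not a:
        raise ValidationError("label sequences must be non-empty")
    n = len(a)
    labels = sorted(set(a) | set(b), key=repr)
    index = {lab: k for k, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)))
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    p_o = float(np.trace(table)) / n
    p_e = float((table.sum(axis=1) / n) @ (table.sum(axis=0) / n))
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def screen_annotations(
    kappas: Sequence[float], cutoff: float = KAPPA_CUTOFF
) -> tuple[list[float], list[float]]:
    """Partition per-video kappa values into (kept, omitted).

    A video is kept iff its kappa is at least the cutoff; only values
    strictly below the cutoff are omitted.
    """
    for k in kappas:
        if not -1.0 <= k <= 1.0:
            raise ValidationError(f"kappa out of range [-1, 1]: {k}")
    kept = [k for k in kappas if k >= cutoff]
    omitted = [k for k in kappas if k < cutoff]
    return kept, omitted
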