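"""Classification reports, detection-rate tables, multi-seed aggregation,
and McNemar's paired test with Edwards' continuity correction.

The McNemar statistic on the discordant correctness counts is

    chi2 = (|n10 - n01| - 1)^2 / (n10 + n01),

with ``n10`` the images the proposed model got right and the baseline
wrong, ``n01`` the reverse, and the p-value from the upper tail of the
chi-square distribution with one degree of freedom (computed to full
double precision via the regularized incomplete gamma function, so
printed 4-decimal comparisons are pure rounding).

Undefined quantities (zero denominators, single-run SDs, zero
discordant pairs) are reported as ``None`` sentinels, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with nodule (label 1) as positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class ClassMetrics:
    precision: float | None
    recall: float | None
    f1: float | None


@dataclass(frozen=True)
class McNemarResult:
    n00: int  # both models wrong
    n11: int  # both models correct
    n01: int  # baseline-only correct
    n10: int  # proposed-only correct
    chi2: float | None
    p_value: float | None
    message: str = ""


@dataclass(frozen=True)
class RunSummary:
    metric: str
    values: tuple[float, ...]
    mean: float
    sd: float | None  # sample (n-1) standard deviation; None for one run


# ---------------------------------------------------------------------
# per-class report


def _prf(tp: int, fp: int, fn: int) -> ClassMetrics:
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassMetrics(precision, recall, f1)


def confusion_matrix(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionMatrix:
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if y.shape != p.shape:
        raise ValueError("labels and predictions must have equal length")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary")
    return ConfusionMatrix(
        tp=int(((y == 1) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


def per_class_report(labels: Sequence[int], predictions: Sequence[int]) -> dict:
    """Precision/recall/F1 for both classes plus the confusion matrix."""
    cm = confusion_matrix(labels, predictions)
    return {
        "confusion": cm,
        "nodule": _prf(cm.tp, cm.fp, cm.fn),
        "no_nodule": _prf(cm.tn, cm.fn, cm.fp),
    }


# ---------------------------------------------------------------------
# McNemar


def mcnemar_from_counts(n10: int, n01: int, n11: int = 0, n00: int = 0) -> McNemarResult:
    if min(n10, n01, n11, n00) < 0:
        raise ValueError("counts must be non-negative")
    if n10 + n01 == 0:
        return McNemarResult(n00, n11, n01, n10, None, None, "no discordant pairs: statistic undefined")
    chi2 = (abs(n10 - n01) - 1) ** 2 / (n10 + n01)
    p = float(stats.chi2.sf(chi2, df=1))
    return McNemarResult(n00, n11, n01, n10, float(chi2), p)


def mcnemar_test(correct_proposed: Sequence[bool], correct_baseline: Sequence[bool]) -> McNemarResult:
    """Paired comparison from per-image correctness indicators."""
    a = np.asarray(correct_proposed, bool)
    b = np.asarray(correct_baseline, bool)
    if a.shape != b.shape:
        raise ValueError("correctness vectors must be aligned to identical images")
    return mcnemar_from_counts(
        n10=int((a & ~b).sum()),
        n01=int((~a & b).sum()),
        n11=int((a & b).sum()),
        n00=int((~a & ~b).sum()),
    )


def discordant_count(result: McNemarResult) -> int:
    return result.n01 + result.n10


# ---------------------------------------------------------------------
# detection-rate tables


def detection_rate_pct(correct: int, total: int) -> float:
    """Detection rate rendered at one decimal, in percent."""
    if total < 1:
        raise ValueError("stratum must contain at least one positive image")
    return round(100.0 * correct / total, 1)


def rate_improvement(proposed: tuple[int, int], baseline: tuple[int, int]) -> float:
    """Difference of the rounded percentage rates (as printed)."""
    return round(detection_rate_pct(*proposed) - detection_rate_pct(*baseline), 1)


def detection_rate_table(per_model: dict[str, dict[str, tuple[int, int]]]) -> pd.DataFrame:
    """Rows of correct/total, false negatives and rate per model and stratum.

    ``per_model[model][stratum] = (correctly_detected, total_positives)``.
    Empty strata are omitted with a warning column-free skip.
    """
    rows = []
    for model, strata in per_model.items():
        for stratum, (correct, total) in strata.items():
            if total < 1:
                import warnings

                warnings.warn(f"empty stratum {stratum!r} for {model!r} omitted", stacklevel=2)
                continue
            rows.append(
                {
                    "model": model,
                    "stratum": stratum,
                    "correctly_detected": f"{correct}/{total}",
                    "false_negatives": total - correct,
                    "detection_rate_pct": detection_rate_pct(correct, total),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# multi-seed aggregation


def aggregate_runs(metric: str, values: Sequence[float]) -> RunSummary:
    vals = tuple(float(v) for v in values)
    if not vals:
        raise ValueError("no values to aggregate")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else None
    return RunSummary(metric=metric, values=vals, mean=mean, sd=sd)


# ---------------------------------------------------------------------
# predictions files


PREDICTION_COLUMNS = ["image_id", "label", "prediction", "probability"]


def write_predictions(path, image_ids, labels, predictions, probabilities) -> None:
    pd.DataFrame(
        {
            "image_id": image_ids,
            "label": np.asarray(labels, int),
            "prediction": np.asarray(predictions, int),
            "probability": np.asarray(probabilities, float),
        }
    ).to_csv(path, index=False)


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"image_id": str})
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"predictions file missing columns: {sorted(missing)}")
    return df


def mcnemar_from_files(proposed_path, baseline_path) -> McNemarResult:
    """Paired test from two prediction CSVs, aligned by image id."""
    a = read_predictions(proposed_path).set_index("image_id").sort_index()
    b = read_predictions(baseline_path).set_index("image_id").sort_index()
    if not a.index.equals(b.index):
        raise ValueError("prediction files cover different image id sets")
    if not (a["label"] == b["label"]).all():
        raise ValueError("prediction files disagree on ground-truth labels")
    return mcnemar_test(
        (a["prediction"] == a["label"]).to_numpy(),
        (b["prediction"] == b["label"]).to_numpy(),
    )
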