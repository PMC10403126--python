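"""Classification metrics and the compound-level agreement analysis.

Site-level prediction records (true label, argmax label) are summarized as
macro-F1 per split, per-class F1 pooled over all test sets, normalized
confusion matrices, and per-compound accuracies.  Compound accuracies from
two pipelines (e.g. brightfield vs fluorescence) are compared by Pearson
correlation and by the "consistently better / worse" boxes obtained by
thresholding at 0.6 and 0.4.

Per-class F1 with an empty denominator is defined as 0 (standard
convention), which keeps the macro average defined.  DMSO is excluded from
the compound-level analysis: it is a control, not a compound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score

from .config import DMSO_LABEL

TRUE_COL = "moa_label"
PRED_COL = "pred_label"


def _check_records(records: pd.DataFrame) -> None:
    if len(records) == 0:
        raise ValueError("no prediction records")
    for col in (TRUE_COL, PRED_COL):
        if col not in records.columns:
            raise ValueError(f"prediction records lack column {col!r}")


def macro_f1(records: pd.DataFrame) -> float:
    """Unweighted mean of per-class F1 over the classes present."""
    _check_records(records)
    labels = sorted(set(records[TRUE_COL]) | set(records[PRED_COL]))
    return float(f1_score(records[TRUE_COL], records[PRED_COL],
                          labels=labels, average="macro", zero_division=0))


def per_class_f1(records: pd.DataFrame,
                 labels: list[str] | None = None) -> pd.Series:
    _check_records(records)
    if labels is None:
        labels = sorted(set(records[TRUE_COL]) | set(records[PRED_COL]))
    scores = f1_score(records[TRUE_COL], records[PRED_COL], labels=labels,
                      average=None, zero_division=0)
    return pd.Series(scores, index=labels, name="f1")


def pooled_per_class_f1(records_by_split: dict[int, pd.DataFrame],
                        labels: list[str] | None = None,
                        expected_splits: int | None = None
                        ) -> tuple[pd.Series, bool]:
    """Per-class F1 on the records of all test sets pooled together.

    Returns the per-class series with a trailing ``macro_average`` row, and
    a flag that is False when fewer splits than expected were supplied (a
    warning is emitted in that case and the result is partial).
    """
    complete = True
    if expected_splits is not None and len(records_by_split) < expected_splits:
        import warnings
        warnings.warn(
            f"only {len(records_by_split)} of {expected_splits} splits "
            "supplied; pooled F1 is partial", stacklevel=2)
        complete = False
    pooled = pd.concat(records_by_split.values(), ignore_index=True)
    scores = per_class_f1(pooled, labels)
    scores.loc["macro_average"] = scores.mean()
    return scores, complete


def confusion_matrix(records: pd.DataFrame, labels: list[str],
                     normalize: bool = True) -> pd.DataFrame:
    """Confusion matrix over a fixed label vocabulary.

    Rows are true labels; with ``normalize`` each non-empty row sums to 1.
    """
    _check_records(records)
    unknown = (set(records[TRUE_COL]) | set(records[PRED_COL])) - set(labels)
    if unknown:
        raise ValueError(f"labels outside the vocabulary: {sorted(unknown)}")
    m = _sk_confusion(records[TRUE_COL], records[PRED_COL],
                      labels=labels).astype(float)
    if normalize:
        row_sums = m.sum(axis=1, keepdims=True)
        m = np.divide(m, row_sums, out=np.zeros_like(m), where=row_sums > 0)
    return pd.DataFrame(m, index=labels, columns=labels)


def compound_accuracy(records: pd.DataFrame) -> pd.DataFrame:
    """Fraction of each compound's test images predicted as its MoA.

    One row per non-DMSO compound with columns ``compound_id, moa_label,
    accuracy, n_images``.  Records are expected to pool all test sets, so
    each compound appears in exactly one split's test data.
    """
    _check_records(records)
    sub = records[records.compound_id != DMSO_LABEL]
    if sub.empty:
        raise ValueError("no non-control compounds in the records")
    grouped = sub.assign(correct=(sub[TRUE_COL] == sub[PRED_COL])).groupby(
        ["compound_id", TRUE_COL], as_index=False).agg(
            accuracy=("correct", "mean"), n_images=("correct", "size"))
    if (grouped.n_images == 0).any():
        raise ValueError("compound with zero test images")
    return grouped.rename(columns={TRUE_COL: "moa_label"}).sort_values(
        "compound_id", ignore_index=True)


@dataclass
class AgreementResult:
    """Compound-level agreement between one pipeline and two comparators."""

    pearson_ab: float
    pearson_ac: float
    better_set: list[str]
    worse_set: list[str]


def modality_agreement(acc_a: pd.DataFrame, acc_b: pd.DataFrame,
                       acc_c: pd.DataFrame, hi: float = 0.6,
                       lo: float = 0.4) -> AgreementResult:
    """Compare compound accuracies of pipeline A against B and C.

    ``better_set`` holds compounds with A-accuracy >= ``hi`` while both B
    and C are <= ``lo`` (consistently better for A); ``worse_set`` is the
    mirror image.  Pearson r is computed over the common compound order and
    raises for zero-variance inputs.
    """
    frames = []
    for name, df in (("a", acc_a), ("b", acc_b), ("c", acc_c)):
        frames.append(df.set_index("compound_id")["accuracy"].rename(name))
    joined = pd.concat(frames, axis=1)
    if joined.isna().any().any():
        raise ValueError("compound sets differ between the accuracy tables")
    for col in ("a", "b", "c"):
        if np.isclose(joined[col].std(ddof=0), 0.0):
            raise ValueError(
                f"accuracy table {col!r} has zero variance; Pearson "
                "correlation is undefined")
    r_ab = float(stats.pearsonr(joined.a, joined.b).statistic)
    r_ac = float(stats.pearsonr(joined.a, joined.c).statistic)
    better = joined[(joined.a >= hi) & (joined.b <= lo) & (joined.c <= lo)]
    worse = joined[(joined.a <= lo) & (joined.b >= hi) & (joined.c >= hi)]
    return AgreementResult(pearson_ab=r_ab, pearson_ac=r_ac,
                           better_set=sorted(better.index),
                           worse_set=sorted(worse.index))
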