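"""Three-region clinical decision model for failed right-sided AVS.

When only the left adrenal vein is successfully sampled, the LAV/IVC index
still separates the subtypes well enough to act on in most patients.  The
model partitions the positive axis into four regions (defaults at the
0.90-specificity tier):

* LAV/IVC < 1.2            -> unilateral right-sided disease
* 1.2 <= LAV/IVC < 2.4     -> bilateral disease
* 2.4 <= LAV/IVC < 4.4     -> indeterminate, repeat AVS (resample)
* LAV/IVC >= 4.4           -> unilateral left-sided disease

Boundaries are half-open (closed on the left) by default so that the four
regions always partition (0, inf); the alternative right-closed convention
is available.  The model presumes an adequate left-sided sample (SI >= 3);
inadequate sampling short-circuits to resampling before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidMeasurementError
from .indices import (
    PatientAVSRecord,
    SamplingAdequacy,
    Subtype,
    compute_indices,
    is_adequate,
)

__all__ = [
    "DecisionCategory",
    "DecisionThresholds",
    "Decision",
    "CohortEvaluation",
    "classify",
    "classify_record",
    "evaluate_on_cohort",
    "compare_to_literature",
    "load_literature_table",
]


class DecisionCategory(str, Enum):
    """Ordered decision regions along increasing LAV/IVC."""

    UNILATERAL_RIGHT = "unilateral_right"
    BILATERAL = "bilateral"
    RESAMPLE = "resample"
    UNILATERAL_LEFT = "unilateral_left"


#: region order along the LAV/IVC axis
CATEGORY_ORDER = (
    DecisionCategory.UNILATERAL_RIGHT,
    DecisionCategory.BILATERAL,
    DecisionCategory.RESAMPLE,
    DecisionCategory.UNILATERAL_LEFT,
)


@dataclass(frozen=True)
class DecisionThresholds:
    """Ordered boundaries (right | bilateral | resample | left) for one tier."""

    right_upper: float = 1.2
    bilateral_upper: float = 2.4
    left_lower: float = 4.4
    specificity_tier: float = 0.90
    boundary_convention: str = "left_closed"  # or "right_closed"

    def __post_init__(self):
        if not (0 < self.right_upper < self.bilateral_upper <= self.left_lower):
            raise ValueError(
                "thresholds must satisfy 0 < right_upper < bilateral_upper <= left_lower, "
                f"got {self.right_upper!r}, {self.bilateral_upper!r}, {self.left_lower!r}"
            )
        if self.boundary_convention not in ("left_closed", "right_closed"):
            raise ValueError(f"unknown boundary convention {self.boundary_convention!r}")


@dataclass(frozen=True)
class Decision:
    """The category assigned to one LAV/IVC value."""

    category: DecisionCategory
    lav_ivc: float
    thresholds_used: DecisionThresholds


@dataclass(frozen=True)
class CohortEvaluation:
    """Decision-model performance on a labeled, bilaterally successful cohort.

    ``confusion`` is a 3x4 table (true subtype x decided category).  Per-class
    sensitivity treats resample as abstention (excluded from the denominator);
    the ``_strict`` variant counts abstentions as misses.  Specificity counts
    a resample call as a non-positive call for every class.
    """

    confusion: pd.DataFrame
    interpretable_fraction: float
    per_class_sensitivity: dict[str, float]
    per_class_sensitivity_strict: dict[str, float]
    per_class_specificity: dict[str, float]
    n: int
    thresholds: DecisionThresholds


def classify(lav_ivc: float, thresholds: Optional[DecisionThresholds] = None) -> Decision:
    """Map one LAV/IVC value to a decision region.

    With the default left-closed convention: x < right_upper is right-sided,
    right_upper <= x < bilateral_upper bilateral, bilateral_upper <= x <
    left_lower resample, x >= left_lower left-sided.  The right-closed
    convention moves the two lower boundaries into their lower regions
    (x <= right_upper right-sided, etc.); the left boundary is always closed
    from above.
    """
    if thresholds is None:
        thresholds = DecisionThresholds()
    x = float(lav_ivc)
    if not np.isfinite(x) or x <= 0:
        raise InvalidMeasurementError(f"LAV/IVC must be a positive finite number, got {lav_ivc!r}")
    t = thresholds
    if t.boundary_convention == "left_closed":
        below_right = x < t.right_upper
        below_bil = x < t.bilateral_upper
    else:  # right_closed
        below_right = x <= t.right_upper
        below_bil = x <= t.bilateral_upper
    if below_right:
        cat = DecisionCategory.UNILATERAL_RIGHT
    elif below_bil:
        cat = DecisionCategory.BILATERAL
    elif x < t.left_lower:
        cat = DecisionCategory.RESAMPLE
    else:
        cat = DecisionCategory.UNILATERAL_LEFT
    return Decision(category=cat, lav_ivc=x, thresholds_used=t)


def classify_record(
    record: PatientAVSRecord,
    thresholds: Optional[DecisionThresholds] = None,
    si_threshold: float = 3.0,
    ratio_method: str = "mean_of_ratios",
) -> Decision:
    """Classify a patient record, requiring an adequate left-sided sample.

    A record whose LAV selectivity index is below the adequacy threshold
    cannot be interpreted at all and short-circuits to ``resample``.
    """
    if thresholds is None:
        thresholds = DecisionThresholds()
    adequacy = is_adequate(record, si_threshold)
    if adequacy == SamplingAdequacy.FAILED:
        panel = compute_indices(record, ratio_method)
        return Decision(
            category=DecisionCategory.RESAMPLE, lav_ivc=panel.lav_ivc, thresholds_used=thresholds
        )
    panel = compute_indices(record, ratio_method)
    return classify(panel.lav_ivc, thresholds)


_SUBTYPE_TO_CATEGORY = {
    Subtype.UNILATERAL_RIGHT: DecisionCategory.UNILATERAL_RIGHT,
    Subtype.BILATERAL: DecisionCategory.BILATERAL,
    Subtype.UNILATERAL_LEFT: DecisionCategory.UNILATERAL_LEFT,
}


def evaluate_on_cohort(
    records: Sequence[PatientAVSRecord],
    thresholds: Optional[DecisionThresholds] = None,
    ratio_method: str = "mean_of_ratios",
) -> CohortEvaluation:
    """Run the decision model over a labeled cohort, ignoring RAV data.

    Emulates applying the failed-right model to bilaterally successful,
    reference-labeled patients: each patient is classified purely by
    LAV/IVC.  The interpretable fraction is 1 - resample_count / n.
    """
    if thresholds is None:
        thresholds = DecisionThresholds()
    unlabeled = [r.patient_id for r in records if r.reference_subtype is None]
    if unlabeled:
        raise ValueError(f"records without reference subtype: {unlabeled}")
    if not records:
        raise ValueError("empty cohort")

    subtype_rows = [s.value for s in Subtype]
    cat_cols = [c.value for c in CATEGORY_ORDER]
    confusion = pd.DataFrame(0, index=subtype_rows, columns=cat_cols, dtype=int)
    for r in records:
        panel = compute_indices(r, ratio_method)
        d = classify(panel.lav_ivc, thresholds)
        confusion.loc[r.reference_subtype.value, d.category.value] += 1

    n = int(confusion.to_numpy().sum())
    resample_total = int(confusion[DecisionCategory.RESAMPLE.value].sum())
    interpretable = 1.0 - resample_total / n

    sens, sens_strict, spec = {}, {}, {}
    for st in Subtype:
        cat = _SUBTYPE_TO_CATEGORY[st].value
        row = confusion.loc[st.value]
        tp = int(row[cat])
        n_class = int(row.sum())
        abstained = int(row[DecisionCategory.RESAMPLE.value])
        denom = n_class - abstained
        sens[st.value] = tp / denom if denom > 0 else float("nan")
        sens_strict[st.value] = tp / n_class if n_class > 0 else float("nan")
        neg_rows = confusion.drop(index=st.value)
        n_neg = int(neg_rows.to_numpy().sum())
        fp = int(neg_rows[cat].sum())
        spec[st.value] = (n_neg - fp) / n_neg if n_neg > 0 else float("nan")

    return CohortEvaluation(
        confusion=confusion,
        interpretable_fraction=interpretable,
        per_class_sensitivity=sens,
        per_class_sensitivity_strict=sens_strict,
        per_class_specificity=spec,
        n=n,
        thresholds=thresholds,
    )


def load_literature_table() -> pd.DataFrame:
    """Published LAV/IVC cut-offs for each decision region.

    Columns: region, author, n, comparator, cutoff, sensitivity_pct,
    specificity_pct, li_convention, si_convention, acth_stimulated, source
    (``published`` or ``this_study``).
    """
    from importlib.resources import files

    with (files("avskit.data") / "literature_cutoffs.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def compare_to_literature(
    thresholds: Optional[DecisionThresholds] = None,
    table: Optional[pd.DataFrame] = None,
    include_self: bool = False,
) -> pd.DataFrame:
    """Nearest published cut-off for each decision boundary.

    Returns one row per region (left, bilateral, right) with the closest
    cut-off by absolute distance; ``include_self`` also considers the rows
    contributed by the study cohort that produced the default thresholds.
    """
    if thresholds is None:
        thresholds = DecisionThresholds()
    if table is None:
        table = load_literature_table()
    if not include_self:
        table = table[table["source"] == "published"]
    boundaries = {
        "left": thresholds.left_lower,
        "bilateral": thresholds.bilateral_upper,
        "right": thresholds.right_upper,
    }
    rows = []
    for region, value in boundaries.items():
        sub = table[table["region"] == region].copy()
        if sub.empty:
            continue
        sub["distance"] = (sub["cutoff"] - value).abs()
        best = sub.sort_values(["distance", "n"], ascending=[True, False]).iloc[0]
        rows.append(
            {
                "region": region,
                "boundary_value": value,
                "author": best["author"],
                "n": int(best["n"]),
                "comparator": best["comparator"],
                "cutoff": float(best["cutoff"]),
                "sensitivity_pct": float(best["sensitivity_pct"]),
                "specificity_pct": float(best["specificity_pct"]),
                "li_convention": best["li_convention"],
                "si_convention": best["si_convention"],
                "acth_stimulated": bool(best["acth_stimulated"]),
                "distance": float(best["distance"]),
            }
        )
    return pd.DataFrame(rows)
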