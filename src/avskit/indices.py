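"""Per-patient adrenal vein sampling (AVS) indices.

AVS localizes autonomous aldosterone secretion in primary aldosteronism by
comparing aldosterone/cortisol (A/C) ratios between the left adrenal vein
(LAV), right adrenal vein (RAV) and a peripheral reference site in the
inferior vena cava (IVC).  Cortisol acts as an internal dilution control
under continuous ACTH stimulation.  This module computes:

* the per-site A/C ratio from duplicate samples,
* the selectivity index (SI = adrenal-vein cortisol / IVC cortisol), used to
  judge whether a catheter truly sampled adrenal effluent (adequate if >= 3),
* the lateralization index (LI = dominant A/C / non-dominant A/C),
* the contralateral suppression index (CSI = non-dominant A/C / IVC A/C),
* the LAV/IVC index (LAV A/C / IVC A/C), the only lateralization quantity
  still available when right-sided cannulation fails,

and assigns the reference subtype label (bilateral / unilateral left /
unilateral right) from LI and CSI for bilaterally successful samplings:
unilateral disease if LI >= 4 or CSI < 1, on the side of the dominant vein.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .errors import CannotLabelError, InvalidMeasurementError

__all__ = [
    "Subtype",
    "SamplingAdequacy",
    "SiteMeasurement",
    "PatientAVSRecord",
    "IndexPanel",
    "ac_ratio",
    "selectivity_index",
    "is_adequate",
    "compute_indices",
    "reference_subtype_label",
]

#: Default selectivity-index adequacy threshold (inclusive).
SI_THRESHOLD = 3.0
#: Default lateralization-index threshold for calling unilateral disease.
LI_THRESHOLD = 4.0
#: Default contralateral-suppression threshold (CSI below this is suppressed).
CSI_THRESHOLD = 1.0


class Subtype(str, Enum):
    """Primary aldosteronism subtype."""

    BILATERAL = "bilateral"
    UNILATERAL_LEFT = "unilateral_left"
    UNILATERAL_RIGHT = "unilateral_right"


class SamplingAdequacy(str, Enum):
    """Outcome of the selectivity-index adequacy check."""

    BILATERAL_SUCCESS = "bilateral_success"
    LEFT_ONLY_SUCCESS = "left_only_success"
    FAILED = "failed"


def _as_positive_tuple(values: Sequence[float], what: str) -> tuple[float, ...]:
    vals = tuple(float(v) for v in values)
    if len(vals) == 0:
        raise InvalidMeasurementError(f"{what}: at least one sample required")
    for v in vals:
        if not math.isfinite(v) or v <= 0.0:
            raise InvalidMeasurementError(f"{what}: non-positive or non-finite value {v!r}")
    return vals


@dataclass(frozen=True)
class SiteMeasurement:
    """Duplicate aldosterone/cortisol readings at one vascular site.

    Aldosterone in pmol/L, cortisol in nmol/L (any consistent unit pair works
    since only ratios enter the analysis).  Lists are typically length 2; they
    may differ in length only when a sample was lost, which is warned about.
    """

    aldosterone: tuple[float, ...]
    cortisol: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "aldosterone", _as_positive_tuple(self.aldosterone, "aldosterone"))
        object.__setattr__(self, "cortisol", _as_positive_tuple(self.cortisol, "cortisol"))
        if len(self.aldosterone) != len(self.cortisol):
            warnings.warn(
                "aldosterone and cortisol sample counts differ (lost sample?); "
                "A/C falls back to ratio-of-means",
                stacklevel=2,
            )


@dataclass(frozen=True)
class PatientAVSRecord:
    """One patient's AVS measurements.

    ``rav is None`` encodes failed right-sided cannulation.  The reference
    subtype can only be *derived* from bilaterally successful sampling, but a
    record may carry a retained label with RAV data removed (the
    failed-right validation scenario).
    """

    patient_id: str
    lav: SiteMeasurement
    ivc: SiteMeasurement
    rav: Optional[SiteMeasurement] = None
    reference_subtype: Optional[Subtype] = None


@dataclass(frozen=True)
class IndexPanel:
    """Derived AVS indices for one patient.

    ``li``/``csi``/``dominant_side`` are ``None`` when the RAV is absent.
    ``li >= 1`` by construction (dominant over non-dominant vein).
    """

    ac_lav: float
    ac_ivc: float
    lav_ivc: float
    si_lav: float
    ac_rav: Optional[float] = None
    si_rav: Optional[float] = None
    li: Optional[float] = None
    csi: Optional[float] = None
    dominant_side: Optional[str] = None  # "left" | "right" | None


def ac_ratio(site: SiteMeasurement, method: str = "mean_of_ratios") -> float:
    """Aldosterone/cortisol ratio of a site from its duplicate samples.

    ``method="mean_of_ratios"`` (default) averages per-sample ratios when the
    aldosterone and cortisol lists are paired (equal length); otherwise — or
    with ``method="ratio_of_means"`` — it divides the mean aldosterone by the
    mean cortisol.  The two conventions differ by less than duplicate assay
    noise.
    """
    a, c = site.aldosterone, site.cortisol
    if method == "mean_of_ratios" and len(a) == len(c):
        return sum(ai / ci for ai, ci in zip(a, c)) / len(a)
    if method not in ("mean_of_ratios", "ratio_of_means"):
        raise ValueError(f"unknown A/C method {method!r}")
    return (sum(a) / len(a)) / (sum(c) / len(c))


def selectivity_index(adrenal: SiteMeasurement, ivc: SiteMeasurement) -> float:
    """Selectivity index: mean adrenal-vein cortisol over mean IVC cortisol."""
    return (sum(adrenal.cortisol) / len(adrenal.cortisol)) / (
        sum(ivc.cortisol) / len(ivc.cortisol)
    )


def is_adequate(record: PatientAVSRecord, si_threshold: float = SI_THRESHOLD) -> SamplingAdequacy:
    """Classify sampling adequacy from the selectivity indices.

    ``bilateral_success`` requires the RAV present and SI >= threshold on both
    sides (the threshold value itself counts as adequate);
    ``left_only_success`` requires an adequate LAV with the RAV absent or
    inadequate; anything else is ``failed``.
    """
    si_lav = selectivity_index(record.lav, record.ivc)
    si_rav = None if record.rav is None else selectivity_index(record.rav, record.ivc)
    if si_rav is not None and si_lav >= si_threshold and si_rav >= si_threshold:
        return SamplingAdequacy.BILATERAL_SUCCESS
    if si_lav >= si_threshold:
        return SamplingAdequacy.LEFT_ONLY_SUCCESS
    return SamplingAdequacy.FAILED


def compute_indices(record: PatientAVSRecord, method: str = "mean_of_ratios") -> IndexPanel:
    """Compute all indices computable from a record.

    LI and CSI require both adrenal veins; the LAV/IVC index only the left.
    On an exact A/C tie between the veins no dominant side exists: LI is 1,
    the side is ``None`` and a warning is emitted (probability-zero on real
    data).
    """
    ac_lav = ac_ratio(record.lav, method)
    ac_ivc = ac_ratio(record.ivc, method)
    si_lav = selectivity_index(record.lav, record.ivc)
    lav_ivc = ac_lav / ac_ivc

    ac_rav = si_rav = li = csi = None
    dominant = None
    if record.rav is not None:
        ac_rav = ac_ratio(record.rav, method)
        si_rav = selectivity_index(record.rav, record.ivc)
        if ac_lav == ac_rav:
            warnings.warn(
                f"patient {record.patient_id}: exact A/C tie between adrenal veins; "
                "no dominant side",
                stacklevel=2,
            )
            li = 1.0
            csi = ac_lav / ac_ivc
        else:
            dominant = "left" if ac_lav > ac_rav else "right"
            hi, lo = (ac_lav, ac_rav) if ac_lav > ac_rav else (ac_rav, ac_lav)
            li = hi / lo
            csi = lo / ac_ivc
    return IndexPanel(
        ac_lav=ac_lav,
        ac_ivc=ac_ivc,
        lav_ivc=lav_ivc,
        si_lav=si_lav,
        ac_rav=ac_rav,
        si_rav=si_rav,
        li=li,
        csi=csi,
        dominant_side=dominant,
    )


def reference_subtype_label(
    panel: IndexPanel,
    li_threshold: float = LI_THRESHOLD,
    csi_threshold: float = CSI_THRESHOLD,
    csi_side: str = "both",
) -> Subtype:
    """Assign the reference (gold-standard) subtype from LI and CSI.

    Unilateral disease is called when ``li >= li_threshold`` or
    ``csi < csi_threshold`` (the side being that of the dominant vein);
    a patient failing both criteria is bilateral.  ``li_threshold`` defaults
    to 4 (with 3 in clinical use for offering adrenalectomy).  ``csi_side``
    may restrict the CSI criterion to ``"right"``-dominant patients, where a
    suppressed left gland flags right-sided disease; the default applies it
    symmetrically.

    Raises :class:`CannotLabelError` when LI/CSI are unavailable (failed
    right-sided sampling is the decision model's job, not this one's).
    """
    if panel.li is None or panel.csi is None:
        raise CannotLabelError("LI/CSI unavailable: bilaterally successful sampling required")
    if csi_side not in ("both", "right"):
        raise ValueError(f"csi_side must be 'both' or 'right', got {csi_side!r}")
    if panel.dominant_side is None:
        # exact A/C tie: no dominant vein exists, label bilateral
        warnings.warn("exact A/C tie: labeling bilateral regardless of CSI", stacklevel=2)
        return Subtype.BILATERAL
    csi_applies = csi_side == "both" or panel.dominant_side == "right"
    unilateral = panel.li >= li_threshold or (csi_applies and panel.csi < csi_threshold)
    if not unilateral:
        return Subtype.BILATERAL
    return Subtype.UNILATERAL_LEFT if panel.dominant_side == "left" else Subtype.UNILATERAL_RIGHT
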