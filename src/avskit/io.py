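"""Cohort CSV reading/writing with validation, and report assembly.

The cohort schema is one row per patient with duplicate aldosterone and
cortisol columns per site; empty RAV cells encode failed right-sided
cannulation.  Decimal points (not commas), UTF-8, header required.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .decision import CohortEvaluation, DecisionThresholds
from .errors import InvalidMeasurementError, ValidationError
from .indices import PatientAVSRecord, SiteMeasurement, Subtype

__all__ = [
    "COHORT_COLUMNS",
    "ReadIssue",
    "read_cohort",
    "write_cohort",
    "write_report",
    "thresholds_from_mapping",
]

COHORT_COLUMNS = [
    "patient_id",
    "aldo_lav_1", "aldo_lav_2", "cort_lav_1", "cort_lav_2",
    "aldo_rav_1", "aldo_rav_2", "cort_rav_1", "cort_rav_2",
    "aldo_ivc_1", "aldo_ivc_2", "cort_ivc_1", "cort_ivc_2",
    "reference_subtype",
]


@dataclass(frozen=True)
class ReadIssue:
    """A non-fatal (or row-fatal) problem found while reading a cohort CSV."""

    patient_id: str
    severity: str  # "info" | "warning" | "error"
    message: str


def _site_values(row: pd.Series, site: str):
    vals = {}
    for analyte in ("aldo", "cort"):
        pair = []
        for i in (1, 2):
            v = row.get(f"{analyte}_{site}_{i}")
            if v is not None and not pd.isna(v):
                pair.append(float(v))
        vals[analyte] = pair
    return vals["aldo"], vals["cort"]


def read_cohort(path) -> tuple[list[PatientAVSRecord], list[ReadIssue]]:
    """Read and validate a cohort CSV.

    Returns typed records plus a list of per-row issues.  Rows with
    non-positive or absent LAV/IVC measurements are rejected (listed as
    ``error`` issues); missing duplicates and absent RAV columns are
    collected as warnings/info but keep the row.  A malformed header is
    fatal, reporting the column difference.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    required = [c for c in COHORT_COLUMNS if c != "reference_subtype"]
    missing = [c for c in required if c not in df.columns]
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if missing:
        raise ValidationError(
            f"{path.name}: malformed header; missing columns {missing}, unexpected {extra}"
        )

    records: list[PatientAVSRecord] = []
    issues: list[ReadIssue] = []
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        try:
            sites = {}
            for site in ("lav", "ivc", "rav"):
                aldo, cort = _site_values(row, site)
                if not aldo and not cort:
                    sites[site] = None
                    continue
                if len(aldo) < 2 or len(cort) < 2:
                    issues.append(ReadIssue(pid, "warning", f"{site}: missing duplicate sample"))
                sites[site] = SiteMeasurement(tuple(aldo), tuple(cort))
            if sites["lav"] is None or sites["ivc"] is None:
                raise InvalidMeasurementError("LAV and IVC measurements are required")
            if sites["rav"] is None:
                issues.append(ReadIssue(pid, "info", "failed right cannulation (RAV absent)"))
            label = None
            raw_label = row.get("reference_subtype")
            if raw_label is not None and not pd.isna(raw_label) and str(raw_label).strip():
                label = Subtype(str(raw_label).strip())
            records.append(
                PatientAVSRecord(
                    patient_id=pid,
                    lav=sites["lav"],
                    ivc=sites["ivc"],
                    rav=sites["rav"],
                    reference_subtype=label,
                )
            )
        except (InvalidMeasurementError, ValueError) as exc:
            issues.append(ReadIssue(pid, "error", f"row rejected: {exc}"))
    return records, issues


def write_cohort(records: Sequence[PatientAVSRecord], path) -> None:
    """Write records in the cohort CSV schema (lossless for float64 values)."""
    rows = []
    for r in records:
        row = {c: "" for c in COHORT_COLUMNS}
        row["patient_id"] = r.patient_id
        for site_name, site in (("lav", r.lav), ("rav", r.rav), ("ivc", r.ivc)):
            if site is None:
                continue
            for i, v in enumerate(site.aldosterone[:2], start=1):
                row[f"aldo_{site_name}_{i}"] = repr(float(v))
            for i, v in enumerate(site.cortisol[:2], start=1):
                row[f"cort_{site_name}_{i}"] = repr(float(v))
        if r.reference_subtype is not None:
            row["reference_subtype"] = r.reference_subtype.value
        rows.append(row)
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def thresholds_from_mapping(cfg: dict) -> DecisionThresholds:
    """Build DecisionThresholds from a parsed YAML/JSON mapping."""
    known = {f.name for f in dataclasses.fields(DecisionThresholds)}
    unknown = set(cfg) - known
    if unknown:
        raise ValidationError(f"unknown threshold keys: {sorted(unknown)}")
    return DecisionThresholds(**cfg)


def _thresholds_dict(t: DecisionThresholds) -> dict:
    return dataclasses.asdict(t)


def write_report(
    evaluation: CohortEvaluation,
    thresholds: DecisionThresholds,
    literature_comparison: Optional[pd.DataFrame],
    out_dir,
    config_echo: Optional[dict] = None,
    seed: Optional[int] = None,
    interpretable_ci: Optional[tuple[float, float]] = None,
) -> tuple[Path, Path]:
    """Write a machine-readable JSON and a human-readable text report.

    Both embed the full effective configuration (thresholds, conventions,
    seed) so every number in them is recomputable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t = thresholds
    payload = {
        "thresholds": _thresholds_dict(t),
        "seed": seed,
        "config": config_echo or {},
        "n": evaluation.n,
        "confusion": {
            true: {cat: int(v) for cat, v in row.items()}
            for true, row in evaluation.confusion.to_dict(orient="index").items()
        },
        "interpretable_fraction": evaluation.interpretable_fraction,
        "interpretable_fraction_ci": list(interpretable_ci) if interpretable_ci else None,
        "per_class_sensitivity": evaluation.per_class_sensitivity,
        "per_class_sensitivity_strict": evaluation.per_class_sensitivity_strict,
        "per_class_specificity": evaluation.per_class_specificity,
        "nearest_literature": (
            literature_comparison.to_dict(orient="records")
            if literature_comparison is not None
            else None
        ),
    }
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")

    closed = t.boundary_convention == "left_closed"
    lb, rb = ("[", ")") if closed else ("(", "]")
    lines = [
        "AVS decision-model report",
        "=" * 25,
        f"specificity tier: {t.specificity_tier:g}   boundary convention: {t.boundary_convention}",
        f"seed: {seed}",
        "",
        "decision regions (LAV/IVC):",
    ]
    if t.bilateral_upper == t.left_lower:
        lines += [
            f"  {lb}0, {t.right_upper:g}{rb} unilateral right, "
            f"{lb}{t.right_upper:g}, {t.bilateral_upper:g}{rb} bilateral, "
            f"[{t.left_lower:g}, inf) unilateral left  (empty resample region)",
        ]
    else:
        lines += [
            f"  [0,{t.right_upper:g}) right, [{t.right_upper:g},{t.bilateral_upper:g}) bilateral, "
            f"[{t.bilateral_upper:g},{t.left_lower:g}) resample, [{t.left_lower:g},inf) left"
            if closed
            else f"  (0,{t.right_upper:g}] right, ({t.right_upper:g},{t.bilateral_upper:g}] bilateral, "
            f"({t.bilateral_upper:g},{t.left_lower:g}) resample, [{t.left_lower:g},inf) left",
        ]
    lines += [
        "",
        f"n = {evaluation.n}",
        f"interpretable fraction = {evaluation.interpretable_fraction:.3f}"
        + (
            f"  (95% CI {interpretable_ci[0]:.3f}-{interpretable_ci[1]:.3f})"
            if interpretable_ci
            else ""
        ),
        "",
        "confusion (true subtype x decided category):",
        evaluation.confusion.to_string(),
        "",
        "per-class sensitivity (resample as abstention): "
        + ", ".join(f"{k}={v:.3f}" for k, v in evaluation.per_class_sensitivity.items()),
        "per-class sensitivity (strict): "
        + ", ".join(f"{k}={v:.3f}" for k, v in evaluation.per_class_sensitivity_strict.items()),
        "per-class specificity: "
        + ", ".join(f"{k}={v:.3f}" for k, v in evaluation.per_class_specificity.items()),
    ]
    if literature_comparison is not None and not literature_comparison.empty:
        lines += ["", "nearest published cut-offs:", literature_comparison.to_string(index=False)]
    txt_path = out_dir / "report.txt"
    txt_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return json_path, txt_path
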