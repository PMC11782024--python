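"""Empirical ROC curves and specificity-constrained Youden cut-off selection.

The subtype cut-offs of the decision model come from empirical (staircase)
ROC curves of the LAV/IVC index, one per subtype contrast.  The operating
point is chosen by maximizing Youden's J = sensitivity + specificity - 1
among points whose specificity exceeds a floor (0.90 by default, with 0.85
and 0.95 tiers also derived), so that false-positive surgical referrals stay
rare.  AUC confidence intervals use DeLong's nonparametric method or a
stratified bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .decision import DecisionThresholds
from .errors import DegenerateContrastError, InfeasibleConstraintError, ThresholdOrderingError
from .indices import PatientAVSRecord, Subtype, compute_indices

__all__ = [
    "BinaryContrast",
    "EmpiricalROC",
    "CutoffResult",
    "empirical_roc",
    "auc_ci",
    "constrained_youden",
    "derive_threshold_table",
    "cohort_contrasts",
]


@dataclass(frozen=True)
class BinaryContrast:
    """Scores and positive-class labels for one subtype contrast.

    ``direction="lower_is_positive"`` means small scores indicate the positive
    class (e.g. a low LAV/IVC index flags right-sided disease).
    """

    scores: tuple[float, ...]
    labels: tuple[bool, ...]
    direction: str = "higher_is_positive"
    name: str = ""

    def __post_init__(self):
        object.__setattr__(self, "scores", tuple(float(s) for s in self.scores))
        object.__setattr__(self, "labels", tuple(bool(l) for l in self.labels))
        if len(self.scores) != len(self.labels):
            raise ValueError("scores and labels must have equal length")
        if self.direction not in ("higher_is_positive", "lower_is_positive"):
            raise ValueError(f"bad direction {self.direction!r}")
        npos = sum(self.labels)
        if npos == 0 or npos == len(self.labels):
            raise DegenerateContrastError(
                f"contrast {self.name!r} needs at least one positive and one negative"
            )

    def canonical_scores(self) -> np.ndarray:
        """Scores oriented so that higher always means more positive."""
        s = np.asarray(self.scores, dtype=float)
        return s if self.direction == "higher_is_positive" else -s


@dataclass(frozen=True)
class EmpiricalROC:
    """Empirical ROC staircase for one contrast.

    Thresholds are on the *original* score scale, ordered so the operating
    point tightens (sensitivity non-increasing) along the list, with
    +/-infinity sentinels.  A point calls a patient positive when the score
    is on the positive side of the threshold (>= for higher_is_positive,
    <= for lower_is_positive).
    """

    thresholds: tuple[float, ...]
    sensitivity: tuple[float, ...]
    specificity: tuple[float, ...]
    auc: float
    auc_ci_low: float
    auc_ci_high: float
    direction: str
    name: str = ""
    n_positive: int = 0
    n_negative: int = 0


@dataclass(frozen=True)
class CutoffResult:
    """A selected cut-off with its operating characteristics."""

    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    constraint: float
    contrast_name: str = ""
    direction: str = "higher_is_positive"


def _candidate_thresholds(canonical: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct scores, plus +/-inf sentinels.

    Midpoints keep the reported cut-off off any patient's exact value.
    """
    uniq = np.unique(canonical)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _operating_points(canonical: np.ndarray, labels: np.ndarray):
    """(thresholds, sens, spec) over all candidate thresholds, call = score >= t."""
    thr = _candidate_thresholds(canonical)
    pos = canonical[labels]
    neg = canonical[~labels]
    # calls positive at threshold t: score >= t
    sens = np.array([(pos >= t).mean() for t in thr])
    spec = np.array([(neg < t).mean() for t in thr])
    return thr, sens, spec


def _midrank_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC as the normalized Mann-Whitney statistic (ties count one half)."""
    allv = np.concatenate([pos, neg])
    rz = stats.rankdata(allv)
    m = len(pos)
    return (rz[:m].sum() - m * (m + 1) / 2.0) / (m * len(neg))


def _delong_ci(pos: np.ndarray, neg: np.ndarray, level: float):
    """DeLong nonparametric AUC variance via placement values."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    rz = stats.rankdata(allv)
    rx = stats.rankdata(pos)
    ry = stats.rankdata(neg)
    auc = (rz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (rz[:m] - rx) / n          # placements of positives among negatives
    v10 = 1.0 - (rz[m:] - ry) / m    # placements of negatives among positives
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(np.clip(auc - half, 0.0, 1.0)), float(np.clip(auc + half, 0.0, 1.0))


def empirical_roc(
    contrast: BinaryContrast,
    ci_method: str = "delong",
    level: float = 0.95,
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> EmpiricalROC:
    """Build the empirical ROC staircase with trapezoid AUC and a CI.

    The trapezoid AUC over the staircase equals the Mann-Whitney U statistic
    divided by n_pos * n_neg, with ties contributing one half.
    """
    canonical = contrast.canonical_scores()
    labels = np.asarray(contrast.labels, dtype=bool)
    thr, sens, spec = _operating_points(canonical, labels)
    pos, neg = canonical[labels], canonical[~labels]
    auc = _midrank_auc(pos, neg)
    low, high = auc_ci(contrast, method=ci_method, level=level, n_boot=n_boot, seed=seed)
    if contrast.direction == "lower_is_positive":
        thr = -thr  # back to the original scale; call = score <= threshold
    return EmpiricalROC(
        thresholds=tuple(thr),
        sensitivity=tuple(sens),
        specificity=tuple(spec),
        auc=float(auc),
        auc_ci_low=low,
        auc_ci_high=high,
        direction=contrast.direction,
        name=contrast.name,
        n_positive=int(labels.sum()),
        n_negative=int((~labels).sum()),
    )


def auc_ci(
    contrast: BinaryContrast,
    method: str = "delong",
    level: float = 0.95,
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """Two-sided AUC confidence interval, clipped to [0, 1].

    ``delong`` uses the asymptotic placement-value variance; ``bootstrap``
    resamples patients with replacement within each class (so no resample is
    degenerate) and takes percentile limits.
    """
    import warnings as _warnings

    canonical = contrast.canonical_scores()
    labels = np.asarray(contrast.labels, dtype=bool)
    pos, neg = canonical[labels], canonical[~labels]
    if method == "delong":
        return _delong_ci(pos, neg, level)
    if method != "bootstrap":
        raise ValueError(f"unknown CI method {method!r}")
    if n_boot < 100:
        _warnings.warn(f"n_boot={n_boot} is small; interval will be unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    m, n = len(pos), len(neg)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        aucs[b] = _midrank_auc(pos[rng.integers(0, m, m)], neg[rng.integers(0, n, n)])
    alpha = 1.0 - level
    low, high = np.quantile(aucs, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(np.clip(low, 0.0, 1.0)), float(np.clip(high, 0.0, 1.0))


def constrained_youden(
    roc: EmpiricalROC, min_specificity: float, strict: bool = True
) -> CutoffResult:
    """Best-Youden operating point subject to a specificity floor.

    Among operating points with specificity > ``min_specificity`` (or >= when
    ``strict=False``), returns the one maximizing J = sens + spec - 1.
    J ties are broken toward higher specificity, then higher sensitivity —
    the specificity-first reading of the constraint's purpose (limit false
    positives).  Raises :class:`InfeasibleConstraintError`, reporting the
    maximum attainable specificity among points with nonzero sensitivity,
    when the floor cannot be met.
    """
    sens = np.asarray(roc.sensitivity)
    spec = np.asarray(roc.specificity)
    thr = np.asarray(roc.thresholds)
    feasible = spec > min_specificity if strict else spec >= min_specificity
    # the degenerate call-nobody point (sens 0) trivially attains spec 1;
    # it is a valid operating point but a useless cut-off, so exclude it
    # unless nothing else is feasible with sens > 0
    useful = feasible & (sens > 0)
    if not useful.any():
        with_sens = spec[sens > 0]
        max_spec = float(with_sens.max()) if with_sens.size else 0.0
        raise InfeasibleConstraintError(min_specificity, max_spec, roc.name)
    j = sens + spec - 1.0
    order = np.lexsort((sens, spec, j))  # last key dominates
    best = [i for i in order if useful[i]][-1]
    return CutoffResult(
        cutoff=float(thr[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        youden_j=float(j[best]),
        constraint=min_specificity,
        contrast_name=roc.name,
        direction=roc.direction,
    )


def cohort_contrasts(
    records: Sequence[PatientAVSRecord],
    scheme: str = "sequential_pairwise",
    ratio_method: str = "mean_of_ratios",
) -> dict[str, BinaryContrast]:
    """LAV/IVC contrasts for the three subtype cut-offs.

    ``one_vs_all`` compares each subtype against everyone else.
    ``sequential_pairwise`` (default) mirrors the decision model's reading
    order: right vs (bilateral + left), bilateral vs left, left vs bilateral.
    """
    scores, labels = [], []
    for r in records:
        if r.reference_subtype is None:
            raise ValueError(f"record {r.patient_id!r} has no reference subtype")
        scores.append(compute_indices(r, ratio_method).lav_ivc)
        labels.append(r.reference_subtype)
    s = np.asarray(scores)
    lab = np.asarray([l.value for l in labels])

    def make(name, pos_mask, keep_mask, direction):
        return BinaryContrast(
            scores=tuple(s[keep_mask]),
            labels=tuple(pos_mask[keep_mask]),
            direction=direction,
            name=name,
        )

    is_r = lab == Subtype.UNILATERAL_RIGHT.value
    is_b = lab == Subtype.BILATERAL.value
    is_l = lab == Subtype.UNILATERAL_LEFT.value
    all_mask = np.ones(len(s), dtype=bool)
    if scheme == "one_vs_all":
        return {
            "right": make("right", is_r, all_mask, "lower_is_positive"),
            "bilateral": make("bilateral", is_b, all_mask, "lower_is_positive"),
            "left": make("left", is_l, all_mask, "higher_is_positive"),
        }
    if scheme == "sequential_pairwise":
        return {
            "right": make("right", is_r, all_mask, "lower_is_positive"),
            "bilateral": make("bilateral", is_b, is_b | is_l, "lower_is_positive"),
            "left": make("left", is_l, is_l | is_b, "higher_is_positive"),
        }
    raise ValueError(f"unknown contrast scheme {scheme!r}")


def derive_threshold_table(
    records: Sequence[PatientAVSRecord],
    specificity_tiers: Iterable[float] = (0.85, 0.90, 0.95),
    contrast_scheme: str = "sequential_pairwise",
    strict: bool = True,
    ratio_method: str = "mean_of_ratios",
    boundary_convention: str = "left_closed",
) -> dict[float, DecisionThresholds]:
    """Derive the three decision boundaries at each specificity tier.

    The right boundary comes from the right contrast (low LAV/IVC positive),
    the bilateral upper bound from the bilateral contrast (low positive) and
    the left boundary from the left contrast (high positive).  Boundaries
    must come out ordered right < bilateral-upper <= left, otherwise a
    :class:`ThresholdOrderingError` is raised.
    """
    contrasts = cohort_contrasts(records, contrast_scheme, ratio_method)
    rocs = {k: empirical_roc(c) for k, c in contrasts.items()}
    out: dict[float, DecisionThresholds] = {}
    for tier in specificity_tiers:
        cuts = {k: constrained_youden(r, tier, strict) for k, r in rocs.items()}
        right, bil, left = cuts["right"].cutoff, cuts["bilateral"].cutoff, cuts["left"].cutoff
        if not (0 < right < bil <= left):
            raise ThresholdOrderingError(
                f"tier {tier:g}: boundaries not ordered "
                f"(right {right:g}, bilateral {bil:g}, left {left:g})"
            )
        out[float(tier)] = DecisionThresholds(
            right_upper=right,
            bilateral_upper=bil,
            left_lower=left,
            specificity_tier=float(tier),
            boundary_convention=boundary_convention,
        )
    return out
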