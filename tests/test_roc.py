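"""Empirical ROC, AUC confidence intervals and constrained Youden selection."""

import numpy as np
import pytest

from avskit import (
    BinaryContrast,
    DegenerateContrastError,
    InfeasibleConstraintError,
    Subtype,
    ThresholdOrderingError,
    auc_ci,
    constrained_youden,
    derive_threshold_table,
    empirical_roc,
)


def contrast(pos, neg, direction="higher_is_positive"):
    scores = tuple(pos) + tuple(neg)
    labels = (True,) * len(pos) + (False,) * len(neg)
    return BinaryContrast(scores, labels, direction)


def pair_counting_auc(pos, neg):
    """Brute-force Mann-Whitney AUC oracle: ties count one half."""
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def exhaustive_constrained_youden(pos, neg, min_spec, strict=True):
    """Independent oracle: enumerate every candidate threshold directly from
    the scores; feasibility requires nonzero sensitivity; maximize
    (J, specificity, sensitivity) lexicographically."""
    uniq = np.unique(np.concatenate([pos, neg]))
    cands = [-np.inf, *(uniq[:-1] + uniq[1:]) / 2.0, np.inf]
    best = None
    for t in cands:
        sens = np.mean(pos >= t)
        spec = np.mean(neg < t)
        feasible = spec > min_spec if strict else spec >= min_spec
        if not feasible or sens == 0:
            continue
        key = (sens + spec - 1.0, spec, sens)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    return best


class TestEmpiricalROC:
    def test_perfect_separation(self):
        roc = empirical_roc(contrast([0.1, 0.2], [3.0, 4.0], "lower_is_positive"))
        assert roc.auc == 1.0

    def test_interleaved_auc_quarter(self):
        assert empirical_roc(contrast([1, 3], [2, 4])).auc == pytest.approx(0.25)

    def test_exchangeable_auc_half(self):
        assert empirical_roc(contrast([1, 2, 3], [1, 2, 3])).auc == pytest.approx(0.5)

    def test_degenerate_contrast_rejected(self):
        with pytest.raises(DegenerateContrastError):
            BinaryContrast((1.0, 2.0), (True, True))

    def test_staircase_monotone_and_thresholds_off_data(self):
        rng = np.random.default_rng(3)
        pos, neg = rng.normal(1, 1, 12), rng.normal(0, 1, 15)
        roc = empirical_roc(contrast(pos, neg))
        sens = np.asarray(roc.sensitivity)
        spec = np.asarray(roc.specificity)
        assert (np.diff(sens) <= 1e-12).all()
        assert (np.diff(spec) >= -1e-12).all()
        finite = [t for t in roc.thresholds if np.isfinite(t)]
        assert not set(finite) & set(np.concatenate([pos, neg]).tolist())

    @pytest.mark.parametrize("seed", range(8))
    def test_direction_flip_maps_auc(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.integers(0, 10, 9).astype(float)
        neg = rng.integers(0, 10, 7).astype(float)
        hi = empirical_roc(contrast(pos, neg, "higher_is_positive")).auc
        lo = empirical_roc(contrast(pos, neg, "lower_is_positive")).auc
        assert hi + lo == pytest.approx(1.0, abs=1e-12)

    def test_mann_whitney_oracle_200_random_contrasts(self):
        """Trapezoid AUC equals brute-force pair counting (ties = 1/2) on 200
        random small contrasts with heavy ties."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            m = int(rng.integers(1, 16))
            n = int(rng.integers(1, 16))
            pos = rng.integers(0, 6, m).astype(float)  # integer grid forces ties
            neg = rng.integers(0, 6, n).astype(float)
            got = empirical_roc(contrast(pos, neg)).auc
            assert got == pytest.approx(pair_counting_auc(pos, neg), abs=1e-12)

    def test_sklearn_cross_check(self):
        """Independent library oracle on continuous and tied scores."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        for _ in range(20):
            scores = np.round(rng.normal(0, 1, 40), 1)
            labels = rng.random(40) < 0.4
            if labels.all() or not labels.any():
                continue
            c = BinaryContrast(tuple(scores), tuple(labels))
            assert empirical_roc(c).auc == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )


class TestAucCI:
    def test_delong_perfect_separation_contains_one(self):
        low, high = auc_ci(contrast([0.1, 0.2], [3.0, 4.0], "lower_is_positive"))
        assert low >= 0 and high == 1.0 and low <= 1.0 <= high

    def test_exchangeable_interval_symmetric_about_half(self):
        rng = np.random.default_rng(0)
        s = rng.normal(0, 1, 40)
        low, high = auc_ci(contrast(s[:20], s[20:]))
        assert (low + high) / 2 == pytest.approx(0.5, abs=0.12)
        assert low < 0.5 < high

    def test_bootstrap_and_delong_overlap(self):
        rng = np.random.default_rng(1)
        c = contrast(rng.normal(1.2, 1, 25), rng.normal(0, 1, 30))
        d_lo, d_hi = auc_ci(c, "delong")
        b_lo, b_hi = auc_ci(c, "bootstrap", n_boot=5000, seed=9)
        assert max(d_lo, b_lo) < min(d_hi, b_hi)  # intervals overlap

    def test_small_n_boot_warns(self):
        c = contrast([2.0, 3.0], [0.0, 1.0])
        with pytest.warns(UserWarning, match="small"):
            auc_ci(c, "bootstrap", n_boot=50, seed=0)


class TestConstrainedYouden:
    def test_perfect_separation_j_one(self):
        roc = empirical_roc(contrast([5.0, 6.0], [1.0, 2.0]))
        res = constrained_youden(roc, 0.90)
        assert res.youden_j == pytest.approx(1.0)
        assert 2.0 < res.cutoff < 5.0

    def test_six_point_toy(self):
        roc = empirical_roc(contrast([5.0, 4.5, 2.0], [1.0, 1.5, 3.0]))
        res = constrained_youden(roc, 0.60)
        assert 3.0 < res.cutoff < 4.5
        assert res.sensitivity == pytest.approx(2 / 3)
        assert res.specificity == 1.0
        assert res.youden_j == pytest.approx(2 / 3)

    def test_infeasible_constraint_reports_max_attainable(self):
        roc = empirical_roc(contrast([1.0, 2.0], [1.0, 2.0]))
        with pytest.raises(InfeasibleConstraintError) as exc:
            constrained_youden(roc, 0.99)
        assert exc.value.max_attainable <= 0.99

    def test_exhaustive_oracle_200_random_contrasts(self):
        """Selection equals exhaustive search over all empirical operating
        points, including infeasible-constraint cases."""
        rng = np.random.default_rng(7)
        checked_infeasible = 0
        for _ in range(200):
            m = int(rng.integers(1, 16))
            n = int(rng.integers(1, 16))
            pos = rng.integers(0, 8, m).astype(float)
            neg = rng.integers(0, 8, n).astype(float)
            min_spec = float(rng.choice([0.3, 0.6, 0.9, 0.97]))
            roc = empirical_roc(contrast(pos, neg))
            expected = exhaustive_constrained_youden(pos, neg, min_spec)
            if expected is None:
                checked_infeasible += 1
                with pytest.raises(InfeasibleConstraintError):
                    constrained_youden(roc, min_spec)
                continue
            got = constrained_youden(roc, min_spec)
            (j, spec, sens), t, o_sens, o_spec = expected
            assert got.youden_j == pytest.approx(j, abs=1e-12)
            assert got.sensitivity == pytest.approx(o_sens, abs=1e-12)
            assert got.specificity == pytest.approx(o_spec, abs=1e-12)
        assert checked_infeasible > 0  # the case mix actually exercised the error

    def test_raising_floor_never_raises_j(self):
        rng = np.random.default_rng(13)
        roc = empirical_roc(contrast(rng.normal(1, 1, 20), rng.normal(0, 1, 20)))
        last = np.inf
        for floor in (0.2, 0.5, 0.7, 0.9):
            try:
                j = constrained_youden(roc, floor).youden_j
            except InfeasibleConstraintError:
                break
            assert j <= last + 1e-12
            last = j

    def test_strict_vs_nonstrict_at_exact_floor(self):
        # one negative of 10 misclassified: spec exactly 0.9
        roc = empirical_roc(contrast([5.0] * 5, [1.0] * 9 + [6.0]))
        res = constrained_youden(roc, 0.90, strict=False)
        assert res.specificity == pytest.approx(0.9)
        with pytest.raises(InfeasibleConstraintError):
            constrained_youden(roc, 0.90, strict=True)


class TestDeriveThresholdTable:
    def test_infinitely_separated_groups(self):
        """Cleanly separated groups give boundaries strictly between them and
        J = 1 in every contrast."""
        from avskit import PatientAVSRecord, SiteMeasurement

        def rec(i, lav_ivc, subtype):
            c = 1000.0
            return PatientAVSRecord(
                f"p{i}",
                lav=SiteMeasurement((lav_ivc * 2.0 * 5 * c,), (5 * c,)),
                ivc=SiteMeasurement((2.0 * c,), (c,)),
                rav=SiteMeasurement((2.0 * 5 * c,), (5 * c,)),
                reference_subtype=subtype,
            )

        records = (
            [rec(i, v, Subtype.UNILATERAL_RIGHT) for i, v in enumerate([0.1, 0.2, 0.3])]
            + [rec(10 + i, v, Subtype.BILATERAL) for i, v in enumerate([2.0, 2.1, 2.2])]
            + [rec(20 + i, v, Subtype.UNILATERAL_LEFT) for i, v in enumerate([8.0, 9.0, 10.0])]
        )
        table = derive_threshold_table(records, [0.60])
        t = table[0.60]
        assert 0.3 < t.right_upper < 2.0
        assert 2.2 < t.bilateral_upper <= t.left_lower < 8.0

    def test_tier_monotonicity(self, large_cohort):
        """A tighter specificity tier never selects a looser specificity."""
        from avskit.roc import cohort_contrasts

        contrasts = cohort_contrasts(large_cohort)
        for c in contrasts.values():
            roc = empirical_roc(c)
            s85 = constrained_youden(roc, 0.85).specificity
            s95 = constrained_youden(roc, 0.95).specificity
            assert s95 >= s85

    def test_ordering_violation_detected(self, study_cohort, monkeypatch):
        """Misordered per-contrast cutoffs are refused when assembled."""
        import avskit.roc as roc_mod
        from avskit.roc import CutoffResult

        fake = {
            "right": 3.0,  # right boundary above the bilateral one
            "bilateral": 2.0,
            "left": 4.0,
        }

        def fake_youden(roc, tier, strict=True):
            return CutoffResult(
                cutoff=fake[roc.name], sensitivity=1.0, specificity=1.0,
                youden_j=1.0, constraint=tier, contrast_name=roc.name,
            )

        monkeypatch.setattr(roc_mod, "constrained_youden", fake_youden)
        with pytest.raises(ThresholdOrderingError):
            derive_threshold_table(study_cohort, [0.90])

    def test_one_vs_all_middle_class_infeasible(self, study_cohort):
        """With a single monotone score, a one-vs-all contrast for the middle
        (bilateral) group cannot reach high specificity — the right-sided
        group always sits below it — and the infeasibility propagates.  The
        pairwise scheme avoids this by comparing bilateral against left only."""
        with pytest.raises(InfeasibleConstraintError):
            derive_threshold_table(study_cohort, [0.85], contrast_scheme="one_vs_all")
        table = derive_threshold_table(study_cohort, [0.85])
        t = table[0.85]
        assert 0 < t.right_upper < t.bilateral_upper <= t.left_lower

    def test_one_vs_all_right_contrast_matches_pairwise(self, study_cohort):
        from avskit.roc import cohort_contrasts

        a = cohort_contrasts(study_cohort, "one_vs_all")["right"]
        b = cohort_contrasts(study_cohort, "sequential_pairwise")["right"]
        assert a.scores == b.scores and a.labels == b.labels
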