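"""Joint calibration, fit statistics, reliability and diagnostics."""

import math

import numpy as np
import pytest

from raschcat import (
    CalibrationConfig,
    AbilityEstimate,
    CohortSpec,
    Item,
    ItemBank,
    RatingScale,
    ResponseMatrix,
    category_diagnostics,
    fit_statistics,
    jmle_calibrate,
    misfit_filter,
    residual_pca,
    sem_stop_value,
    separation_reliability,
    simulate_cohort,
)


def _matrix_from(data, n_categories=4):
    data = np.asarray(data, dtype=float)
    return ResponseMatrix(
        person_ids=[f"P{i}" for i in range(data.shape[0])],
        item_ids=list(range(1, data.shape[1] + 1)),
        data=data,
        n_categories=n_categories,
    )


class TestResponseMatrix:
    def test_rejects_out_of_range_and_tiny(self):
        with pytest.raises(ValueError):
            _matrix_from([[0, 5], [1, 2]], n_categories=4)
        with pytest.raises(ValueError):
            _matrix_from([[0], [1]])  # single item

    def test_missing_cells_allowed(self):
        m = _matrix_from([[0, np.nan, 2], [1, 2, np.nan], [2, 1, 0]])
        assert m.n_persons == 3 and m.n_items == 3


class TestJmleCalibrate:
    def test_identical_items_get_identical_difficulties(self, rng):
        base = rng.integers(0, 4, size=60)
        other = rng.integers(0, 4, size=60)
        data = np.column_stack([base, base, other]).astype(float)
        res = jmle_calibrate(_matrix_from(data))
        d = [it.difficulty for it in res.bank.items]
        assert d[0] == pytest.approx(d[1], abs=1e-6)

    def test_unanchored_recovery_correlates_with_truth(self, bank24):
        thetas, matrix = simulate_cohort(CohortSpec(n_persons=500, seed=5), bank24)
        res = jmle_calibrate(matrix)
        true_d = np.array([it.difficulty for it in bank24.calibrated])
        est_d = np.array(
            [res.bank.get(it.item_id).difficulty for it in bank24.calibrated]
        )
        assert np.corrcoef(true_d, est_d)[0, 1] > 0.99
        # unanchored identification: centered difficulties, zero-sum thresholds
        assert abs(est_d.mean()) < 1e-6
        assert abs(sum(res.bank.scale.thresholds)) < 1e-6

    def test_anchored_equals_unanchored_after_reparameterization(self, bank24):
        # refitting with difficulties anchored at the unanchored estimates is
        # a pure change of frame: thresholds must agree (pure-MLE mode)
        _, matrix = simulate_cohort(CohortSpec(n_persons=400, seed=9), bank24)
        cfg = CalibrationConfig(bias_correction=False)
        ru = jmle_calibrate(matrix, config=cfg)
        ra = jmle_calibrate(matrix, anchors=ru.bank, config=cfg)
        np.testing.assert_allclose(
            ra.bank.scale.thresholds, ru.bank.scale.thresholds, atol=0.02
        )

    def test_deterministic(self, bank24):
        _, matrix = simulate_cohort(CohortSpec(n_persons=120, seed=3), bank24)
        r1 = jmle_calibrate(matrix)
        r2 = jmle_calibrate(matrix)
        assert [it.difficulty for it in r1.bank.items] == [
            it.difficulty for it in r2.bank.items
        ]
        assert r1.bank.scale.thresholds == r2.bank.scale.thresholds

    def test_no_variance_item_dropped_with_warning(self, rng):
        data = rng.integers(0, 4, size=(40, 3)).astype(float)
        data[:, 1] = 2.0
        with pytest.warns(UserWarning, match="no-variance"):
            res = jmle_calibrate(_matrix_from(data))
        assert res.dropped_items == [2]
        assert [it.item_id for it in res.bank.items] == [1, 3]


class TestFitStatistics:
    def test_zero_residuals_give_zero_outfit(self):
        # symmetric two-step scale: E = 1 exactly at theta = delta
        scale = RatingScale((0.0, 0.0))
        items = [Item(item_id=i, difficulty=0.0) for i in (1, 2, 3)]
        bank = ItemBank(items=items, scale=scale)
        data = np.ones((4, 3))
        matrix = _matrix_from(data, n_categories=3)
        measures = [AbilityEstimate(theta=0.0, se=1.0, n_items=3) for _ in range(4)]
        fit = fit_statistics(matrix, bank, measures)
        assert np.allclose(fit.items["outfit"], 0.0)
        assert np.allclose(fit.items["infit"], 0.0)

    def test_model_consistent_data_has_unit_mean_outfit(self, bank24):
        _, matrix = simulate_cohort(CohortSpec(n_persons=1000, seed=17), bank24)
        res = jmle_calibrate(matrix, anchors=bank24)
        assert 0.9 <= res.fit.items["outfit"].mean() <= 1.1
        assert 0.9 <= res.fit.items["infit"].mean() <= 1.1
        # Z is roughly centered; jointly estimated person measures absorb
        # ~1/L of the residual variance, so a small negative shift remains
        assert abs(res.fit.items["infit_z"].mean()) < 2.0


class TestMisfitFilter:
    def test_packaged_fixture_retains_24(self, bank37):
        retained, misfit = misfit_filter(bank37)
        assert len(retained.items) == 24
        assert len(misfit) == 13

    def test_boundaries_are_closed(self):
        scale = RatingScale((0.0,))
        items = [
            Item(item_id=1, difficulty=0.0, infit=0.5),
            Item(item_id=2, difficulty=0.0, infit=1.5),
            Item(item_id=3, difficulty=0.0, infit=0.49),
            Item(item_id=4, difficulty=0.0, infit=1.51),
        ]
        retained, misfit = misfit_filter(ItemBank(items=items, scale=scale))
        assert [it.item_id for it in retained.items] == [1, 2]
        assert misfit == [3, 4]

    def test_unbounded_filter_is_identity(self, bank37):
        retained, misfit = misfit_filter(bank37, lower=0.0, upper=math.inf)
        # misfit-status rows are still excluded; all calibrated rows kept
        assert len(retained.items) == 24

    def test_all_misfit_raises(self):
        scale = RatingScale((0.0,))
        items = [Item(item_id=1, difficulty=0.0, infit=3.0)]
        with pytest.raises(ValueError):
            misfit_filter(ItemBank(items=items, scale=scale))


class TestReliabilityAndSem:
    def test_error_free_measures_give_one(self):
        ms = [AbilityEstimate(theta=t, se=0.0, n_items=5) for t in (-1, 0, 1, 2)]
        assert separation_reliability(ms) == pytest.approx(1.0)

    def test_floor_at_zero(self):
        thetas = [-1.0, 1.0]
        sd = np.std(thetas, ddof=1)
        ms = [AbilityEstimate(theta=t, se=sd, n_items=5) for t in thetas]
        assert separation_reliability(ms) == 0.0

    def test_increases_with_test_length(self, bank24):
        _, matrix = simulate_cohort(CohortSpec(n_persons=250, seed=21), bank24)
        rels = []
        for n_items in (6, 12, 24):
            ids = [it.item_id for it in bank24.calibrated[:n_items]]
            sub = ResponseMatrix(
                person_ids=matrix.person_ids,
                item_ids=ids,
                data=matrix.to_frame()[ids].to_numpy(),
                n_categories=4,
            )
            sub_bank = ItemBank(
                items=[bank24.get(i) for i in ids], scale=bank24.scale
            )
            res = jmle_calibrate(sub, anchors=sub_bank)
            rels.append(res.reliability)
        assert rels[0] < rels[1] < rels[2]

    def test_sem_stop_value(self):
        assert sem_stop_value(1.99, 0.88) == pytest.approx(1.99 * math.sqrt(0.12))
        assert sem_stop_value(1.99, 1.0) == 0.0
        assert sem_stop_value(1.99, 0.0) == pytest.approx(1.99)
        with pytest.raises(ValueError):
            sem_stop_value(0.0, 0.5)
        with pytest.raises(ValueError):
            sem_stop_value(1.0, 1.2)


class TestResidualPca:
    def test_two_pasted_traits_raise_first_contrast(self, bank24):
        # two independent 12-item traits in one matrix must show a larger
        # first residual contrast than the strictly unidimensional case
        items = bank24.calibrated
        half_a = ItemBank(items=items[:12], scale=bank24.scale)
        half_b = ItemBank(items=items[12:], scale=bank24.scale)
        _, ma = simulate_cohort(CohortSpec(n_persons=400, seed=31), half_a)
        _, mb = simulate_cohort(CohortSpec(n_persons=400, seed=32), half_b)
        pasted = ResponseMatrix(
            person_ids=ma.person_ids,
            item_ids=ma.item_ids + mb.item_ids,
            data=np.hstack([ma.data, mb.data]),
            n_categories=4,
        )
        res_two = jmle_calibrate(pasted, anchors=bank24)
        _, muni = simulate_cohort(CohortSpec(n_persons=400, seed=31), bank24)
        res_uni = jmle_calibrate(muni, anchors=bank24)
        assert (
            res_two.dimensionality.first_contrast_eigenvalue
            > res_uni.dimensionality.first_contrast_eigenvalue
        )

    def test_pure_noise_eigenvalues_near_one(self, bank24, rng):
        # residual correlation of independent noise is near identity, whose
        # eigenvalues are all 1; the top eigenvalue stays well below 3
        _, matrix = simulate_cohort(CohortSpec(n_persons=600, seed=8), bank24)
        res = jmle_calibrate(matrix, anchors=bank24)
        d = res.dimensionality
        assert 1.0 <= d.first_contrast_eigenvalue < 2.0


class TestCategoryDiagnostics:
    def _diag_for(self, thresholds, bank24):
        scale = RatingScale(thresholds)
        items = [
            Item(item_id=it.item_id, difficulty=it.difficulty)
            for it in bank24.calibrated
        ]
        bank = ItemBank(items=items, scale=scale)
        _, matrix = simulate_cohort(CohortSpec(n_persons=200, seed=13), bank)
        measures = [
            AbilityEstimate(theta=t, se=0.5, n_items=matrix.n_items)
            for t in simulate_cohort(CohortSpec(n_persons=200, seed=13), bank)[0]
        ]
        return category_diagnostics(matrix, bank, measures)

    def test_reference_thresholds_pass(self, bank24):
        diag = self._diag_for((-4.16, -1.50, 2.66), bank24)
        np.testing.assert_allclose(diag.threshold_advances, [2.66, 4.16])
        flags = diag.guideline_flags
        assert flags["steps_advance"] is True
        assert flags["advance_at_least_1.4"] is True
        assert flags["advance_less_than_5.0"] is True

    def test_small_advance_fails_guideline_3(self, bank24):
        diag = self._diag_for((0.0, 0.5), bank24)
        assert diag.guideline_flags["advance_at_least_1.4"] is False

    def test_large_advance_fails_guideline_4(self, bank24):
        diag = self._diag_for((-3.0, 3.0), bank24)
        assert diag.threshold_advances == [6.0]
        assert diag.guideline_flags["advance_less_than_5.0"] is False

    def test_average_measures_advance_on_model_data(self, bank24, cohort300):
        thetas, matrix = cohort300
        measures = [
            AbilityEstimate(theta=t, se=0.5, n_items=24) for t in thetas
        ]
        diag = category_diagnostics(matrix, bank24, measures)
        assert diag.guideline_flags["average_measures_advance"] is True
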