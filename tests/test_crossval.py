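"""Nested leave-one-subject-out cross-validation and grid selection."""

import numpy as np
import pytest

from wmvpa import (CohortSpec, HyperparameterGrid, build_dataset, default_mask,
                   confusion_from_decisions, final_model, generate_cohort,
                   inner_select, outer_loso)
from wmvpa.volumes import CohortDataset


def _toy_dataset(rng, n_pos=4, n_neg=4, n_voxels=24, separator=None):
    X = rng.normal(0.5, 0.1, size=(n_pos + n_neg, n_voxels))
    y = np.array([1] * n_pos + [-1] * n_neg)
    if separator is not None:
        X[:, separator] = 0.5 + 0.3 * y  # perfectly separating column
    ids = [f"S{i}" for i in range(len(y))]
    mask = np.ones((2, 3, n_voxels // 6), dtype=bool)
    idx = np.argwhere(mask)
    return CohortDataset(X=X, y=y, mask=mask, grid_shape=mask.shape,
                         voxel_size_mm=(1, 1, 1), voxel_index_map=idx,
                         subject_ids=ids, clinical=None)


class TestGrid:
    @pytest.mark.parametrize("kw", [
        dict(C_values=()), dict(k_values=()), dict(C_values=(0.0, 1.0)),
        dict(C_values=(2.0, 1.0)), dict(k_values=(5, 5)),
    ])
    def test_invalid_grids_rejected(self, kw):
        with pytest.raises(ValueError):
            HyperparameterGrid(**kw)


class TestInnerSelect:
    def test_single_cell_returned_without_search(self):
        rng = np.random.default_rng(0)
        ds = _toy_dataset(rng)
        grid = HyperparameterGrid(C_values=(3.0,), k_values=(7,))
        assert inner_select(ds.X, ds.y, grid) == (3.0, 7)

    def test_separating_column_selects_smallest_k(self):
        rng = np.random.default_rng(1)
        ds = _toy_dataset(rng, n_voxels=24, separator=5)
        grid = HyperparameterGrid(C_values=(1.0,), k_values=(1, 24))
        C, k = inner_select(ds.X, ds.y, grid)
        assert k == 1

    def test_selection_is_value_based_not_grid_order_based(self):
        rng = np.random.default_rng(2)
        ds = _toy_dataset(rng, n_voxels=18)
        g1 = HyperparameterGrid(C_values=(0.5, 8.0), k_values=(3, 9))
        choice = inner_select(ds.X, ds.y, g1)
        # rebuilding the same grid must reproduce the same choice
        g2 = HyperparameterGrid(C_values=(0.5, 8.0), k_values=(3, 9))
        assert inner_select(ds.X, ds.y, g2) == choice

    def test_oversized_k_values_are_skipped(self):
        rng = np.random.default_rng(3)
        ds = _toy_dataset(rng, n_voxels=12, separator=2)
        grid = HyperparameterGrid(C_values=(1.0,), k_values=(1, 500))
        C, k = inner_select(ds.X, ds.y, grid)
        assert k == 1

    def test_too_few_per_class_raises(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(3, 5))
        with pytest.raises(ValueError):
            inner_select(X, np.array([1, -1, -1]),
                         HyperparameterGrid(C_values=(1.0,), k_values=(2,)))


class TestOuterLoso:
    def test_one_prediction_per_subject(self, small_grid):
        rng = np.random.default_rng(5)
        ds = _toy_dataset(rng, n_pos=4, n_neg=3)
        cv = outer_loso(ds, small_grid)
        assert len(cv.decision_value) == 7
        assert cv.subject_ids == ds.subject_ids
        assert [f.test_subject for f in cv.folds] == ds.subject_ids
        np.testing.assert_array_equal(cv.y_pred, np.where(cv.decision_value > 0, 1, -1))
        for f in cv.folds:
            assert len(f.columns) == f.k
            assert f.k in small_grid.k_values and f.C in small_grid.C_values

    def test_strong_signal_perfect_outer_accuracy(self, strong_signal_dataset):
        """Planted delta = 3 * noise_sd is recovered with balanced accuracy 1."""
        grid = HyperparameterGrid(C_values=(0.1, 1.0, 10.0), k_values=(10, 50))
        cv = outer_loso(strong_signal_dataset, grid)
        c = confusion_from_decisions(cv.y_true, cv.decision_value)
        assert c.balanced_accuracy == 1.0

    def test_preconditions_checked_before_compute(self, small_grid):
        rng = np.random.default_rng(6)
        ds = _toy_dataset(rng, n_pos=2, n_neg=1)
        with pytest.raises(ValueError):
            outer_loso(ds, small_grid)

    def test_leakage_invariant_exact(self):
        """Corrupting the held-out subject's features changes neither the
        fold's hyperparameters nor its selected voxel columns."""
        rng = np.random.default_rng(8)
        ds = _toy_dataset(rng, n_pos=3, n_neg=3, n_voxels=18)
        grid = HyperparameterGrid(C_values=(1.0, 32.0), k_values=(3, 9))
        cv = outer_loso(ds, grid)
        for i in range(ds.n_subjects):
            X2 = ds.X.copy()
            X2[i] = rng.normal(50.0, 10.0, size=ds.n_voxels)  # absurd values
            ds2 = CohortDataset(X=X2, y=ds.y, mask=ds.mask,
                                grid_shape=ds.grid_shape,
                                voxel_size_mm=ds.voxel_size_mm,
                                voxel_index_map=ds.voxel_index_map,
                                subject_ids=ds.subject_ids, clinical=None)
            cv2 = outer_loso(ds2, grid)
            assert cv2.folds[i].C == cv.folds[i].C
            assert cv2.folds[i].k == cv.folds[i].k
            np.testing.assert_array_equal(cv2.folds[i].columns, cv.folds[i].columns)

    def test_to_frame_layout(self, small_grid):
        rng = np.random.default_rng(9)
        ds = _toy_dataset(rng)
        cv = outer_loso(ds, small_grid)
        df = cv.to_frame()
        assert list(df.columns) == ["subject_id", "label", "decision_value",
                                    "predicted_label"]
        assert len(df) == ds.n_subjects


class TestFinalModel:
    def test_refit_is_deterministic(self, strong_signal_dataset):
        grid = HyperparameterGrid(C_values=(1.0,), k_values=(10,))
        m1, c1, h1 = final_model(strong_signal_dataset, grid)
        m2, c2, h2 = final_model(strong_signal_dataset, grid)
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_allclose(m1.w, m2.w)
        assert h1 == h2 == (1.0, 10)

    def test_single_cell_refit_uses_that_cell(self, strong_signal_dataset):
        grid = HyperparameterGrid(C_values=(2.0,), k_values=(25,))
        model, cols, (C, k) = final_model(strong_signal_dataset, grid)
        assert (C, k) == (2.0, 25)
        assert len(cols) == 25 and model.w.shape == (25,)

    def test_selected_columns_recover_planted_voxels(self, strong_signal_spec,
                                                     strong_signal_dataset):
        """At strong signal, >= 80% of the selected voxels fall inside the
        smoothing-dilated planted region."""
        from scipy.ndimage import binary_dilation
        from wmvpa.synthetic import effect_mask
        from wmvpa.volumes import fwhm_to_sigma
        grid = HyperparameterGrid(C_values=(0.1, 1.0, 10.0), k_values=(10, 50))
        _, cols, _ = final_model(strong_signal_dataset, grid)
        sigma = fwhm_to_sigma(strong_signal_spec.smooth_fwhm_mm,
                              strong_signal_spec.voxel_size_mm)
        region = binary_dilation(
            effect_mask(strong_signal_spec.effects[0], strong_signal_spec.grid_shape),
            iterations=int(np.ceil(2 * sigma.max())))
        coords = strong_signal_dataset.voxel_index_map[cols]
        precision = region[tuple(coords.T)].mean()
        assert precision >= 0.8


def test_null_cohort_chance_calibration_smoke():
    """Two null seeds stay within a generous chance band (the full 20-seed
    calibration runs in the acceptance suite)."""
    grid = HyperparameterGrid(C_values=(2.0 ** -5, 1.0, 32.0, 1024.0),
                              k_values=(10, 100))
    baccs = []
    for seed in (0, 1):
        spec = CohortSpec(grid_shape=(12, 12, 12), n_positive=10, n_negative=10,
                          noise_sd=0.05, effects=[], seed=seed)
        volumes, clinical = generate_cohort(spec)
        ds = build_dataset(volumes, default_mask(volumes), clinical)
        cv = outer_loso(ds, grid)
        baccs.append(confusion_from_decisions(cv.y_true, cv.decision_value)
                     .balanced_accuracy)
    assert all(0.0 <= b <= 1.0 for b in baccs)
    assert np.mean(baccs) < 0.9  # no spurious signal on pure noise
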