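import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crosstalk.classify import train_classifier
from crosstalk.core_io import DescriptorMatrix, PipelineConfig
from crosstalk.screening import (
    leverage,
    leverages,
    natom_filter,
    ocsvm_filter,
    rank_candidates,
    run_screening,
    warning_leverage,
)
from crosstalk.synthetic import SyntheticSpec, simulate_screen_library


def dmatrix(array, ids=None, cols=None, natom=None):
    array = np.asarray(array, dtype=float)
    ids = ids or [f"m{i}" for i in range(array.shape[0])]
    cols = cols or [f"f{i}" for i in range(array.shape[1])]
    return DescriptorMatrix(pd.DataFrame(array, index=ids, columns=cols), natom)


class TestNatomFilter:
    def test_boundary_at_seven(self):
        m = dmatrix([[6.0], [7.0], [8.0]], cols=["nAtom"], natom="nAtom")
        kept, removed = natom_filter(m, 7)
        assert removed == ["m0"]
        assert kept.molecule_ids == ["m1", "m2"]

    def test_empty_library(self):
        m = dmatrix(np.empty((0, 1)), ids=[], cols=["nAtom"], natom="nAtom")
        kept, removed = natom_filter(m, 7)
        assert kept.shape[0] == 0 and removed == []

    def test_missing_atom_column_raises(self):
        m = dmatrix([[1.0]], cols=["x"])
        with pytest.raises(ValueError):
            natom_filter(m, 7)


class TestWarningLeverage:
    def test_study_arithmetic(self):
        assert warning_leverage(6, 2304, 3) == pytest.approx(0.0091, abs=5e-5)

    def test_zero_features_gives_3_over_n(self):
        assert warning_leverage(0, 100, 3) == pytest.approx(0.03)

    def test_zero_multiplier_rejects_everything_positive(self):
        assert warning_leverage(6, 100, 0) == 0.0

    def test_zero_compounds_raises(self):
        with pytest.raises(ValueError):
            warning_leverage(6, 0, 3)


class TestLeverage:
    def test_single_column_explicit_inverse(self):
        # X = (1, 2)^T: X^T X = 5, so h for x = (1) is 1/5
        assert leverage(np.array([1.0]), np.array([[1.0], [2.0]])) == pytest.approx(0.2)

    def test_orthonormal_basis_row(self):
        X = np.eye(3)
        for j in range(3):
            assert leverage(X[j], X) == pytest.approx(1.0)

    def test_hat_trace_identity_on_random_matrix(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 3))
        h = leverages(X, X)
        brute = np.diag(X @ np.linalg.inv(X.T @ X) @ X.T)
        assert np.allclose(h, brute, atol=1e-10)
        assert float(h.sum()) == pytest.approx(3.0, abs=1e-10)
        assert (h >= 0).all() and (h <= 1.0 + 1e-12).all()

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            leverage(np.ones(2), np.ones((4, 3)))

    def test_rank_deficient_falls_back_to_pseudoinverse(self):
        X = np.ones((5, 2))  # duplicated column -> singular gram
        h = leverages(X, X)
        assert np.all(np.isfinite(h))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(5, 20), p=st.integers(1, 4))
    def test_hat_trace_identity_property(self, seed, n, p):
        if p >= n:
            p = n - 1
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        assert float(leverages(X, X).sum()) == pytest.approx(p, abs=1e-8)


class TestOneClassSVM:
    def _train(self, seed=0, n=40, w=4):
        rng = np.random.default_rng(seed)
        return dmatrix(rng.normal(size=(n, w)))

    def test_centroid_retained_far_point_rejected(self):
        train = self._train()
        centroid = train.frame.mean().to_numpy()
        far = centroid + 100 * train.frame.std().to_numpy()
        screen = dmatrix(np.vstack([centroid, far]), ids=["center", "far"],
                         cols=train.feature_names)
        kept, removed = ocsvm_filter(train, screen, nu=0.1)
        assert "center" in kept.molecule_ids
        assert removed == ["far"]

    def test_empty_screen(self):
        train = self._train()
        empty = dmatrix(np.empty((0, 4)), ids=[], cols=train.feature_names)
        kept, removed = ocsvm_filter(train, empty)
        assert kept.shape[0] == 0 and removed == []

    def test_zero_variance_training_feature_raises(self):
        train = dmatrix(np.hstack([np.ones((10, 1)), np.random.default_rng(0).normal(size=(10, 1))]))
        screen = dmatrix(np.zeros((1, 2)), cols=train.feature_names)
        with pytest.raises(ValueError, match="zero-variance"):
            ocsvm_filter(train, screen)

    def test_training_rejection_near_nominal_nu(self):
        train = self._train(n=400)
        kept, removed = ocsvm_filter(train, train, nu=0.1)
        assert 0.02 < len(removed) / 400 < 0.25


class TestRankCandidates:
    def _model(self, separable_descriptors):
        matrix, labels = separable_descriptors
        return train_classifier(matrix, labels, n_trees=100, seed=0), matrix, labels

    def test_threshold_boundary_excludes_below(self, separable_descriptors):
        model, matrix, labels = self._model(separable_descriptors)
        table = rank_candidates(model, matrix, threshold=0.95)
        assert (table.rows.probability >= 0.95).all()

    def test_training_positives_rank_positive(self, separable_descriptors):
        model, matrix, labels = self._model(separable_descriptors)
        table = rank_candidates(model, matrix, threshold=0.9)
        listed = set(table.positives.drug_id)
        assert listed <= set(labels.positives)
        assert listed  # separable training drugs are confidently their own class

    def test_threshold_one_keeps_only_certain_drugs(self, separable_descriptors):
        model, matrix, _ = self._model(separable_descriptors)
        table = rank_candidates(model, matrix, threshold=1.0)
        assert (table.rows.probability == 1.0).all()

    def test_sorted_descending_within_label(self, separable_descriptors):
        model, matrix, _ = self._model(separable_descriptors)
        table = rank_candidates(model, matrix, threshold=0.8)
        for part in (table.positives, table.negatives):
            p = part.probability.to_numpy()
            assert (np.diff(p) <= 0).all()

    def test_bad_threshold_rejected(self, separable_descriptors):
        model, matrix, _ = self._model(separable_descriptors)
        with pytest.raises(ValueError):
            rank_candidates(model, matrix, threshold=0.4)


class TestRunScreening:
    @pytest.fixture
    def world(self, separable_descriptors):
        matrix, labels = separable_descriptors
        model = train_classifier(matrix, labels, n_trees=100, seed=0)
        spec = SyntheticSpec(seed=31)
        spec.screening.n_screen = 300
        full = matrix.frame.copy()
        full["nAtom"] = np.random.default_rng(1).integers(10, 60, len(full)).astype(float)
        train_full = DescriptorMatrix(full, "nAtom")
        label_map = {d: ("positive" if d in labels.positives else "negative")
                     for d in train_full.molecule_ids}
        library, flags = simulate_screen_library(spec, train_full, label_map)
        return model, matrix, library, flags

    def test_stage_counts_reconcile(self, world):
        model, train, library, _ = world
        report, _ = run_screening(model, train, library, PipelineConfig(rng_seed=0))
        total = (
            len(report.removed_small_molecules) + len(report.removed_missing_features)
            + len(report.removed_high_leverage) + len(report.removed_ocsvm)
            + len(report.retained)
        )
        assert total == report.n_input == library.shape[0]

    def test_planted_outliers_never_retained(self, world):
        model, train, library, flags = world
        report, candidates = run_screening(model, train, library, PipelineConfig())
        outliers = set(flags.index[flags.outlier])
        assert not outliers & set(report.retained)
        assert not outliers & set(candidates.rows.drug_id)

    def test_planted_positives_rank_positive(self, world):
        model, train, library, flags = world
        report, candidates = run_screening(model, train, library, PipelineConfig())
        pos_listed = set(candidates.positives.drug_id)
        planted_pos = set(flags.index[flags.planted_class == "positive"])
        planted_neg = set(flags.index[flags.planted_class == "negative"])
        assert pos_listed <= planted_pos          # no planted negative sneaks in
        assert len(pos_listed) > 0

    def test_monotone_attrition_under_tighter_thresholds(self, world):
        model, train, library, _ = world
        base_cfg = PipelineConfig()
        base, _ = run_screening(model, train, library, base_cfg)
        tight_cfg = PipelineConfig(natom_min=15, ocsvm_nu=0.3)
        tight, _ = run_screening(model, train, library, tight_cfg)
        assert len(tight.retained) <= len(base.retained)
        assert len(tight.removed_small_molecules) >= len(base.removed_small_molecules)

    def test_higher_probability_threshold_shrinks_candidates(self, world):
        model, train, library, _ = world
        cfg_lo = PipelineConfig(probability_threshold=0.8)
        cfg_hi = PipelineConfig(probability_threshold=0.99)
        _, lo = run_screening(model, train, library, cfg_lo)
        _, hi = run_screening(model, train, library, cfg_hi)
        assert set(hi.rows.drug_id) <= set(lo.rows.drug_id)
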