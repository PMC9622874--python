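import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from crosstalk.core_io import DescriptorMatrix, LabeledDrugSet, PipelineConfig
from crosstalk.features import (
    entropy_filter,
    prune_correlated,
    remove_constant,
    select_features,
    shannon_entropy,
    ttest_filter,
)


def dm(frame_dict, index=None):
    frame = pd.DataFrame(frame_dict, index=index)
    if index is None:
        frame.index = [f"m{i}" for i in range(len(frame))]
    return DescriptorMatrix(frame)


class TestRemoveConstant:
    def test_constant_column_removed(self):
        m = dm({"flat": [7.0] * 4, "varies": [1.0, 2, 3, 4]})
        kept, removed = remove_constant(m)
        assert removed == ["flat"]
        assert kept.feature_names == ["varies"]

    def test_constant_except_missing_cell_removed(self):
        # distinct non-missing values: just one -> constant
        m = dm({"gappy": [3.0, 3.0, np.nan, 3.0], "varies": [1.0, 2, 3, 4]})
        _, removed = remove_constant(m)
        assert removed == ["gappy"]

    def test_all_constant_raises(self):
        m = dm({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(ValueError):
            remove_constant(m)


class TestPruneCorrelated:
    def test_one_of_identical_pair_removed(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        m = dm({"a": x, "b": x.copy(), "z": rng.normal(size=30)})
        kept, removed = prune_correlated(m, 0.9)
        assert len(removed) == 1 and removed[0] in {"a", "b"}
        assert "z" in kept.feature_names

    def test_highest_mean_abs_correlation_member_removed(self):
        """Toy with r(A,B)~0.95, r(A,C)~0.5, r(B,C)~0.1: A has the highest
        mean |r| and is the one dropped."""
        rng = np.random.default_rng(42)
        n = 400
        b = rng.normal(size=n)
        c_ind = rng.normal(size=n)
        a = 0.9 * b + 0.35 * c_ind + 0.15 * rng.normal(size=n)
        c = c_ind
        m = dm({"A": a, "B": b, "C": c})
        corr = m.frame.corr().abs()
        assert corr.loc["A", "B"] > 0.9
        assert 0.3 < corr.loc["A", "C"] < 0.7
        assert corr.loc["B", "C"] < 0.3
        _, removed = prune_correlated(m, 0.9)
        assert removed == ["A"]

    def test_no_high_pairs_removes_nothing(self):
        rng = np.random.default_rng(1)
        m = dm({k: rng.normal(size=50) for k in "abcd"})
        _, removed = prune_correlated(m, 0.9)
        assert removed == []

    def test_no_surviving_pair_exceeds_cutoff(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(60, 3))
        cols = {}
        for i in range(3):
            cols[f"g{i}a"] = base[:, i]
            cols[f"g{i}b"] = base[:, i] + 0.01 * rng.normal(size=60)
        kept, _ = prune_correlated(dm(cols), 0.9)
        corr = kept.frame.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.9

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_caret_findcorrelation_on_random_matrix(self, tmp_path):
        """Independent oracle: caret::findCorrelation (non-exact mode)."""
        rng = np.random.default_rng(7)
        base = rng.normal(size=(40, 4))
        cols = {}
        for i in range(4):
            cols[f"v{i}"] = base[:, i]
            cols[f"w{i}"] = base[:, i] + 0.05 * rng.normal(size=40)
        cols["u"] = rng.normal(size=40)
        m = dm(cols)
        csv = tmp_path / "x.csv"
        m.frame.to_csv(csv, index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            "suppressMessages(library(caret))\n"
            f"x <- read.csv('{csv}')\n"
            "idx <- findCorrelation(cor(x), cutoff = 0.9, exact = FALSE)\n"
            "cat(sort(colnames(x)[idx]), sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, check=True,
        )
        oracle = sorted(l for l in out.stdout.splitlines() if l.strip())
        _, removed = prune_correlated(m, 0.9)
        assert sorted(removed) == oracle


class TestEntropyFilter:
    def test_uniform_over_ten_bins_is_ln10(self):
        x = np.linspace(0, 10, 40, endpoint=False)  # 4 values per bin
        assert shannon_entropy(x, 10) == pytest.approx(math.log(10), abs=1e-12)

    def test_two_point_half_half_is_ln2_and_removed(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        assert shannon_entropy(x, 10) == pytest.approx(math.log(2), abs=1e-12)
        m = dm({"twopoint": x, "uniform": np.linspace(0, 10, 40, endpoint=False)})
        kept, removed, entropies = entropy_filter(m, theta=1.5, n_bins=10)
        assert removed == ["twopoint"]
        assert entropies["uniform"] == pytest.approx(math.log(10))

    def test_single_bin_mass_has_zero_entropy(self):
        x = np.array([5.0] * 39 + [5.0001])
        assert shannon_entropy(x, 10) == pytest.approx(
            -(0.975 * math.log(0.975) + 0.025 * math.log(0.025))
        )
        near_const = np.full(40, 2.0)
        assert shannon_entropy(near_const, 10) == 0.0


class TestTTestFilter:
    def _labels(self, ids, n_pos):
        return LabeledDrugSet(
            positives=frozenset(ids[:n_pos]), negatives=frozenset(ids[n_pos:])
        )

    def test_identical_class_distributions_not_selected(self):
        vals = np.array(list(range(8)) * 2, dtype=float)
        ids = [f"m{i}" for i in range(16)]
        m = dm({"same": vals}, index=ids)
        selected, p = ttest_filter(m, self._labels(ids, 8))
        assert selected == []
        assert p["same"] > 0.9

    def test_three_sd_separated_feature_always_selected(self):
        """At a 3-pooled-SD gap and n=16/24 the two-sample t-test has
        essentially full power (checked over 200 simulated draws)."""
        rng = np.random.default_rng(0)
        ids = [f"m{i}" for i in range(40)]
        labels = self._labels(ids, 16)
        hits = 0
        for _ in range(200):
            x = rng.normal(size=40)
            x[:16] += 3.0
            selected, _ = ttest_filter(dm({"f": x}, index=ids), labels)
            hits += selected == ["f"]
        assert hits == 200

    def test_small_class_raises(self):
        ids = [f"m{i}" for i in range(5)]
        m = dm({"f": [1.0, 2, 3, 4, 5]}, index=ids)
        with pytest.raises(ValueError):
            ttest_filter(m, self._labels(ids, 1))

    def test_unlabeled_row_raises(self):
        ids = [f"m{i}" for i in range(6)]
        m = dm({"f": [1.0, 2, 3, 4, 5, 6]}, index=ids)
        labels = LabeledDrugSet(
            positives=frozenset(ids[:2]), negatives=frozenset(ids[2:5])
        )
        with pytest.raises(ValueError, match="without a class label"):
            ttest_filter(m, labels)


class TestCascade:
    def test_planted_structure_recovered(self, labeled_descriptors):
        matrix, labels, planted = labeled_descriptors
        selected, report = select_features(matrix, labels)
        assert set(planted["informative"]) <= set(report.selected)
        assert set(planted["constant"]) <= set(report.removed_constant)
        for i in range(len(planted["correlated"]) // 2):
            pair = {f"dup{i}a", f"dup{i}b"}
            assert pair & set(report.removed_correlated)
        assert not set(planted["low_entropy"]) & set(report.selected)

    def test_report_partitions_input_features(self, labeled_descriptors):
        matrix, labels, _ = labeled_descriptors
        _, report = select_features(matrix, labels)
        total = (
            len(report.removed_constant) + len(report.removed_correlated)
            + len(report.removed_low_entropy) + len(report.removed_nonsignificant)
            + len(report.selected)
        )
        assert total == report.n_input_features == len(matrix.feature_names)

    def test_cascade_idempotent(self, labeled_descriptors):
        matrix, labels, _ = labeled_descriptors
        once, report1 = select_features(matrix, labels)
        twice, report2 = select_features(once, labels)
        assert report2.selected == report1.selected
        assert not report2.removed_constant
        assert not report2.removed_correlated
        assert not report2.removed_low_entropy

    def test_row_permutation_invariance(self, labeled_descriptors):
        matrix, labels, _ = labeled_descriptors
        rng = np.random.default_rng(9)
        perm = list(rng.permutation(matrix.molecule_ids))
        _, a = select_features(matrix, labels)
        _, b = select_features(matrix.subset_molecules(perm), labels)
        assert a.selected == b.selected
        assert a.removed_correlated == b.removed_correlated

    def test_report_tsv_round_trip(self, labeled_descriptors, tmp_path):
        matrix, labels, _ = labeled_descriptors
        _, report = select_features(matrix, labels)
        path = tmp_path / "fs.tsv"
        report.to_tsv(path)
        frame = pd.read_csv(path, sep="\t")
        assert len(frame) == report.n_input_features
        assert set(frame.fate) <= {
            "removed_constant", "removed_correlated", "removed_low_entropy",
            "removed_nonsignificant", "selected",
        }
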