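"""Adjudication, kappa, confusion/accuracy, splits, CV, Kruskal-Wallis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import cohen_kappa_score

from aoqc import (
    accuracy,
    adjudicate,
    cohens_kappa,
    confusion,
    kfold_cv,
    kruskal_wallis_by_category,
    subjectwise_split,
)
from aoqc.grading_agreement import GradingRecord


def _records(cats, senior="G1"):
    return [
        GradingRecord(patch_id="p0", grader_id=f"G{i + 1}", category=c)
        for i, c in enumerate(cats)
    ]


class TestAdjudicate:
    def test_unanimity(self):
        assert adjudicate(_records([3, 3, 3]), senior_grader="G1") == 3

    def test_majority(self):
        assert adjudicate(_records([2, 3, 3]), senior_grader="G1") == 3

    def test_three_way_split_goes_to_senior(self):
        assert adjudicate(_records([1, 2, 3]), senior_grader="G2") == 2

    def test_three_way_split_can_be_flagged(self):
        with pytest.raises(ValueError, match="no majority"):
            adjudicate(_records([1, 2, 3]), senior_grader="G2", on_tie="flag")

    def test_duplicate_grader_is_data_error(self):
        recs = [
            GradingRecord("p0", "G1", 1),
            GradingRecord("p0", "G1", 2),
            GradingRecord("p0", "G2", 3),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            adjudicate(recs, senior_grader="G1")

    def test_single_grader_rejected(self):
        with pytest.raises(ValueError, match="2 graders"):
            adjudicate(_records([2]), senior_grader="G1")


class TestConfusionAccuracy:
    def test_identical_vectors_are_diagonal(self):
        labels = [1, 2, 3, 2, 2, 1]
        cm = confusion(labels, labels)
        assert np.trace(cm.counts) == len(labels)
        assert accuracy(cm) == 100.0

    def test_single_off_diagonal_cell(self):
        cm = confusion([2] * 7, [3] * 7)
        assert cm.counts[1, 2] == 7 and cm.total == 7
        assert accuracy(cm) == 0.0

    def test_hand_built_nine_labels(self):
        ref = [1, 1, 1, 2, 2, 2, 3, 3, 3]
        pred = [1, 2, 3, 2, 2, 1, 3, 3, 2]
        cm = confusion(ref, pred)
        expected = np.array([[1, 1, 1], [1, 2, 0], [0, 1, 2]])
        np.testing.assert_array_equal(cm.counts, expected)

    def test_accuracy_arithmetic(self):
        counts = np.diag([10, 20, 10])
        counts[0, 1] = 5
        counts[2, 1] = 5
        from aoqc.grading_agreement import ConfusionMatrix

        assert accuracy(ConfusionMatrix(counts)) == pytest.approx(80.0)

    def test_marginals_match_class_counts(self):
        rng = np.random.default_rng(0)
        ref = rng.integers(1, 4, 200)
        pred = rng.integers(1, 4, 200)
        cm = confusion(ref, pred)
        for c in (1, 2, 3):
            assert cm.counts[c - 1].sum() == (ref == c).sum()
            assert cm.counts[:, c - 1].sum() == (pred == c).sum()

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 2], [1, 2, 3])


class TestCohensKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa([1, 2, 3, 2], [1, 2, 3, 2]) == pytest.approx(1.0)

    def test_chance_level_on_independent_labels(self):
        rng = np.random.default_rng(42)
        a = rng.integers(1, 4, 10_000)
        b = rng.integers(1, 4, 10_000)
        assert abs(cohens_kappa(a, b)) < 0.05

    def test_two_by_two_closed_form(self):
        # table ((20,5),(10,15)): p_o = 0.70, p_e = 0.5*0.6 + 0.5*0.4 = 0.50
        a = [1] * 25 + [2] * 25
        b = [1] * 20 + [2] * 5 + [1] * 10 + [2] * 15
        expected = (0.70 - 0.50) / (1 - 0.50)
        assert cohens_kappa(a, b) == pytest.approx(expected, abs=1e-9)

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            a = rng.integers(1, 4, 300)
            b = np.where(rng.uniform(size=300) < 0.6, a, rng.integers(1, 4, 300))
            assert cohens_kappa(a, b) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12
            )

    @given(st.lists(st.tuples(st.integers(1, 3), st.integers(1, 3)), min_size=2, max_size=60))
    @settings(max_examples=80, deadline=None)
    def test_symmetric_and_relabel_invariant(self, pairs):
        a = np.array([p[0] for p in pairs])
        b = np.array([p[1] for p in pairs])
        pe_degenerate = len(set(a)) == 1 and len(set(b)) == 1
        if pe_degenerate and not (a == b).all():
            return  # undefined by construction
        k_ab = cohens_kappa(a, b)
        assert k_ab == pytest.approx(cohens_kappa(b, a), abs=1e-12)
        perm = {1: 3, 2: 1, 3: 2}
        a2 = np.vectorize(perm.get)(a)
        b2 = np.vectorize(perm.get)(b)
        assert cohens_kappa(a2, b2) == pytest.approx(k_ab, abs=1e-12)

    def test_degenerate_marginals(self):
        # both raters constant and identical: p_e = 1 with perfect
        # agreement, defined as kappa = 1
        assert cohens_kappa([2, 2, 2], [2, 2, 2]) == 1.0
        # both constant but different: p_e = 0, p_o = 0 -> kappa = 0
        assert cohens_kappa([1, 1], [2, 2]) == pytest.approx(0.0)


class TestSubjectwiseSplit:
    @pytest.fixture()
    def manifest(self):
        return pd.DataFrame(
            {
                "subject_id": np.repeat([f"S{i:02d}" for i in range(50)], 4),
                "category": np.tile([1, 2, 3, 2], 50),
            }
        )

    def test_disjoint_and_complete(self, manifest):
        train, val = subjectwise_split(manifest, 23 / 50, seed=0)
        assert len(train) == 23 and len(val) == 27
        assert not set(train) & set(val)
        assert set(train) | set(val) == set(manifest["subject_id"])

    def test_extreme_fraction_keeps_one_per_side(self):
        m = pd.DataFrame({"subject_id": ["A"] * 3 + ["B"] * 3})
        train, val = subjectwise_split(m, 0.99, seed=1)
        assert len(train) == 1 and len(val) == 1

    def test_deterministic(self, manifest):
        assert subjectwise_split(manifest, 0.5, seed=3) == subjectwise_split(
            manifest, 0.5, seed=3
        )

    def test_bad_fraction(self, manifest):
        with pytest.raises(ValueError, match="train_fraction"):
            subjectwise_split(manifest, 1.0, seed=0)


class TestKFoldCV:
    @pytest.fixture()
    def separable(self):
        # per-subject scores perfectly separated by category
        rng = np.random.default_rng(5)
        rows = []
        for i in range(20):
            cat = 1 + i % 3
            for _ in range(5):
                rows.append(
                    {"subject_id": f"S{i:02d}", "category": cat,
                     "score": cat * 10 + rng.uniform(-2, 2)}
                )
        return pd.DataFrame(rows)

    @staticmethod
    def _band_fitter(train_rows, test_rows):
        s = test_rows["score"].to_numpy()
        return np.where(s < 15, 1, np.where(s < 25, 2, 3))

    def test_ten_folds_and_perfect_accuracy(self, separable):
        accs, mean = kfold_cv(separable, 10, self._band_fitter, seed=0)
        assert len(accs) == 10
        assert mean == 100.0

    def test_folds_partition_subjects(self, separable):
        seen = []

        def spy(train_rows, test_rows):
            seen.append(set(test_rows["subject_id"]))
            return self._band_fitter(train_rows, test_rows)

        kfold_cv(separable, 10, spy, seed=1)
        union = set().union(*seen)
        assert union == set(separable["subject_id"])
        assert sum(len(s) for s in seen) == len(union)  # disjoint

    def test_deterministic_fold_assignment(self, separable):
        seen = [[], []]
        for trial in range(2):
            kfold_cv(
                separable, 5,
                lambda tr, te, t=trial: (seen[t].append(tuple(sorted(set(te["subject_id"])))), self._band_fitter(tr, te))[1],
                seed=9,
            )
        assert seen[0] == seen[1]

    def test_k_exceeding_subjects(self, separable):
        with pytest.raises(ValueError, match="exceeds"):
            kfold_cv(separable, 21, self._band_fitter, seed=0)


class TestKruskalWallis:
    def test_fully_separated_groups_reach_max_h(self):
        # brute-force oracle for n=9, 3 groups of 3 with distinct values:
        # ranks 1..9, group mean ranks 2, 5, 8 -> H = 12/(9*10) * 3*(9+0+9) = 7.2
        h, p = kruskal_wallis_by_category(
            [1, 2, 3, 10, 20, 30, 100, 200, 300], [1, 1, 1, 2, 2, 2, 3, 3, 3]
        )
        assert h == pytest.approx(7.2, abs=1e-9)

    def test_null_simulation_rarely_significant(self):
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(100):
            scores = rng.normal(size=300)
            labels = rng.integers(1, 4, 300)
            _, p = kruskal_wallis_by_category(scores, labels)
            rejections += p <= 0.01
        assert rejections <= 5

    def test_category_separated_scores_are_significant(self, ordering_experiment):
        h, p = kruskal_wallis_by_category(
            ordering_experiment["scores"], ordering_experiment["labels"]
        )
        assert p < 0.001

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            kruskal_wallis_by_category([1.0, 2.0], [2, 2])
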