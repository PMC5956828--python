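"""Multiclass ROC, cutoff sweeps and the A/B/C error taxonomy."""

import itertools

import numpy as np
import pandas as pd
import pytest

import embedclass as ec
from embedclass import SlideTruth


def _pair_counting_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestMrocAuc:
    def test_perfect_separation(self):
        scores = pd.DataFrame({"a": [0.9, 0.8, 0.1, 0.2], "b": [0.1, 0.2, 0.9, 0.8]})
        assert ec.mroc_auc(scores, ["a", "a", "b", "b"]) == 1.0

    def test_constant_scores_are_chance(self):
        scores = pd.DataFrame({"a": [0.5] * 6, "b": [0.5] * 6})
        assert ec.mroc_auc(scores, ["a", "b", "a", "b", "a", "b"]) == 0.5

    def test_worked_two_class_example(self):
        scores = pd.DataFrame({"a": [0.9, 0.6, 0.4, 0.2], "b": [0.1, 0.4, 0.6, 0.8]})
        truths = ["a", "a", "b", "b"]
        per = ec.mroc_auc(scores, truths, per_class=True)
        assert per == {"a": 1.0, "b": 1.0}
        swapped = pd.DataFrame({"a": [0.9, 0.4, 0.6, 0.2], "b": [0.1, 0.4, 0.6, 0.8]})
        per = ec.mroc_auc(swapped, truths, per_class=True)
        assert per["a"] == 0.75

    def test_single_truth_class_rejected(self):
        scores = pd.DataFrame({"a": [0.9, 0.8], "b": [0.1, 0.2]})
        with pytest.raises(ValueError, match="two distinct"):
            ec.mroc_auc(scores, ["a", "a"])

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(7)
        classes = ["a", "b", "c"]
        for _ in range(25):
            n = int(rng.integers(4, 21))
            truths = rng.choice(classes, size=n)
            while len(set(truths)) < 2:
                truths = rng.choice(classes, size=n)
            # coarse scores force ties, exercising the midrank convention
            scores = pd.DataFrame(
                np.round(rng.random(size=(n, 3)), 1), columns=classes
            )
            per = ec.mroc_auc(scores, truths, per_class=True)
            for cls, auc in per.items():
                y = (truths == cls).astype(int)
                assert auc == pytest.approx(
                    _pair_counting_auc(scores[cls].to_numpy(), y), abs=1e-12
                )


class TestAccuracySweep:
    def _rows(self):
        return pd.DataFrame(
            {
                "prediction": ["a", "a", "b", "b", "UNDEFINED"],
                "score": [0.9, 0.6, 0.8, 0.3, 0.99],
                "truth": ["a", "b", "b", "b", "a"],
            }
        )

    def test_zero_cutoff_has_full_coverage(self):
        sweep = ec.accuracy_sweep(self._rows(), [0.0])
        row = sweep.iloc[0]
        assert row["coverage"] == 0.8  # the abstaining slide never counts
        assert row["accuracy"] == pytest.approx(3 / 4)

    def test_cutoff_above_max_score_empties_the_sweep(self):
        sweep = ec.accuracy_sweep(self._rows(), [1.01])
        assert sweep.iloc[0]["coverage"] == 0.0
        assert np.isnan(sweep.iloc[0]["accuracy"])

    def test_coverage_is_non_increasing(self):
        grid = np.linspace(0, 1, 21)
        sweep = ec.accuracy_sweep(self._rows(), grid)
        cov = sweep["coverage"].to_numpy()
        assert (np.diff(cov) <= 1e-12).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ec.accuracy_sweep(self._rows(), [])


class TestTypeErrors:
    LESIONS = ["glioma", "meningioma", "schwannoma", "metastasis", "lymphoma"]

    def test_normal_tissue_called_lesion_is_type_a(self):
        truth = SlideTruth("s", "cerebellum", is_lesional=False, is_trained_class=True)
        assert ec.type_errors("glioma", truth, self.LESIONS) == "TYPE_A"

    def test_wrong_lesion_class_is_type_b(self):
        truth = SlideTruth("s", "meningioma", is_lesional=True, is_trained_class=True)
        assert ec.type_errors("metastasis", truth, self.LESIONS) == "TYPE_B"

    def test_untrained_truth_is_type_c(self):
        truth = SlideTruth("s", ec.NOVEL, is_lesional=True, is_trained_class=False)
        assert ec.type_errors("glioma", truth, self.LESIONS) == "TYPE_C"

    def test_match_and_abstention(self):
        truth = SlideTruth("s", "glioma", is_lesional=True, is_trained_class=True)
        assert ec.type_errors("glioma", truth, self.LESIONS) == "CORRECT"
        assert ec.type_errors("UNDEFINED", truth, self.LESIONS) == "EXCLUDED"
        assert ec.type_errors("DIFFERENTIAL", truth, self.LESIONS) == "EXCLUDED"
        assert ec.type_errors("INSUFFICIENT_LESIONAL", truth, self.LESIONS) == "EXCLUDED"

    def test_report_partitions_the_cohort(self):
        truths = {
            "s1": SlideTruth("s1", "glioma", True, True),
            "s2": SlideTruth("s2", "cerebellum", False, True),
            "s3": SlideTruth("s3", ec.NOVEL, True, False),
            "s4": SlideTruth("s4", "meningioma", True, True),
        }
        preds = {
            "m": {"s1": "glioma", "s2": "glioma", "s3": "UNDEFINED", "s4": "lymphoma"}
        }
        report = ec.evaluation_report(preds, truths, self.LESIONS)
        outcomes = report["outcome"].value_counts().to_dict()
        assert sum(outcomes.values()) == len(truths)
        assert outcomes == {"CORRECT": 1, "TYPE_A": 1, "EXCLUDED": 1, "TYPE_B": 1}
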