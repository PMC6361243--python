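"""Metric suite, Mann-Whitney testing and leave-one-out bookkeeping."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from pairsite.encoding import encode_complex
from pairsite.errors import EmptyInputError, PairsiteError, SingleClassError
from pairsite.evaluation import (
    ChainPrediction,
    confusion_metrics,
    evaluation_report,
    loo_cv,
    mann_whitney_u,
    max_mcc_threshold,
    metrics,
    partner_specificity_test,
    rank_auc,
    sequence_identity,
    write_report,
)
from pairsite.fixtures import ToyComplexSpec, make_toy_complex
from pairsite.model import ModelConfig


class TestMetrics:
    def test_perfect_ranking(self):
        out = metrics(np.array([0.9, 0.8, 0.1]), np.array([1, 1, 0]))
        assert out["auc_roc"] == 1.0
        assert out["mcc"] == pytest.approx(1.0)

    def test_confusion_closed_form(self):
        m = confusion_metrics(tp=2, fp=0, tn=1, fn=0)
        assert m["mcc"] == pytest.approx(1.0)
        assert m["precision"] == 1.0 and m["recall"] == 1.0
        m2 = confusion_metrics(tp=1, fp=1, tn=1, fn=1)
        assert m2["mcc"] == pytest.approx(0.0)
        assert m2["specificity"] == 0.5 and m2["npv"] == 0.5

    def test_max_mcc_threshold_prefers_lowest_tie(self):
        scores = np.array([0.1, 0.4, 0.4, 0.9])
        labels = np.array([0, 1, 1, 1])
        threshold, m = max_mcc_threshold(scores, labels)
        assert threshold == pytest.approx(0.4)
        assert m["mcc"] == pytest.approx(1.0)

    def test_random_scores_near_chance(self, rng):
        scores = rng.random(2000)
        labels = rng.integers(0, 2, 2000)
        out = metrics(scores, labels)
        assert abs(out["auc_roc"] - 0.5) < 0.04
        # PR-AUC of a random scorer approximates the positive prevalence
        assert abs(out["auc_pr"] - labels.mean()) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(SingleClassError):
            metrics(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_rank_formulation_agrees_with_curve_auc(self, rng):
        for _ in range(5):
            scores = rng.integers(0, 20, 500) / 20.0  # heavy ties
            labels = rng.integers(0, 2, 500)
            assert abs(rank_auc(scores, labels)
                       - roc_auc_score(labels, scores)) < 1e-12


class TestMannWhitney:
    def test_identical_tied_samples(self):
        u, p = mann_whitney_u([1.0] * 5, [1.0] * 5)
        assert u == pytest.approx(12.5)
        assert p == pytest.approx(1.0)

    def test_complete_separation_exact_p(self):
        u, p = mann_whitney_u([3.0, 4.0, 5.0], [0.0, 1.0, 2.0])
        assert u == 9.0
        assert p == pytest.approx(0.1)  # 2 of the 20 orderings

    def test_u_identity(self, rng):
        x, y = rng.random(6), rng.random(7)
        ux, _ = mann_whitney_u(x, y)
        uy, _ = mann_whitney_u(y, x)
        assert ux + uy == pytest.approx(6 * 7)

    def test_empty_group_rejected(self):
        with pytest.raises(EmptyInputError):
            mann_whitney_u([], [1.0])


class TestPartnerSpecificity:
    def _prediction(self, iid, seq, iface_positions, rng, specific_boost):
        n = len(seq)
        iface = np.zeros(n, dtype=bool)
        iface[list(iface_positions)] = True
        scores = rng.random(n) * 0.3
        scores[iface] += specific_boost
        return ChainPrediction(iid, seq, scores, iface)

    def test_partner_specific_scores_detected(self, rng):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
        preds = [
            self._prediction("x1", seq, range(0, 8), rng, 0.6),
            self._prediction("x2", seq, range(15, 23), rng, 0.6),
            self._prediction("x3", seq, range(8, 15), rng, 0.6),
        ]
        u, p = partner_specificity_test(preds)
        assert p < 0.01  # specific interfaces score higher than borrowed ones

    def test_nonspecific_scores_give_large_p(self, rng):
        seq = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"
        preds = [
            self._prediction("x1", seq, range(0, 8), rng, 0.0),
            self._prediction("x2", seq, range(15, 23), rng, 0.0),
        ]
        _, p = partner_specificity_test(preds)
        assert p > 0.05

    def test_unrelated_sequences_not_grouped(self, rng):
        preds = [
            self._prediction("x1", "ACDEFGHIKLMNPQRSTVWY", range(0, 5), rng, 0.5),
            self._prediction("y1", "WYWYWYWYWYWYWYWYWYWY", range(5, 10), rng, 0.5),
        ]
        with pytest.raises(EmptyInputError):
            partner_specificity_test(preds)

    def test_sequence_identity_values(self):
        assert sequence_identity("ACDEFGHIKL", "ACDEFGHIKL") == 1.0
        assert sequence_identity("ACDEFGHIKL", "ACDEFGHIKV") == pytest.approx(0.9)


@pytest.fixture(scope="module")
def small_loo():
    tiny = ModelConfig(n_rounds=25, max_depth=3, n_oof_folds=2)
    encs = {}
    for k, seed in enumerate((21, 22, 23)):
        toy = make_toy_complex(ToyComplexSpec(
            seed=seed, n_res_a=12, n_res_b=12, interface_width=3))
        encs[toy.complex_id] = encode_complex(
            toy.pair, toy.contacts, toy.profiles_a, toy.profiles_b)
    return encs, loo_cv(encs, config=tiny, seed=0)


class TestLooCv:
    def test_one_result_per_complex(self, small_loo):
        encs, results = small_loo
        assert sorted(r.complex_id for r in results) == sorted(encs)

    def test_left_out_complex_scored_unsampled(self, small_loo):
        encs, results = small_loo
        for r in results:
            na, nb = encs[r.complex_id].shape
            assert r.step2_matrix.scores.shape == (na, nb)
            assert r.labels.size == na * nb  # every pair, no sampling

    def test_needs_two_complexes(self, small_loo):
        encs, _ = small_loo
        cid = sorted(encs)[0]
        with pytest.raises(PairsiteError):
            loo_cv({cid: encs[cid]})

    def test_report_fields_within_bounds(self, small_loo, tmp_path):
        _, results = small_loo
        report = evaluation_report(results)
        for key, value in report.items():
            if "auc" in key:
                assert 0.0 <= value <= 1.0, key
        assert -1.0 <= report["site_mcc"] <= 1.0
        write_report(report, str(tmp_path / "r.json"), str(tmp_path / "r.tsv"))
        header, row = (tmp_path / "r.tsv").read_text().splitlines()
        assert header.split("\t")[:3] == ["AUCrocAvg", "AUCroc", "AUCpr"]
        assert len(row.split("\t")) == len(header.split("\t"))
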