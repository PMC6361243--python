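"""Two-step stacked classifier: training, stacking, prediction, importance."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from pairsite.encoding import STEP2_EXTRA_STRUCT
from pairsite.errors import ShapeMismatchError, SingleClassError
from pairsite.model import (
    ModelConfig,
    SklearnBackend,
    augment_step2,
    feature_importance,
    load_bundle,
    predict,
    save_bundle,
    train_step,
)
from pairsite.pairs import all_pairs_table, build_design_matrix

SMALL = ModelConfig(n_rounds=30, max_depth=3)


def _toy_data(rng, n=300, d=8):
    X = rng.normal(size=(n, d))
    y = (X[:, 0] + 0.5 * X[:, 1] > 0).astype(int)
    names = [f"sig.f{k}" if k < 2 else f"noise.f{k}" for k in range(d)]
    return X, y, names


class TestTrainStep:
    def test_separable_data_learned(self, rng):
        X, y, names = _toy_data(rng)
        step = train_step(X, y, names, mode="structural", config=SMALL, seed=0)
        acc = ((step.predict(X) > 0.5).astype(int) == y).mean()
        assert acc >= 0.97

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(50, 4))
        with pytest.raises(SingleClassError):
            train_step(X, np.ones(50), [f"f.{k}" for k in range(4)],
                       mode="structural", config=SMALL, seed=0)

    def test_retraining_is_reproducible(self, rng):
        X, y, names = _toy_data(rng)
        a = train_step(X, y, names, mode="structural", config=SMALL, seed=3)
        b = train_step(X, y, names, mode="structural", config=SMALL, seed=3)
        assert a.predict(X) == pytest.approx(b.predict(X), abs=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        X, y, names = _toy_data(rng)
        step = train_step(X, y, names, mode="structural", config=SMALL, seed=0)
        with pytest.raises(ShapeMismatchError):
            step.predict(X[:, :4])

    def test_pure_noise_gives_chance_level_auc(self, rng):
        # 5-fold CV on random labels: AUC must sit near 0.5
        X = rng.normal(size=(2000, 10))
        y = rng.integers(0, 2, size=2000)
        names = [f"noise.f{k}" for k in range(10)]
        aucs = []
        for train, test in StratifiedKFold(5).split(X, y):
            step = train_step(X[train], y[train], names,
                              mode="structural", config=SMALL, seed=0)
            aucs.append(roc_auc_score(y[test], step.predict(X[test])))
        assert abs(np.mean(aucs) - 0.5) < 0.08


class TestStacking:
    def test_structural_augmentation_adds_13_columns(self, encodings4, trained4):
        cid = sorted(encodings4)[0]
        enc = encodings4[cid]
        table = all_pairs_table(enc)
        X, _, names = build_design_matrix(table, {cid: enc})
        from pairsite.model import predict_step1_matrix

        f1 = predict_step1_matrix(enc, trained4.step1)
        X2, extra = augment_step2(X, table, {cid: f1}, {cid: enc})
        assert X2.shape[1] == X.shape[1] + 13
        assert extra == STEP2_EXTRA_STRUCT

    def test_constant_scores_give_degree_dependent_block(self, encodings4):
        from pairsite.pairs import PairScoreMatrix

        cid = sorted(encodings4)[0]
        enc = encodings4[cid]
        table = all_pairs_table(enc)
        X, _, _ = build_design_matrix(table, {cid: enc})
        na, nb = enc.shape
        const = PairScoreMatrix(cid, np.full((na, nb), 0.25))
        X2, _ = augment_step2(X, table, {cid: const}, {cid: enc})
        extras = X2[:, X.shape[1]:]
        assert np.all(extras[:, 0] == 0.25)           # score column
        # mean/max/min aggregations of a constant matrix are the constant
        for col in (2, 3, 4, 6, 7, 8, 10, 11):
            nz = extras[:, col] != 0  # zero only for empty neighbourhoods
            assert np.all(extras[nz, col] == pytest.approx(0.25))


class TestPredict:
    def test_matrix_shape_and_range(self, encodings4, trained4):
        cid = sorted(encodings4)[0]
        enc = encodings4[cid]
        f2, f1 = predict(enc, trained4.step1, trained4.step2)
        assert f2.scores.shape == enc.shape == f1.scores.shape
        for f in (f1, f2):
            assert np.all((f.scores >= 0) & (f.scores <= 1))

    def test_chain_swap_transposes_exactly(self, encodings4, trained4):
        cid = sorted(encodings4)[1]
        enc = encodings4[cid]
        f2, f1 = predict(enc, trained4.step1, trained4.step2)
        f2s, f1s = predict(enc.swapped(), trained4.step1, trained4.step2)
        assert np.array_equal(f1s.scores, f1.scores.T)
        assert np.array_equal(f2s.scores, f2.scores.T)


class TestFeatureImportance:
    def test_shares_sum_to_one_and_signal_dominates(self, rng):
        X, y, names = _toy_data(rng, n=500)
        step = train_step(X, y, names, mode="structural", config=SMALL, seed=0)
        shares = feature_importance(step)
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)
        assert max(shares, key=shares.get) == "sig"

    def test_unused_feature_has_zero_share(self, rng):
        X, y, names = _toy_data(rng, n=500)
        X[:, -1] = 0.0  # constant column can never split
        step = train_step(X, y, names, mode="structural", config=SMALL, seed=0)
        shares = feature_importance(step, family_map=lambda n: n)
        assert shares.get(names[-1], 0.0) == 0.0

    def test_sklearn_backend_fulfils_contract(self, rng):
        X, y, names = _toy_data(rng, n=300, d=5)
        cfg = ModelConfig(n_rounds=30, max_depth=2)
        step = train_step(X, y, names, mode="structural", config=cfg,
                          seed=0, backend="sklearn")
        assert isinstance(step.backend, SklearnBackend)
        assert roc_auc_score(y, step.predict(X)) > 0.95
        shares = feature_importance(step)
        assert sum(shares.values()) == pytest.approx(1.0)
        assert max(shares, key=shares.get) == "sig"


def test_bundle_roundtrip(tmp_path, encodings4, trained4):
    path = str(tmp_path / "bundle")
    save_bundle(path, trained4.step1, trained4.step2, trained4.calibrator)
    step1, step2, calibrator, meta = load_bundle(path)
    cid = sorted(encodings4)[0]
    enc = encodings4[cid]
    before, _ = predict(enc, trained4.step1, trained4.step2)
    after, _ = predict(enc, step1, step2)
    assert after.scores == pytest.approx(before.scores, abs=1e-7)
    assert meta["mode"] == "structural"
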