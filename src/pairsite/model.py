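"""Two-step stacked boosted-tree contact classifier.

Step 1 scores every ordered residue pair from its concatenated feature
blocks.  Step 2 sees the same features plus the (symmetry-averaged) step-1
score of the pair and, in structural mode, the twelve structural pairwise
environment aggregations of the step-1 score matrix over the Voronoi
neighbourhoods of both residues.  During training the step-1 scores fed to
step 2 come from out-of-fold prediction over complexes, so step 2 never
sees scores produced by a model that saw the same complex.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .encoding import (
    EncodedComplex,
    STEP2_EXTRA_SEQ,
    STEP2_EXTRA_STRUCT,
    family_of,
)
from .environments import pairwise_env_features
from .errors import ModeMismatchError, ShapeMismatchError, SingleClassError
from .pairs import (
    PairScoreMatrix,
    all_pairs_table,
    build_design_matrix,
    symmetrize,
)


@dataclass
class ModelConfig:
    """Boosted-tree hyperparameters (fixed defaults, all overridable)."""

    max_depth: int = 6
    n_rounds: int = 500
    learning_rate: float = 0.1
    subsample: float = 1.0
    n_oof_folds: int = 5

    def to_dict(self) -> dict:
        return asdict(self)


def _sanitize(names: list[str]) -> list[str]:
    return [n.replace("[", "(").replace("]", ")").replace("<", "_") for n in names]


class XGBoostBackend:
    """Default tree backend: xgboost binary-logistic booster."""

    def __init__(self) -> None:
        self.booster: xgb.Booster | None = None
        self.feature_names: list[str] = []

    def fit(self, X: np.ndarray, y: np.ndarray, feature_names: list[str],
            config: ModelConfig, seed: int) -> "XGBoostBackend":
        self.feature_names = _sanitize(feature_names)
        dtrain = xgb.DMatrix(X, label=y, feature_names=self.feature_names)
        params = {
            "max_depth": config.max_depth,
            "eta": config.learning_rate,
            "subsample": config.subsample,
            "objective": "binary:logistic",
            "eval_metric": "logloss",
            "tree_method": "hist",
            "nthread": 1,
            "seed": int(seed) % (2 ** 31),
        }
        self.booster = xgb.train(params, dtrain, num_boost_round=config.n_rounds)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        dmat = xgb.DMatrix(X, feature_names=self.feature_names)
        return self.booster.predict(dmat)

    def split_counts(self) -> dict[str, float]:
        return self.booster.get_score(importance_type="weight")

    def save(self, path: str) -> None:
        self.booster.save_model(path)

    @classmethod
    def load(cls, path: str, feature_names: list[str]) -> "XGBoostBackend":
        backend = cls()
        backend.booster = xgb.Booster()
        backend.booster.load_model(path)
        backend.feature_names = _sanitize(feature_names)
        backend.booster.feature_names = backend.feature_names
        return backend


class SklearnBackend:
    """Alternative backend (scikit-learn gradient boosting) used as an
    independent cross-check of the fit/predict/split-count contract."""

    def __init__(self) -> None:
        self.model = None
        self.feature_names: list[str] = []

    def fit(self, X, y, feature_names, config: ModelConfig, seed: int):
        from sklearn.ensemble import GradientBoostingClassifier

        self.feature_names = list(feature_names)
        self.model = GradientBoostingClassifier(
            max_depth=config.max_depth,
            n_estimators=config.n_rounds,
            learning_rate=config.learning_rate,
            subsample=config.subsample,
            random_state=int(seed) % (2 ** 31),
        ).fit(X, y)
        return self

    def predict(self, X):
        return self.model.predict_proba(X)[:, 1]

    def split_counts(self) -> dict[str, float]:
        counts: dict[str, float] = {}
        for est in self.model.estimators_.ravel():
            tree = est.tree_
            for f in tree.feature:
                if f >= 0:
                    name = self.feature_names[f]
                    counts[name] = counts.get(name, 0) + 1
        return counts


BACKENDS = {"xgboost": XGBoostBackend, "sklearn": SklearnBackend}


@dataclass
class TrainedStep:
    """One trained classification step and its metadata."""

    step: int
    backend: object
    feature_names: list[str]
    mode: str
    seed: int
    config: ModelConfig = field(default_factory=ModelConfig)

    def predict(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != len(self.feature_names):
            raise ShapeMismatchError(
                f"step {self.step}: {X.shape[1]} features given, model "
                f"expects {len(self.feature_names)}"
            )
        return np.asarray(self.backend.predict(X), dtype=float)


def train_step(X: np.ndarray, y: np.ndarray, feature_names: list[str],
               mode: str, step: int = 1,
               config: ModelConfig | None = None, seed: int = 0,
               backend: str = "xgboost") -> TrainedStep:
    """Fit one boosted-tree step; requires both classes present."""
    config = config or ModelConfig()
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise SingleClassError(f"step {step}: training labels are single-class")
    handle = BACKENDS[backend]().fit(np.asarray(X, dtype=float), y,
                                     feature_names, config, seed)
    return TrainedStep(step=step, backend=handle,
                       feature_names=list(feature_names), mode=mode,
                       seed=seed, config=config)


def step2_extras(table: pd.DataFrame, score_matrices: dict[str, PairScoreMatrix],
                 encodings: dict[str, EncodedComplex]) -> np.ndarray:
    """Step-2 augmentation columns for a table of ordered pair examples.

    Structural mode appends 13 columns per row: the pair's step-1 score and
    the 12 pairwise-environment aggregations.  For BA-ordered rows the
    "neighbours of the first residue" aggregation refers to the beta
    residue, so the dot-j and i-dot blocks are swapped — the BA vector is
    the exact mirror image of the AB vector.  Sequence mode appends the
    score only.
    """
    any_enc = next(iter(encodings.values()))
    structural = any_enc.mode == "structural"
    width = 13 if structural else 1
    out = np.zeros((len(table), width))
    row0 = 0
    for complex_id, group in table.groupby("complex_id", sort=False):
        enc = encodings[str(complex_id)]
        if str(complex_id) not in score_matrices:
            raise ShapeMismatchError(
                f"no step-1 score matrix for complex {complex_id}")
        f = score_matrices[str(complex_id)].scores
        ii = group["i"].to_numpy()
        jj = group["j"].to_numpy()
        is_ab = (group["ordering"] == "AB").to_numpy()
        rows = slice(row0, row0 + len(group))
        out[rows, 0] = f[ii, jj]
        if structural:
            env = pairwise_env_features(f, enc.graph_a, enc.graph_b)
            vals = env[ii, jj]  # (n, 12): dotj, idot, dotdot
            mirrored = np.concatenate(
                [vals[:, 4:8], vals[:, 0:4], vals[:, 8:12]], axis=1)
            out[rows, 1:] = np.where(is_ab[:, None], vals, mirrored)
        row0 += len(group)
    return out


def augment_step2(X: np.ndarray, table: pd.DataFrame,
                  score_matrices: dict[str, PairScoreMatrix],
                  encodings: dict[str, EncodedComplex]) -> tuple[np.ndarray, list[str]]:
    """Append step-1 score (+ environments) columns to a design matrix."""
    extras = step2_extras(table, score_matrices, encodings)
    any_enc = next(iter(encodings.values()))
    extra_names = (STEP2_EXTRA_STRUCT if any_enc.mode == "structural"
                   else STEP2_EXTRA_SEQ)
    return np.hstack([X, extras]), list(extra_names)


def _matrices_from_table(table: pd.DataFrame, scores: np.ndarray,
                         shape: tuple[int, int],
                         complex_id: str) -> PairScoreMatrix:
    """Reassemble AB/BA row scores into one symmetry-averaged matrix."""
    na, nb = shape
    ab = np.zeros((na, nb))
    ba = np.zeros((nb, na))
    is_ab = (table["ordering"] == "AB").to_numpy()
    ii = table["i"].to_numpy()
    jj = table["j"].to_numpy()
    ab[ii[is_ab], jj[is_ab]] = scores[is_ab]
    ba[jj[~is_ab], ii[~is_ab]] = scores[~is_ab]
    return symmetrize(ab, ba, complex_id)


def predict_step1_matrix(enc: EncodedComplex, step1: TrainedStep) -> PairScoreMatrix:
    """Score all pairs of a complex with step 1 and symmetry-average."""
    if step1.mode != enc.mode:
        raise ModeMismatchError(
            f"model mode {step1.mode!r} vs complex mode {enc.mode!r}")
    table = all_pairs_table(enc)
    X, _, _ = build_design_matrix(table, {enc.complex_id: enc})
    scores = step1.predict(X)
    return _matrices_from_table(table, scores, enc.shape, enc.complex_id)


def predict(enc: EncodedComplex, step1: TrainedStep,
            step2: TrainedStep | None = None
            ) -> tuple[PairScoreMatrix, PairScoreMatrix]:
    """Full two-step pipeline over every cross-chain pair (no sampling).

    Returns ``(final, step1_matrix)``; with no step-2 model both are the
    step-1 matrix.
    """
    f1 = predict_step1_matrix(enc, step1)
    if step2 is None:
        return f1, f1
    table = all_pairs_table(enc)
    X, _, _ = build_design_matrix(table, {enc.complex_id: enc})
    X2, _ = augment_step2(X, table, {enc.complex_id: f1},
                          {enc.complex_id: enc})
    scores = step2.predict(X2)
    f2 = _matrices_from_table(table, scores, enc.shape, enc.complex_id)
    return f2, f1


def feature_importance(step: TrainedStep,
                       family_map=None) -> dict[str, float]:
    """Per-family importance shares from tree split counts.

    The share of a family is the number of tree splits on any of its
    features divided by the total split count; shares sum to 1.
    """
    family_map = family_map or family_of
    counts = step.backend.split_counts()
    shares: dict[str, float] = {}
    total = 0.0
    for raw_name, count in counts.items():
        fam = family_map(raw_name)
        shares[fam] = shares.get(fam, 0.0) + float(count)
        total += float(count)
    if total > 0:
        shares = {k: v / total for k, v in shares.items()}
    return shares


# ---------------------------------------------------------------------------
# Model bundle persistence
# ---------------------------------------------------------------------------

def save_bundle(path: str, step1: TrainedStep, step2: TrainedStep | None,
                calibrator=None, extra_meta: dict | None = None) -> None:
    """Serialize trained steps + metadata (+ isotonic calibration) to a dir."""
    os.makedirs(path, exist_ok=True)
    step1.backend.save(os.path.join(path, "step1.json"))
    meta = {
        "mode": step1.mode,
        "seed": step1.seed,
        "config": step1.config.to_dict(),
        "step1_features": step1.feature_names,
        "step2_features": step2.feature_names if step2 else None,
        "version": 1,
    }
    if extra_meta:
        meta.update(extra_meta)
    if step2 is not None:
        step2.backend.save(os.path.join(path, "step2.json"))
    if calibrator is not None:
        from .scoring import calibrator_to_dict

        with open(os.path.join(path, "calibration.json"), "w") as fh:
            json.dump(calibrator_to_dict(calibrator), fh)
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_bundle(path: str):
    """Load a saved bundle; returns (step1, step2, calibrator, meta)."""
    with open(os.path.join(path, "meta.json")) as fh:
        meta = json.load(fh)
    config = ModelConfig(**meta["config"])
    step1 = TrainedStep(
        step=1,
        backend=XGBoostBackend.load(os.path.join(path, "step1.json"),
                                    meta["step1_features"]),
        feature_names=meta["step1_features"], mode=meta["mode"],
        seed=meta["seed"], config=config,
    )
    step2 = None
    if meta.get("step2_features"):
        step2 = TrainedStep(
            step=2,
            backend=XGBoostBackend.load(os.path.join(path, "step2.json"),
                                        meta["step2_features"]),
            feature_names=meta["step2_features"], mode=meta["mode"],
            seed=meta["seed"], config=config,
        )
    calibrator = None
    cal_path = os.path.join(path, "calibration.json")
    if os.path.exists(cal_path):
        from .scoring import calibrator_from_dict

        with open(cal_path) as fh:
            calibrator = calibrator_from_dict(json.load(fh))
    return step1, step2, calibrator, meta
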