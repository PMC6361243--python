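"""Training orchestration: sampling, out-of-fold stacking, calibration.

`train_pipeline` takes encoded complexes with contact labels and produces a
trained two-step model plus (optionally) an isotonic expected-precision
calibrator.  Step-1 scores fed to step 2 during training are produced by
K-fold out-of-fold prediction over complexes so that no complex is scored
by a model that saw it; the calibrator is likewise fitted on out-of-fold
step-2 site scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import EncodedComplex
from .errors import DatasetError
from .model import (
    ModelConfig,
    TrainedStep,
    augment_step2,
    predict,
    predict_step1_matrix,
    train_step,
)
from .pairs import (
    PairScoreMatrix,
    build_design_matrix,
    enumerate_pairs,
    sample_negatives,
    training_table,
)
from .scoring import binding_site_scores, calibrate, smooth
from .structures import interface_residues


@dataclass
class TrainedPipeline:
    step1: TrainedStep
    step2: TrainedStep
    calibrator: object | None
    mode: str


def sampled_training_table(encodings: dict[str, EncodedComplex],
                           ratio: int, seed: int) -> pd.DataFrame:
    frames = []
    for cid in sorted(encodings):
        enc = encodings[cid]
        if enc.contacts is None:
            raise DatasetError(f"{cid}: training requires contact labels")
        frames.append(enumerate_pairs(enc.pair, enc.contacts))
    all_pairs = pd.concat(frames, ignore_index=True)
    sampled = sample_negatives(all_pairs, ratio=ratio, seed=seed)
    if sampled.empty:
        raise DatasetError("no complex contributed a positive pair")
    return training_table(sampled)


def _complex_folds(cids: list[str], k: int, seed: int) -> list[list[str]]:
    cids = sorted(cids)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cids))
    k = max(2, min(k, len(cids)))
    folds: list[list[str]] = [[] for _ in range(k)]
    for pos, idx in enumerate(order):
        folds[pos % k].append(cids[idx])
    return [sorted(f) for f in folds]


def oof_step1_matrices(encodings: dict[str, EncodedComplex],
                       table: pd.DataFrame, config: ModelConfig,
                       seed: int) -> dict[str, PairScoreMatrix]:
    """Out-of-fold step-1 score matrices for every training complex."""
    folds = _complex_folds(list(encodings), config.n_oof_folds, seed)
    matrices: dict[str, PairScoreMatrix] = {}
    for fold in folds:
        held = set(fold)
        train_rows = ~table["complex_id"].isin(held)
        sub_table = table[train_rows].reset_index(drop=True)
        sub_enc = {c: e for c, e in encodings.items() if c not in held}
        X, y, names = build_design_matrix(sub_table, sub_enc)
        step1 = train_step(X, y, names, mode=next(iter(encodings.values())).mode,
                           step=1, config=config, seed=seed)
        for cid in fold:
            matrices[cid] = predict_step1_matrix(encodings[cid], step1)
    return matrices


def train_pipeline(encodings: dict[str, EncodedComplex],
                   config: ModelConfig | None = None, seed: int = 0,
                   ratio: int = 3,
                   fit_calibration: bool = True) -> TrainedPipeline:
    """Train step 1, step 2 (on out-of-fold step-1 scores) and calibration."""
    config = config or ModelConfig()
    mode = next(iter(encodings.values())).mode
    table = sampled_training_table(encodings, ratio, seed)
    X, y, names = build_design_matrix(table, encodings)
    oof = oof_step1_matrices(encodings, table, config, seed)
    step1 = train_step(X, y, names, mode=mode, step=1, config=config, seed=seed)
    X2, extra_names = augment_step2(X, table, oof, encodings)
    step2 = train_step(X2, y, names + extra_names, mode=mode, step=2,
                       config=config, seed=seed)
    calibrator = None
    if fit_calibration and len(encodings) >= 4:
        calibrator = _fit_calibration(encodings, table, names,
                                      extra_names, oof, config, seed)
    return TrainedPipeline(step1, step2, calibrator, mode)


def _fit_calibration(encodings, table, names, extra_names, oof,
                     config: ModelConfig, seed: int):
    """Isotonic calibration on out-of-fold step-2 site scores."""
    folds = _complex_folds(list(encodings), config.n_oof_folds, seed)
    cal_scores, cal_labels = [], []
    for fold in folds:
        held = set(fold)
        rows = ~table["complex_id"].isin(held)
        sub_table = table[rows].reset_index(drop=True)
        sub_enc = {c: e for c, e in encodings.items() if c not in held}
        Xs, ys, _ = build_design_matrix(sub_table, sub_enc)
        s1 = train_step(Xs, ys, names, mode=next(iter(encodings.values())).mode,
                        step=1, config=config, seed=seed)
        X2s, _ = augment_step2(Xs, sub_table,
                               {c: oof[c] for c in sub_enc}, sub_enc)
        s2 = train_step(X2s, ys, names + extra_names,
                        mode=next(iter(encodings.values())).mode,
                        step=2, config=config, seed=seed)
        for cid in fold:
            enc = encodings[cid]
            final, _ = predict(enc, s1, s2)
            raw_a, raw_b = binding_site_scores(final)
            mask_a, mask_b = interface_residues(enc.contacts)
            cal_scores.append(smooth(raw_a))
            cal_scores.append(smooth(raw_b))
            cal_labels.append(mask_a.astype(int))
            cal_labels.append(mask_b.astype(int))
    scores = np.concatenate(cal_scores)
    labels = np.concatenate(cal_labels)
    if len(np.unique(labels)) < 2:
        return None
    return calibrate(scores, labels)
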