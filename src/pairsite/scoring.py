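"""Conversion of pair-score matrices into per-residue binding-site scores.

The site score of residue alpha is rank based: with all n = |A| x |B| pair
scores sorted from highest to lowest,

    Is(alpha) = sum_{i = 0..floor(log2 n)}  Xc(alpha, 2^i) / 2^i

where Xc(alpha, 2^i) counts how many of the 2^i highest-scoring pairs
(bucket capped at n) contain alpha.  The score therefore depends only on
the ordering of the pair scores, and improving any pair involving alpha
can only raise it.  Site scores are then smoothed along the sequence with
weights (1/4, 1/2, 1/4) and optionally mapped to an expected precision by
isotonic regression fitted on held-out predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .errors import EmptyInputError, SingleClassError
from .pairs import PairScoreMatrix


@dataclass
class BindingSiteProfile:
    """Per-residue interface scores of one chain."""

    chain_id: str
    raw: np.ndarray
    smoothed: np.ndarray
    expected_precision: np.ndarray | None = None


def _ranked_pairs(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair indices sorted by descending score (stable in (i, j) order),
    together with the sorted score values."""
    na, nb = scores.shape
    flat = scores.ravel()  # C order == (i, j) lexicographic
    order = np.argsort(-flat, kind="stable")
    return order // nb, order % nb, flat[order]


def binding_site_scores(matrix: PairScoreMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Rank-based site scores Is for both chains of one complex.

    Returns ``(scores_a, scores_b)`` with one non-negative value per
    residue of chain A and chain B respectively.  Each bucket counts every
    pair scoring at least as high as its 2^i-th ranked pair, so tied pairs
    are counted all-or-none: for distinct scores this is the plain top-2^i
    bucket, and a symmetric (homodimer) matrix always yields identical
    profiles for the two chains.
    """
    scores = np.asarray(matrix.scores, dtype=float)
    if scores.size == 0:
        raise EmptyInputError(f"{matrix.complex_id}: empty score matrix")
    na, nb = scores.shape
    n = na * nb
    rows, cols, ranked = _ranked_pairs(scores)
    is_a = np.zeros(na)
    is_b = np.zeros(nb)
    i = 0
    while 2 ** i <= n or i == 0:
        bucket = min(2 ** i, n)
        # include every pair tied with the bucket's last score
        count = int(np.searchsorted(-ranked, -ranked[bucket - 1], side="right"))
        weight = 1.0 / 2 ** i
        is_a += np.bincount(rows[:count], minlength=na) * weight
        is_b += np.bincount(cols[:count], minlength=nb) * weight
        if 2 ** i >= n:
            break
        i += 1
    return is_a, is_b


def smooth(raw: np.ndarray) -> np.ndarray:
    """Sequence smoothing with the 3-residue window (1/4, 1/2, 1/4).

    At the termini the missing neighbour is dropped and the remaining
    weights renormalised, so a constant vector is a fixed point.
    """
    raw = np.asarray(raw, dtype=float)
    n = raw.size
    if n <= 1:
        return raw.copy()
    out = np.empty(n)
    out[0] = (2.0 * raw[0] + raw[1]) / 3.0
    out[-1] = (2.0 * raw[-1] + raw[-2]) / 3.0
    if n > 2:
        out[1:-1] = (raw[:-2] + 2.0 * raw[1:-1] + raw[2:]) / 4.0
    return out


def max_score_baseline(matrix: PairScoreMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue maximum-pair-score baseline for both chains."""
    scores = np.asarray(matrix.scores, dtype=float)
    if scores.size == 0:
        raise EmptyInputError(f"{matrix.complex_id}: empty score matrix")
    return scores.max(axis=1), scores.max(axis=0)


def mean_score_baseline(matrix: PairScoreMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue mean-pair-score baseline for both chains."""
    scores = np.asarray(matrix.scores, dtype=float)
    if scores.size == 0:
        raise EmptyInputError(f"{matrix.complex_id}: empty score matrix")
    return scores.mean(axis=1), scores.mean(axis=0)


def calibrate(scores: np.ndarray, labels: np.ndarray) -> IsotonicRegression:
    """Fit a monotone score -> expected-precision map.

    Pool-adjacent-violators isotonic regression of the binary interface
    labels on the site scores from held-out (cross-validated) complexes;
    the fitted map is non-decreasing and clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("calibration labels are single-class")
    model = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    model.fit(scores, labels)
    return model


def apply_calibration(model: IsotonicRegression, scores: np.ndarray) -> np.ndarray:
    return np.clip(model.predict(np.asarray(scores, dtype=float)), 0.0, 1.0)


def calibrator_to_dict(model: IsotonicRegression) -> dict:
    return {
        "x": np.asarray(model.X_thresholds_).tolist(),
        "y": np.asarray(model.y_thresholds_).tolist(),
    }


def calibrator_from_dict(payload: dict) -> IsotonicRegression:
    model = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    x = np.asarray(payload["x"], dtype=float)
    y = np.asarray(payload["y"], dtype=float)
    # y is already non-decreasing, so refitting reproduces the exact same
    # step/interpolation function as the original model.
    model.fit(x, y)
    return model


def site_profiles(matrix: PairScoreMatrix, pair,
                  calibrator: IsotonicRegression | None = None
                  ) -> tuple[BindingSiteProfile, BindingSiteProfile]:
    """Raw + smoothed (+ calibrated) site profiles for both chains."""
    raw_a, raw_b = binding_site_scores(matrix)
    sm_a, sm_b = smooth(raw_a), smooth(raw_b)
    ep_a = ep_b = None
    if calibrator is not None:
        ep_a = apply_calibration(calibrator, sm_a)
        ep_b = apply_calibration(calibrator, sm_b)
    chain_a_id = pair.chain_a[0].chain_id
    chain_b_id = pair.chain_b[0].chain_id
    return (
        BindingSiteProfile(chain_a_id, raw_a, sm_a, ep_a),
        BindingSiteProfile(chain_b_id, raw_b, sm_b, ep_b),
    )


def write_site_table(path: str, pair, profiles) -> None:
    """Per-residue TSV: chain, res_number, aa, raw, smoothed, expected_precision."""
    prof_a, prof_b = profiles
    with open(path, "w") as fh:
        fh.write("chain\tres_number\taa\traw\tsmoothed\texpected_precision\n")
        for chain, prof in ((pair.chain_a, prof_a), (pair.chain_b, prof_b)):
            for k, res in enumerate(chain):
                ep = ("NA" if prof.expected_precision is None
                      else f"{prof.expected_precision[k]:.6f}")
                fh.write(
                    f"{res.chain_id}\t{res.res_number}\t{res.aa}\t"
                    f"{prof.raw[k]:.6f}\t{prof.smoothed[k]:.6f}\t{ep}\n"
                )


def write_pair_table(path: str, pair, matrix: PairScoreMatrix) -> None:
    """Pair-score TSV: chainA, resA, chainB, resB, score."""
    with open(path, "w") as fh:
        fh.write("chain_a\tres_a\tchain_b\tres_b\tscore\n")
        for i, ra in enumerate(pair.chain_a):
            for j, rb in enumerate(pair.chain_b):
                fh.write(
                    f"{ra.chain_id}\t{ra.res_number}\t{rb.chain_id}\t"
                    f"{rb.res_number}\t{matrix.scores[i, j]:.6f}\n"
                )
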