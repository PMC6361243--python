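"""Cross-chain residue pair enumeration, sampling and symmetric encoding.

Because a pair (alpha_i, beta_j) can equally be written (beta_j, alpha_i),
every sampled pair enters the training set twice, once per ordering, with
the two residue blocks concatenated in the stated order.  At prediction
time the two orderings' scores are averaged into one symmetric matrix.

Class imbalance is handled per complex: all contacts are kept and three
times as many non-contacts are drawn uniformly without replacement
(including pairs with unresolved residues); evaluation never samples.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import EncodedComplex, pair_feature_names
from .errors import ShapeMismatchError
from .structures import ContactMap, ProteinPair

NEGATIVE_RATIO = 3


@dataclass
class PairScoreMatrix:
    """Symmetry-averaged predicted contact scores, shape (len A, len B)."""

    complex_id: str
    scores: np.ndarray

    def transposed(self) -> "PairScoreMatrix":
        return PairScoreMatrix(self.complex_id, self.scores.T.copy())


def enumerate_pairs(pair: ProteinPair, contacts: ContactMap) -> pd.DataFrame:
    """All len(A) x len(B) cross-chain pairs with labels.

    Columns: complex_id, i, j, label, missing (no-coordinate flag).
    """
    na, nb = len(pair.chain_a), len(pair.chain_b)
    if contacts.labels.shape != (na, nb):
        raise ShapeMismatchError(
            f"{pair.complex_id}: contact map {contacts.labels.shape} vs "
            f"chains ({na}, {nb})"
        )
    ii, jj = np.meshgrid(np.arange(na), np.arange(nb), indexing="ij")
    missing = (contacts.missing if contacts.missing is not None
               else np.zeros((na, nb), dtype=bool))
    return pd.DataFrame({
        "complex_id": pair.complex_id,
        "i": ii.ravel(),
        "j": jj.ravel(),
        "label": contacts.labels.ravel().astype(int),
        "missing": missing.ravel(),
    })


def complex_rng(seed: int, complex_id: str) -> np.random.Generator:
    """Per-complex RNG substream keyed by a hash of the complex id, so that
    adding or removing complexes never shifts another complex's draws."""
    key = zlib.crc32(complex_id.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def sample_negatives(pairs: pd.DataFrame, ratio: int = NEGATIVE_RATIO,
                     seed: int = 0) -> pd.DataFrame:
    """Per-complex negative sampling: keep all positives, draw
    ``ratio x n_positive`` negatives uniformly without replacement (capped
    at availability).  Complexes with zero positives contribute nothing.
    Deterministic given the seed."""
    kept = []
    for complex_id, group in pairs.groupby("complex_id", sort=True):
        pos = group[group["label"] == 1]
        neg = group[group["label"] == 0]
        if len(pos) == 0:
            continue
        n_draw = min(ratio * len(pos), len(neg))
        rng = complex_rng(seed, str(complex_id))
        chosen = rng.choice(len(neg), size=n_draw, replace=False)
        kept.append(pos)
        kept.append(neg.iloc[np.sort(chosen)])
    if not kept:
        return pairs.iloc[0:0]
    return pd.concat(kept, ignore_index=True)


def encode_pair(i_block: np.ndarray, j_block: np.ndarray,
                ordering: str = "AB") -> np.ndarray:
    """Concatenate two residue blocks in the requested ordering.

    The AB vector is [alpha block, beta block]; BA is the block-swapped
    image.  Blocks must have equal length (same encoding mode).
    """
    i_block = np.asarray(i_block, dtype=float)
    j_block = np.asarray(j_block, dtype=float)
    if i_block.shape != j_block.shape:
        raise ShapeMismatchError(
            f"residue blocks differ in length: {i_block.shape} vs {j_block.shape}"
        )
    if ordering == "AB":
        return np.concatenate([i_block, j_block])
    return np.concatenate([j_block, i_block])


def symmetrize(scores_ab: np.ndarray, scores_ba: np.ndarray,
               complex_id: str = "") -> PairScoreMatrix:
    """Average the two ordering's raw score matrices.

    ``scores_ab`` is indexed (i, j); ``scores_ba`` is indexed (j, i).
    out[i, j] = (ab[i, j] + ba[j, i]) / 2.
    """
    ab = np.asarray(scores_ab, dtype=float)
    ba = np.asarray(scores_ba, dtype=float)
    if ab.shape != ba.shape[::-1]:
        raise ShapeMismatchError(
            f"score matrices do not match: {ab.shape} vs {ba.shape}"
        )
    return PairScoreMatrix(complex_id, (ab + ba.T) / 2.0)


def training_table(sampled: pd.DataFrame) -> pd.DataFrame:
    """Expand sampled pairs into both orderings, canonically sorted.

    The canonical order (complex_id, i, j, ordering) makes downstream
    training invariant to the row order of the input.
    """
    ab = sampled.assign(ordering="AB")
    ba = sampled.assign(ordering="BA")
    table = pd.concat([ab, ba], ignore_index=True)
    return table.sort_values(
        ["complex_id", "i", "j", "ordering"], kind="mergesort"
    ).reset_index(drop=True)


def build_design_matrix(table: pd.DataFrame,
                        encodings: dict[str, EncodedComplex]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Feature matrix and labels for a table of ordered pair examples."""
    blocks = []
    for complex_id, group in table.groupby("complex_id", sort=False):
        enc = encodings[str(complex_id)]
        bi = enc.block_a[group["i"].to_numpy()]
        bj = enc.block_b[group["j"].to_numpy()]
        is_ab = (group["ordering"] == "AB").to_numpy()
        first = np.where(is_ab[:, None], bi, bj)
        second = np.where(is_ab[:, None], bj, bi)
        blocks.append(np.hstack([first, second]))
    X = np.vstack(blocks)
    y = table["label"].to_numpy().astype(int)
    any_enc = next(iter(encodings.values()))
    names = pair_feature_names(any_enc.feature_names, any_enc.mode)
    return X, y, names


def all_pairs_table(enc: EncodedComplex) -> pd.DataFrame:
    """Both-ordering table over every cross-chain pair (no labels needed)."""
    na, nb = enc.shape
    ii, jj = np.meshgrid(np.arange(na), np.arange(nb), indexing="ij")
    base = pd.DataFrame({
        "complex_id": enc.complex_id,
        "i": ii.ravel(), "j": jj.ravel(),
        "label": (enc.contacts.labels.ravel().astype(int)
                  if enc.contacts is not None else 0),
    })
    return training_table(base)
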