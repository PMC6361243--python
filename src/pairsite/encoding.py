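"""Assembly of per-residue feature blocks and per-complex encodings.

A residue block concatenates, in a fixed documented order:

* the 11-residue sliding window over the sequence features (identity
  one-hot, profile log-odds and frequencies, information content,
  conservation) — 11 x 64 columns, window padding marked by the gap
  one-hot;
* structural mode only: the residue's own structural descriptors
  (8-class secondary structure one-hot, relative accessibility,
  half-sphere exposure up/down and contact number, hydrophobicity,
  protrusion and depth proxies — 15 columns);
* structural mode only: Voronoi-environment aggregations of every single
  feature (sum/mean/max/min for reals, element-wise sums for one-hots —
  226 columns) plus two missing-data flags.

Column names follow ``family.detail[.stat]`` so that importance can be
pooled per feature family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._tables import AA_ALPHABET, GAP_INDEX, STANDARD_AAS
from .environments import (
    NeighborGraph,
    env_onehot_matrix,
    env_real_matrix,
    sliding_window,
    voronoi_neighbors,
    WINDOW_WIDTH,
)
from .errors import ModeMismatchError
from .features.geometry import (
    SS_CLASSES,
    SS_INDEX,
    accessibility,
    geometric_descriptors,
    half_sphere_exposure,
    secondary_structure,
)
from .features.profiles import ProfileColumn, conservation, one_hot_aa, pseudo_profile
from .structures import ContactMap, ProteinPair


def _safe_conservation(col: ProfileColumn) -> float:
    if float(np.sum(col.frequencies)) <= 0:
        return 0.0
    return conservation(col)


def seq_feature_names() -> list[str]:
    names = [f"aa.{s}" for s in AA_ALPHABET]
    names += [f"pssm.{a}" for a in STANDARD_AAS]
    names += [f"psfm.{a}" for a in STANDARD_AAS]
    names += ["info.ic", "cons.score"]
    return names


def struct_feature_names() -> list[str]:
    names = [f"ss.{c}" for c in SS_CLASSES]
    names += ["acc.rel", "hse.up", "hse.down", "hse.cn"]
    names += ["geom.kd", "geom.protrusion", "geom.depth"]
    return names


def _seq_single_features(chain, profiles: list[ProfileColumn]) -> np.ndarray:
    aa_oh = np.stack([one_hot_aa(r.aa) for r in chain])
    pssm = np.stack([c.log_odds for c in profiles])
    psfm = np.stack([c.frequencies for c in profiles])
    info = np.array([c.info_content for c in profiles])[:, None]
    cons = np.array([_safe_conservation(c) for c in profiles])[:, None]
    return np.hstack([aa_oh, pssm, psfm, info, cons])


def _struct_single_features(pair: ProteinPair, which: str,
                            sasa_points: int) -> tuple[np.ndarray, np.ndarray]:
    chain = pair.chain(which)
    ss = secondary_structure(chain)
    ss_oh = np.zeros((len(chain), len(SS_CLASSES)))
    for i, c in enumerate(ss):
        ss_oh[i, SS_INDEX[c]] = 1.0
    acc, acc_flags = accessibility(pair, which, n_points=sasa_points)
    up, down, hse_flags = half_sphere_exposure(chain)
    geom = geometric_descriptors(chain, up, down)
    cn = (up + down).astype(float)
    feats = np.hstack([
        ss_oh, acc[:, None], up[:, None].astype(float),
        down[:, None].astype(float), cn[:, None], geom,
    ])
    unresolved = np.array([not r.resolved for r in chain])
    return feats, unresolved | acc_flags


def encode_chain(pair: ProteinPair, which: str,
                 profiles: list[ProfileColumn] | None = None,
                 mode: str | None = None,
                 graph: NeighborGraph | None = None,
                 sasa_points: int = 120) -> tuple[np.ndarray, list[str], NeighborGraph | None]:
    """Encode one chain of a complex into its per-residue block matrix.

    Returns ``(block, column_names, graph)``; the Voronoi graph is None in
    sequence mode.
    """
    mode = mode or pair.mode
    chain = pair.chain(which)
    if profiles is None:
        profiles = pseudo_profile(pair.sequence(which))
    seq_feats = _seq_single_features(chain, profiles)
    seq_names = seq_feature_names()

    pad = np.zeros(seq_feats.shape[1])
    pad[GAP_INDEX] = 1.0  # gap one-hot marks out-of-range window slots
    windowed = sliding_window(seq_feats, WINDOW_WIDTH, pad)
    half = WINDOW_WIDTH // 2
    win_names = [
        f"{base}.w{k:+d}"
        for k in range(-half, half + 1)
        for base in seq_names
    ]

    if mode == "sequence":
        return windowed, win_names, None

    if pair.mode != "structural":
        raise ModeMismatchError(
            f"{pair.complex_id}: structural encoding requested for a "
            "sequence-only pair"
        )
    struct_feats, unresolved = _struct_single_features(pair, which, sasa_points)
    struct_names = struct_feature_names()
    if graph is None:
        graph = voronoi_neighbors(chain)
    nbr_lists = graph.neighbor_lists()

    singles = np.hstack([seq_feats, struct_feats])
    single_names = seq_names + struct_names
    onehot_cols = [k for k, n in enumerate(single_names)
                   if n.startswith(("aa.", "ss."))]
    real_cols = [k for k in range(len(single_names)) if k not in onehot_cols]

    env_real_block, env_missing = env_real_matrix(singles[:, real_cols], nbr_lists)
    env_onehot_block = env_onehot_matrix(singles[:, onehot_cols], nbr_lists)
    real_names = [single_names[k] for k in real_cols]
    env_real_names = [
        f"{n}.env.{stat}" for stat in ("sum", "mean", "max", "min")
        for n in real_names
    ]
    env_onehot_names = [f"{single_names[k]}.env.sum" for k in onehot_cols]

    flags = np.stack([
        env_missing.astype(float), unresolved.astype(float)
    ], axis=1)
    block = np.hstack([windowed, struct_feats, env_real_block,
                       env_onehot_block, flags])
    names = (win_names + struct_names + env_real_names + env_onehot_names
             + ["flag.env_missing", "flag.unresolved"])
    return block, names, graph


@dataclass
class EncodedComplex:
    """A complex with both chains' feature blocks and neighbour graphs."""

    pair: ProteinPair
    contacts: ContactMap | None
    mode: str
    block_a: np.ndarray
    block_b: np.ndarray
    feature_names: list[str]
    graph_a: NeighborGraph | None
    graph_b: NeighborGraph | None

    @property
    def complex_id(self) -> str:
        return self.pair.complex_id

    @property
    def shape(self) -> tuple[int, int]:
        return self.block_a.shape[0], self.block_b.shape[0]

    def swapped(self) -> "EncodedComplex":
        return EncodedComplex(
            pair=self.pair.swapped(),
            contacts=None if self.contacts is None else self.contacts.transposed(),
            mode=self.mode,
            block_a=self.block_b,
            block_b=self.block_a,
            feature_names=self.feature_names,
            graph_a=self.graph_b,
            graph_b=self.graph_a,
        )


def encode_complex(pair: ProteinPair, contacts: ContactMap | None = None,
                   profiles_a: list[ProfileColumn] | None = None,
                   profiles_b: list[ProfileColumn] | None = None,
                   mode: str | None = None,
                   sasa_points: int = 120) -> EncodedComplex:
    """Encode both chains of a complex; profiles default to pseudo-profiles."""
    mode = mode or pair.mode
    block_a, names, graph_a = encode_chain(
        pair, "a", profiles_a, mode, sasa_points=sasa_points)
    block_b, names_b, graph_b = encode_chain(
        pair, "b", profiles_b, mode, sasa_points=sasa_points)
    assert names == names_b
    return EncodedComplex(
        pair=pair, contacts=contacts, mode=mode,
        block_a=block_a, block_b=block_b, feature_names=names,
        graph_a=graph_a, graph_b=graph_b,
    )


def pair_feature_names(block_names: list[str], mode: str) -> list[str]:
    """Names of a concatenated pair vector [first block, second block]."""
    return [f"r1.{n}" for n in block_names] + [f"r2.{n}" for n in block_names]


STEP2_EXTRA_STRUCT = (
    ["step1.score"]
    + [f"step1.envdotj.{s}" for s in ("sum", "mean", "max", "min")]
    + [f"step1.envidot.{s}" for s in ("sum", "mean", "max", "min")]
    + [f"step1.envdotdot.{s}" for s in ("sum", "mean", "max", "min")]
)
STEP2_EXTRA_SEQ = ["step1.score"]


def family_of(name: str) -> str:
    """Feature family of a column name (pools window/env variants)."""
    base = name
    for prefix in ("r1.", "r2."):
        if base.startswith(prefix):
            base = base[len(prefix):]
            break
    return base.split(".", 1)[0]
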