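"""Leave-one-out evaluation, metric suite and partner-specificity test.

Residue-pair predictions are scored with ROC-AUC both averaged over
complexes (unweighted mean over complexes that have at least one contact)
and pooled over all complexes' scores, plus the precision-recall AUC
(step-wise interpolation, which is less forgiving under the extreme
contact/non-contact imbalance).  Binding-site predictions additionally
report MCC, precision, recall, specificity and NPV at the score threshold
maximising the MCC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from Bio import Align

from .encoding import EncodedComplex
from .errors import EmptyInputError, PairsiteError, SingleClassError
from .model import ModelConfig, predict
from .pairs import PairScoreMatrix
from .pipeline import train_pipeline
from .scoring import (
    binding_site_scores,
    max_score_baseline,
    smooth,
)
from .structures import interface_residues


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC-AUC via the Mann-Whitney rank formulation (midranks for ties).

    Used as an independent cross-check of the curve-based ROC-AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("AUC undefined: single-class labels")
    ranks = stats.rankdata(scores)
    return (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """MCC, precision, recall, specificity, NPV from a confusion matrix."""
    tp, fp, tn, fn = (float(v) for v in (tp, fp, tn, fn))
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return {
        "mcc": mcc,
        "precision": tp / (tp + fp) if tp + fp > 0 else 0.0,
        "recall": tp / (tp + fn) if tp + fn > 0 else 0.0,
        "specificity": tn / (tn + fp) if tn + fp > 0 else 0.0,
        "npv": tn / (tn + fn) if tn + fn > 0 else 0.0,
    }


def max_mcc_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, dict[str, float]]:
    """Scan all distinct score values as thresholds (prediction: score >=
    threshold) and return the lowest threshold maximising the MCC together
    with the metrics there."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("threshold metrics need both classes")
    thresholds = np.unique(scores)
    best = (-2.0, None, None)
    for t in thresholds:  # ascending, so ties keep the lowest threshold
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        fn = int(np.sum(~pred & (labels == 1)))
        tn = int(np.sum(~pred & (labels == 0)))
        m = confusion_metrics(tp, fp, tn, fn)
        if m["mcc"] > best[0] + 1e-15:
            best = (m["mcc"], t, m)
    return float(best[1]), best[2]


def metrics(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """ROC-AUC, PR-AUC and max-MCC threshold metrics for one score set."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise SingleClassError("metrics need both classes")
    out = {
        "auc_roc": float(roc_auc_score(labels, scores)),
        "auc_pr": float(average_precision_score(labels, scores)),
    }
    threshold, thr_metrics = max_mcc_threshold(scores, labels)
    out["threshold"] = threshold
    out.update(thr_metrics)
    return out


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both samples have at most 8 observations and no
    ties; otherwise the normal approximation with tie correction.  A
    degenerate zero-variance case (all observations tied) returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EmptyInputError("Mann-Whitney groups must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0
    return float(res.statistic), p


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class ComplexResult:
    complex_id: str
    step1_matrix: PairScoreMatrix
    step2_matrix: PairScoreMatrix
    labels: np.ndarray               # pair labels
    interface_a: np.ndarray
    interface_b: np.ndarray
    site_scores: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)


def loo_cv(encodings: dict[str, EncodedComplex],
           config: ModelConfig | None = None, seed: int = 0,
           ratio: int = 3, progress=None) -> list[ComplexResult]:
    """Leave-one-complex-out cross-validation.

    For every complex, both steps are trained on the sampled pairs of all
    other complexes and the left-out complex is scored over *all* its
    pairs (evaluation is never sampled).  Site scores are computed for the
    rank-based function (raw and smoothed) on both steps' matrices and for
    the max-score baseline on the step-2 matrix.
    """
    if len(encodings) < 2:
        raise PairsiteError("leave-one-out needs at least 2 complexes")
    config = config or ModelConfig()
    results = []
    for cid in sorted(encodings):
        train_enc = {c: e for c, e in encodings.items() if c != cid}
        assert cid not in train_enc
        pipe = train_pipeline(train_enc, config=config, seed=seed,
                              ratio=ratio, fit_calibration=False)
        enc = encodings[cid]
        f2, f1 = predict(enc, pipe.step1, pipe.step2)
        mask_a, mask_b = interface_residues(enc.contacts)
        res = ComplexResult(
            complex_id=cid, step1_matrix=f1, step2_matrix=f2,
            labels=enc.contacts.labels.ravel().astype(int),
            interface_a=mask_a.astype(int), interface_b=mask_b.astype(int),
        )
        for name, matrix in (("step1", f1), ("step2", f2)):
            raw = binding_site_scores(matrix)
            res.site_scores[f"{name}_raw"] = raw
            res.site_scores[f"{name}_smoothed"] = (smooth(raw[0]), smooth(raw[1]))
        res.site_scores["max_baseline"] = max_score_baseline(f2)
        results.append(res)
        if progress is not None:
            progress(cid)
    return results


def _pooled_sites(results: list[ComplexResult], key: str) -> tuple[np.ndarray, np.ndarray]:
    scores = np.concatenate([
        np.concatenate(r.site_scores[key]) for r in results
    ])
    labels = np.concatenate([
        np.concatenate([r.interface_a, r.interface_b]) for r in results
    ])
    return scores, labels


def evaluation_report(results: list[ComplexResult]) -> dict:
    """Aggregate a LOO run into the metric-suite report.

    Averaged AUCs are unweighted means over complexes with at least one
    positive; pooled metrics mix all complexes' scores.  Site threshold
    metrics are reported for the smoothed rank-based scores of the final
    (step-2) matrices.
    """
    report: dict = {"n_complexes": len(results)}
    for step in ("step1", "step2"):
        pair_scores = np.concatenate([
            getattr(r, f"{step}_matrix").scores.ravel() for r in results
        ])
        pair_labels = np.concatenate([r.labels for r in results])
        per_complex = []
        for r in results:
            if 0 < r.labels.sum() < r.labels.size:
                per_complex.append(float(roc_auc_score(
                    r.labels, getattr(r, f"{step}_matrix").scores.ravel())))
        report[f"pair_auc_roc_avg_{step}"] = float(np.mean(per_complex))
        report[f"pair_auc_roc_pooled_{step}"] = float(
            roc_auc_score(pair_labels, pair_scores))
        report[f"pair_auc_pr_pooled_{step}"] = float(
            average_precision_score(pair_labels, pair_scores))
    for key in ("step1_smoothed", "step2_smoothed", "step2_raw", "max_baseline"):
        scores, labels = _pooled_sites(results, key)
        report[f"site_auc_roc_pooled_{key}"] = float(roc_auc_score(labels, scores))
        report[f"site_auc_pr_pooled_{key}"] = float(
            average_precision_score(labels, scores))
    per_site = []
    for r in results:
        lab = np.concatenate([r.interface_a, r.interface_b])
        if 0 < lab.sum() < lab.size:
            per_site.append(float(roc_auc_score(
                lab, np.concatenate(r.site_scores["step2_smoothed"]))))
    report["site_auc_roc_avg_step2_smoothed"] = float(np.mean(per_site))
    scores, labels = _pooled_sites(results, "step2_smoothed")
    threshold, thr = max_mcc_threshold(scores, labels)
    report["site_threshold"] = threshold
    report.update({f"site_{k}": v for k, v in thr.items()})
    return report


def write_report(report: dict, json_path: str, table_path: str | None = None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    if table_path is None:
        return
    cols = [
        ("AUCrocAvg", "pair_auc_roc_avg_step2"),
        ("AUCroc", "pair_auc_roc_pooled_step2"),
        ("AUCpr", "pair_auc_pr_pooled_step2"),
        ("siteAUCrocAvg", "site_auc_roc_avg_step2_smoothed"),
        ("siteAUCroc", "site_auc_roc_pooled_step2_smoothed"),
        ("siteAUCpr", "site_auc_pr_pooled_step2_smoothed"),
        ("MCC", "site_mcc"),
        ("PR", "site_precision"),
        ("RC", "site_recall"),
        ("SPC", "site_specificity"),
        ("NPV", "site_npv"),
    ]
    with open(table_path, "w") as fh:
        fh.write("\t".join(c for c, _ in cols) + "\n")
        fh.write("\t".join(f"{report[k]:.4f}" for _, k in cols) + "\n")


# ---------------------------------------------------------------------------
# Partner specificity
# ---------------------------------------------------------------------------

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.open_gap_score = -10.0
_aligner.extend_gap_score = -0.5
_aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity over the aligned length."""
    seq_a = seq_a.replace("X", "A")
    seq_b = seq_b.replace("X", "A")
    aln = _aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    aligned = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
    return matches / aligned if aligned else 0.0


@dataclass
class ChainPrediction:
    """One chain's per-residue scores + interface labels in one interaction."""

    interaction_id: str
    sequence: str
    scores: np.ndarray
    interface: np.ndarray  # bool


def _map_positions(seq_from: str, seq_to: str) -> dict[int, int]:
    aln = _aligner.align(seq_from.replace("X", "A"), seq_to.replace("X", "A"))[0]
    a, b = str(aln[0]), str(aln[1])
    mapping = {}
    pa = pb = 0
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            mapping[pa] = pb
        if x != "-":
            pa += 1
        if y != "-":
            pb += 1
    return mapping


def partner_specificity_test(predictions: list[ChainPrediction],
                             identity_threshold: float = 0.90) -> tuple[float, float]:
    """Mann-Whitney comparison of specific vs non-specific interface scores.

    Chains are grouped into equivalent proteins by global sequence identity
    above ``identity_threshold``.  For every protein seen in at least two
    interactions, the scores of its own interface residues in a given
    interaction form the specific sample; the scores (in that same
    interaction) of residues that are interface residues only in the
    protein's *other* interactions form the non-specific sample.  Samples
    are pooled over proteins and compared two-sidedly.
    """
    groups: list[list[ChainPrediction]] = []
    for pred in predictions:
        for group in groups:
            if sequence_identity(pred.sequence, group[0].sequence) > identity_threshold:
                group.append(pred)
                break
        else:
            groups.append([pred])
    specific, nonspecific = [], []
    for group in groups:
        if len(group) < 2:
            continue
        for pred in group:
            other_iface = np.zeros(len(pred.sequence), dtype=bool)
            for other in group:
                if other is pred:
                    continue
                mapping = _map_positions(other.sequence, pred.sequence)
                for pos, here in mapping.items():
                    if other.interface[pos]:
                        other_iface[here] = True
            own = pred.interface.astype(bool)
            specific.extend(pred.scores[own])
            nonspecific.extend(pred.scores[other_iface & ~own])
    if not specific or not nonspecific:
        raise EmptyInputError(
            "no shared-protein interface residues to compare")
    return mann_whitney_u(np.array(specific), np.array(nonspecific))
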