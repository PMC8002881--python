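"""Classifier evaluation and degradomics-specific analyses.

Covers the binary-classification statistics used throughout (Matthews
correlation coefficient, F1, precision/recall, ROC/AUC with bootstrap
confidence intervals), extraction of non-tryptic cleavage sites from
peptide evidence, per-window cleavage-density maps, and two-group
comparison by Student's t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .core import (
    AnnotationSource,
    CleavageAnnotation,
    PeptideHit,
    ProteinRecord,
    ValidationError,
    candidate_sites,
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_scores(
        cls, labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
    ) -> "ConfusionCounts":
        labels = np.asarray(labels).astype(bool)
        pred = np.asarray(scores) >= threshold
        return cls(
            tp=int((pred & labels).sum()),
            tn=int((~pred & ~labels).sum()),
            fp=int((pred & ~labels).sum()),
            fn=int((~pred & labels).sum()),
        )


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    ``(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))``, with the
    0/0 convention: if any marginal factor is zero the coefficient is 0.
    """
    if counts.total == 0:
        raise ValidationError("cannot compute MCC of an empty confusion matrix")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def f1(counts: ConfusionCounts) -> float:
    """F1 = 2*TP / (2*TP + FP + FN); defined as 0 when the denominator is 0."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    return 2 * counts.tp / denom if denom else 0.0


def precision(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fp
    return counts.tp / denom if denom else 0.0


def recall(counts: ConfusionCounts) -> float:
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else 0.0


@dataclass(frozen=True)
class RocCurve:
    """ROC points (FPR, TPR) with the thresholds that generate them."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


@dataclass(frozen=True)
class MetricsReport:
    mcc: float
    f1: float
    precision: float
    recall: float
    auc: float
    auc_ci: tuple[float, float]
    n_pos: int
    n_neg: int
    threshold: float = 0.5
    ci_method: str = "bootstrap-percentile"
    ci_seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "mcc": self.mcc,
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "auc": self.auc,
            "auc_ci_low": self.auc_ci[0],
            "auc_ci_high": self.auc_ci[1],
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "threshold": self.threshold,
            "ci_method": self.ci_method,
            "ci_seed": self.ci_seed,
        }


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC via mid-ranks (ties count one half)."""
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    r_pos = ranks[labels == 1].sum()
    return (r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    n_bootstrap: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[RocCurve, float, tuple[float, float]]:
    """ROC curve, trapezoidal AUC, and a bootstrap confidence interval.

    The AUC is the trapezoidal integral of the ROC curve, which equals the
    Mann-Whitney probability that a random positive outscores a random
    negative (ties counting one half).  The CI is a seeded stratified
    bootstrap (positives and negatives resampled separately) using the
    percentile method.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValidationError("roc_auc needs both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    curve = RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)

    rng = np.random.default_rng(seed)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        sp = pos[rng.integers(0, len(pos), len(pos))]
        sn = neg[rng.integers(0, len(neg), len(neg))]
        bs = np.concatenate([sp, sn])
        bl = np.concatenate([np.ones(len(sp), dtype=int), np.zeros(len(sn), dtype=int)])
        boot[b] = _rank_auc(bs, bl)
    alpha = (1.0 - ci_level) / 2.0
    ci = (float(np.quantile(boot, alpha)), float(np.quantile(boot, 1.0 - alpha)))
    return curve, auc, ci


def write_roc_table(curve: RocCurve, path) -> None:
    """Write ROC points (fpr, tpr, threshold) as a TSV for plotting."""
    pd.DataFrame(
        {"fpr": curve.fpr, "tpr": curve.tpr, "threshold": curve.thresholds}
    ).to_csv(path, sep="\t", index=False)


def read_roc_table(path) -> RocCurve:
    df = pd.read_csv(path, sep="\t")
    return RocCurve(
        fpr=df["fpr"].to_numpy(),
        tpr=df["tpr"].to_numpy(),
        thresholds=df["threshold"].to_numpy(),
    )


def nontryptic_sites(
    peptide_hits: Iterable[PeptideHit],
    proteins: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
) -> tuple[list[CleavageAnnotation], list[tuple[PeptideHit, str]]]:
    """Extract non-tryptic cleavage sites from peptide termini.

    For each peptide located (uniquely) in its protein, both boundaries
    are examined.  A boundary at position ``j`` (the bond between residues
    ``j`` and ``j+1``) is *tryptic* when residue ``j`` is Lys/Arg and
    residue ``j+1`` is not Pro; any other internal boundary is evidence of
    another protease and is emitted as a cleavage site with P1 = ``j``.
    Protein termini are never sites.  Peptides that do not map, or map to
    multiple positions, are skipped and reported.

    Returns ``(annotations, skipped)`` where ``skipped`` pairs each
    unusable hit with a reason.
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.id: p for p in proteins}
    found: set[tuple[str, int]] = set()
    skipped: list[tuple[PeptideHit, str]] = []
    for hit in peptide_hits:
        protein = proteins.get(hit.protein_id)
        if protein is None:
            skipped.append((hit, "unknown protein"))
            continue
        seq = protein.sequence
        n_matches = seq.count(hit.peptide)
        if n_matches == 0:
            skipped.append((hit, "peptide not found in protein"))
            continue
        if n_matches > 1:
            skipped.append((hit, f"ambiguous: {n_matches} matches"))
            continue
        start = seq.find(hit.peptide)  # 0-based
        L = protein.length
        # N-terminal boundary: bond between residues `start` and `start+1`.
        j = start
        if j >= 1 and not _is_tryptic_bond(seq, j):
            found.add((protein.id, j))
        # C-terminal boundary: bond after the last peptide residue.
        e = start + len(hit.peptide)
        if e <= L - 1 and not _is_tryptic_bond(seq, e):
            found.add((protein.id, e))
    annotations = [
        CleavageAnnotation(
            protease="nontryptic",
            protein_id=pid,
            p1=p1,
            source=AnnotationSource.EXPERIMENT,
        )
        for pid, p1 in sorted(found)
    ]
    return annotations, skipped


def _is_tryptic_bond(seq: str, p1: int) -> bool:
    """Is the bond after 1-based residue ``p1`` explained by trypsin?"""
    return seq[p1 - 1] in "KR" and seq[p1] != "P"


def cleavage_density(
    annotations: Iterable[CleavageAnnotation],
    protein: ProteinRecord,
    window: int = 50,
) -> list[int]:
    """Sites per ``window``-residue bin along the protein (default 50).

    Bin ``b`` counts sites with ``p1`` in ``[b*window + 1, (b+1)*window]``;
    the last bin is truncated at ``L - 1``.
    """
    if window < 1:
        raise ValidationError("window must be >= 1")
    L = protein.length
    n_bins = max(1, math.ceil((L - 1) / window)) if L > 1 else 1
    bins = [0] * n_bins
    for a in annotations:
        if a.protein_id != protein.id:
            continue
        if 1 <= a.p1 <= L - 1:
            bins[(a.p1 - 1) // window] += 1
    return bins


def evaluate_predictor(
    score_table: pd.DataFrame,
    truth_annotations: Iterable[CleavageAnnotation],
    proteins: Mapping[str, ProteinRecord] | Sequence[ProteinRecord],
    protease: str,
    threshold: float = 0.5,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> MetricsReport:
    """Score any predictor's TSV output against truth annotations.

    The score table has columns protein_id / p1 / score and may come from
    this package's models or from external predictors.  Labels are taken
    from the truth annotations over *all* candidate sites of the given
    proteins; candidates missing from the score table are scored 0 with a
    warning.  MCC/F1/precision/recall are reported at ``threshold``
    (default 0.5) alongside AUC and its bootstrap CI.
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.id: p for p in proteins}
    positives = {
        (a.protein_id, a.p1)
        for a in truth_annotations
        if a.protease == protease and a.protein_id in proteins
    }
    if not positives:
        raise ValidationError(f"no truth positives for protease '{protease}'")
    score_map = {
        (str(r.protein_id), int(r.p1)): float(r.score)
        for r in score_table.itertuples(index=False)
    }
    labels, scores = [], []
    n_missing = 0
    for pid in sorted(proteins):
        for p1 in candidate_sites(proteins[pid]):
            labels.append(1 if (pid, p1) in positives else 0)
            s = score_map.get((pid, p1))
            if s is None:
                n_missing += 1
                s = 0.0
            scores.append(s)
    if n_missing:
        warnings.warn(
            f"{n_missing} candidate sites missing from score table; scored 0",
            stacklevel=2,
        )
    labels_arr = np.asarray(labels)
    scores_arr = np.asarray(scores)
    if labels_arr.sum() == len(labels_arr):
        raise ValidationError("truth contains no negatives")
    counts = ConfusionCounts.from_scores(labels_arr, scores_arr, threshold)
    _, auc, ci = roc_auc(scores_arr, labels_arr, n_bootstrap=n_bootstrap, seed=seed)
    return MetricsReport(
        mcc=mcc(counts),
        f1=f1(counts),
        precision=precision(counts),
        recall=recall(counts),
        auc=auc,
        auc_ci=ci,
        n_pos=int(labels_arr.sum()),
        n_neg=int(len(labels_arr) - labels_arr.sum()),
        threshold=threshold,
        ci_seed=seed,
    )


def compare_groups(values_a: Sequence[float], values_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t-test between two groups."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValidationError("zero pooled variance: t statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)
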