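"""Cross-validation harness: global/local LOOCV, repeated k-fold, ROC/AUC.

Protocol
--------
Every known association is (alone, or as part of a fold) removed from the
association matrix, the scoring pipeline is rerun on the masked matrix,
and the held-out pair's score is recorded. Negatives — pairs never known
to be associated — are scored once from the full-data run. *Global*
evaluation ranks each held-out positive against all unknown pairs;
*local* evaluation ranks it only against the unknown pairs of its own
disease (a strictly harder task).

By default the whole pipeline, sparse reconstruction included, is rerun
per fold, which is the only fully leakage-free protocol. ``fast=True``
reconstructs and fuses the similarities once from the full data and only
redoes the propagation per fold; the held-out edge then still influences
the similarity graphs, so fast-mode AUCs are mildly optimistic — use it
for large fold counts, and the default for final numbers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .matrices import AssociationMatrix, SimilarityMatrix
from .pipeline import fused_similarities, run_pipeline
from .propagate import PropagationConfig, normalize_similarity, propagation_kernel
from .sparse import SparseConfig

log = logging.getLogger(__name__)

#: a scorer maps a (possibly masked) association matrix to miRNA x disease scores
Scorer = Callable[[AssociationMatrix], np.ndarray]


@dataclass(frozen=True)
class CVResult:
    auc: float
    roc: list[tuple[float, float]]
    mode: str
    reps: int
    per_rep_auc: list[float]
    seed: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, list[tuple[float, float]]]:
    """AUC via the Mann-Whitney rank statistic plus the tie-aware ROC curve.

    Average ranks are assigned to ties, making the rank AUC identical to
    trapezoidal integration of the ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and of equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(auc), list(zip(fpr.tolist(), tpr.tolist()))


def degree_distribution(
    A: AssociationMatrix,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Histograms of disease degrees (row sums) and miRNA degrees (column sums)."""
    def hist(degrees: np.ndarray) -> list[tuple[int, int]]:
        vals, counts = np.unique(degrees, return_counts=True)
        return [(int(v), int(c)) for v, c in zip(vals, counts)]

    return hist(A.values.sum(axis=1)), hist(A.values.sum(axis=0))


def make_snmda_scorer(
    mfs: SimilarityMatrix,
    dss: SimilarityMatrix,
    sparse_cfg: SparseConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    fast: bool = False,
    A_full: AssociationMatrix | None = None,
) -> Scorer:
    """Scorer running the pipeline on each masked matrix it is given.

    With ``fast=True`` (requires ``A_full``) the similarity graphs and the
    closed-form propagation kernels are built once from the full data;
    each fold is then two matrix products.
    """
    sparse_cfg = sparse_cfg or SparseConfig()
    prop_cfg = prop_cfg or PropagationConfig()
    if not fast:
        def scorer(A: AssociationMatrix) -> np.ndarray:
            return run_pipeline(A, mfs, dss, sparse_cfg, prop_cfg).values

        return scorer
    if A_full is None:
        raise ValueError("fast mode needs the full association matrix")
    fms, fds = fused_similarities(A_full, mfs, dss, sparse_cfg)
    K_M = propagation_kernel(normalize_similarity(fms), prop_cfg.alpha)
    K_D = propagation_kernel(normalize_similarity(fds), prop_cfg.alpha)
    beta = prop_cfg.beta

    def fast_scorer(A: AssociationMatrix) -> np.ndarray:
        Y = A.values.T.astype(float)
        return beta * (K_M @ Y) + (1.0 - beta) * (K_D @ A.values.astype(float)).T

    return fast_scorer


def uniform_random_scorer(seed: int) -> Scorer:
    """Baseline scorer: i.i.d. uniform scores, ignoring the associations."""
    rng = np.random.default_rng(seed)

    def scorer(A: AssociationMatrix) -> np.ndarray:
        return rng.uniform(size=(A.n_mirnas, A.n_diseases))

    return scorer


def _resolve_scorer(
    A: AssociationMatrix,
    mfs: SimilarityMatrix | None,
    dss: SimilarityMatrix | None,
    sparse_cfg: SparseConfig | None,
    prop_cfg: PropagationConfig | None,
    fast: bool,
    scorer: Scorer | None,
) -> Scorer:
    if scorer is not None:
        return scorer
    if mfs is None or dss is None:
        raise ValueError("either a scorer or both prior similarity matrices are required")
    return make_snmda_scorer(mfs, dss, sparse_cfg, prop_cfg, fast=fast, A_full=A)


def _holdout_scores(
    A: AssociationMatrix, scorer: Scorer
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Leave-one-out scores: full-data score matrix, the positive pairs and
    each positive's score from its own holdout run."""
    positives = A.known_pairs()
    if len(positives) < 2:
        raise ValueError("leave-one-out needs at least 2 known associations")
    F_full = scorer(A)
    pos_scores = np.empty(len(positives))
    for k, (d, m) in enumerate(positives):
        F_mask = scorer(A.with_masked(np.array([[d, m]])))
        pos_scores[k] = F_mask[m, d]
    return F_full, positives, pos_scores


def global_loocv(
    A: AssociationMatrix,
    mfs: SimilarityMatrix | None = None,
    dss: SimilarityMatrix | None = None,
    sparse_cfg: SparseConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    fast: bool = False,
    scorer: Scorer | None = None,
    seed: int = 0,
) -> CVResult:
    """Each known pair held out in turn and ranked against every unknown pair."""
    scorer = _resolve_scorer(A, mfs, dss, sparse_cfg, prop_cfg, fast, scorer)
    F_full, _, pos_scores = _holdout_scores(A, scorer)
    neg_mask = A.values == 0
    neg_scores = F_full.T[neg_mask]
    scores = np.concatenate([pos_scores, neg_scores])
    labels = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
    auc, roc = roc_auc(scores, labels)
    return CVResult(auc, roc, "global_loocv", 1, [auc], seed)


def local_loocv(
    A: AssociationMatrix,
    mfs: SimilarityMatrix | None = None,
    dss: SimilarityMatrix | None = None,
    sparse_cfg: SparseConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    fast: bool = False,
    scorer: Scorer | None = None,
    seed: int = 0,
) -> CVResult:
    """Each held-out pair ranked only within its own disease's unknown pairs.

    Each positive contributes the fraction of its disease's unknown pairs
    it outranks (ties count half); the AUC pools these per-disease
    outcomes by averaging, and the ROC is the curve of "fraction of
    positives recovered" against the per-disease rank-fraction threshold.
    """
    scorer = _resolve_scorer(A, mfs, dss, sparse_cfg, prop_cfg, fast, scorer)
    F_full, positives, pos_scores = _holdout_scores(A, scorer)
    percentiles = []
    for (d, m), s in zip(positives, pos_scores):
        unknown = np.flatnonzero(A.values[d] == 0)
        if unknown.size == 0:
            log.warning(
                "disease %r has no unknown pairs; skipped in local LOOCV",
                A.disease_index[d],
            )
            continue
        neg = F_full[unknown, d]
        wins = (neg < s).sum() + 0.5 * (neg == s).sum()
        percentiles.append(wins / unknown.size)
    if not percentiles:
        raise ValueError("no disease with unknown pairs; local LOOCV undefined")
    percentiles = np.asarray(percentiles)
    auc = float(percentiles.mean())
    xs = np.sort(1.0 - percentiles)
    n = len(xs)
    roc = [(0.0, 0.0)] + [(float(x), (i + 1) / n) for i, x in enumerate(xs)] + [(1.0, 1.0)]
    return CVResult(auc, roc, "local_loocv", 1, [auc], seed)


def kfold_cv(
    A: AssociationMatrix,
    mfs: SimilarityMatrix | None = None,
    dss: SimilarityMatrix | None = None,
    sparse_cfg: SparseConfig | None = None,
    prop_cfg: PropagationConfig | None = None,
    k: int = 5,
    reps: int = 20,
    seed: int = 0,
    fast: bool = False,
    scorer: Scorer | None = None,
) -> CVResult:
    """Repeated k-fold CV over the known pairs; final AUC = mean over reps.

    The known pairs are split into k disjoint folds uniformly at random
    (no stratification); each fold is masked in turn, the pipeline rerun,
    and the masked pairs ranked against the unknown pairs of the full
    data. ``reps=1, k = number of positives`` degenerates to global LOOCV.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    scorer = _resolve_scorer(A, mfs, dss, sparse_cfg, prop_cfg, fast, scorer)
    positives = A.known_pairs()
    if len(positives) < k:
        raise ValueError(f"need at least k={k} known associations, have {len(positives)}")
    F_full = scorer(A)
    neg_scores = F_full.T[A.values == 0]
    rng = np.random.default_rng(seed)
    per_rep_auc: list[float] = []
    pooled_pos: list[np.ndarray] = []
    for _ in range(reps):
        perm = rng.permutation(len(positives))
        pos_scores = np.empty(len(positives))
        for fold in np.array_split(perm, k):
            pairs = positives[fold]
            F_mask = scorer(A.with_masked(pairs))
            pos_scores[fold] = F_mask[pairs[:, 1], pairs[:, 0]]
        scores = np.concatenate([pos_scores, neg_scores])
        labels = np.concatenate([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
        auc, _ = roc_auc(scores, labels)
        per_rep_auc.append(auc)
        pooled_pos.append(pos_scores)
    all_pos = np.concatenate(pooled_pos)
    pooled_scores = np.concatenate([all_pos, neg_scores])
    pooled_labels = np.concatenate([np.ones(len(all_pos)), np.zeros(len(neg_scores))])
    _, roc = roc_auc(pooled_scores, pooled_labels)
    return CVResult(float(np.mean(per_rep_auc)), roc, "kfold", reps, per_rep_auc, seed)
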