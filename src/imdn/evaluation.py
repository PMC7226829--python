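"""Leave-one-out cross-validation, ranking metrics and candidate reports.

Two LOOCV protocols are supported.  *Global* LOOCV holds out each known
miRNA-disease association in turn and ranks it against every unknown pair in
the whole matrix; *local* LOOCV ranks each held-out association only against
the unknown miRNAs of the same disease, then averages per-disease AUCs.
Both can either retrain the model for every fold (faithful but quadratic in
the number of positives) or train once per repeat and rank all positives
against the unknowns without refitting (``fast=True``; an approximation that
leaves each positive in its own training set).

AUC is the rank statistic: the probability that a random positive outscores
a random negative, ties counted one half (Mann-Whitney mid-rank).  AUPRC
uses the step-wise rectangular rule over descending unique score thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.stats import rankdata

from .data_io import AssociationMatrix, WeightMatrix, normalize_id
from .model import LatentModel, ModelConfig, fit, predict_scores

logger = logging.getLogger(__name__)

__all__ = [
    "EvalResult",
    "AblationResult",
    "roc_auc",
    "pr_auc",
    "global_loocv",
    "local_loocv",
    "ablation_network",
    "top_k_candidates",
]

#: a scorer maps a training R (held-out entries zeroed) to a full score matrix
Scorer = Callable[[np.ndarray], np.ndarray]


@dataclass
class EvalResult:
    """Aggregate LOOCV outcome.

    ``per_fold`` holds one record per held-out positive (of the last repeat):
    the pair of IDs, its mid-rank among the candidates, and the candidate-set
    size (held-out pair plus negatives).
    """

    protocol: Literal["global_loocv", "local_loocv"]
    per_fold: list[tuple[tuple[str, str], float, int]]
    auc: float
    auprc: float
    n_repeats: int
    per_repeat_auc: list[float] = field(default_factory=list)


@dataclass
class AblationResult:
    """With- vs without-network comparison under identical seeds."""

    with_network: EvalResult
    without_network: EvalResult

    @property
    def auc_difference(self) -> float:
        return self.with_network.auc - self.without_network.auc


# ---------------------------------------------------------------------------
# ranking metrics
# ---------------------------------------------------------------------------


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based area under the ROC curve (Mann-Whitney statistic).

    Equals the probability that a uniformly drawn positive outranks a
    uniformly drawn negative, ties counted 1/2 — identical to sweeping a
    threshold over sensitivity and specificity and integrating.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires at least one positive and one negative")
    ranks = rankdata(scores)  # average ranks handle ties
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def pr_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve, rectangular rule.

    Thresholds sweep the unique scores in descending order; each threshold
    contributes (recall step) x (precision at that threshold).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("pr_auc requires at least one positive")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = (labels[order] == 1).astype(float)
    tp = np.cumsum(sorted_labels)
    fp = np.cumsum(1.0 - sorted_labels)
    # keep only the last index of each tied block of scores
    is_last = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tp, fp = tp[is_last], fp[is_last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    recall_steps = np.diff(np.r_[0.0, recall])
    return float((recall_steps * precision).sum())


def _fold_rank_auc(pos_score: float, neg_scores: np.ndarray) -> tuple[float, float]:
    """Mid-rank of the positive among {positive} + negatives, and fold AUC."""
    greater = int((neg_scores > pos_score).sum())
    ties = int((neg_scores == pos_score).sum())
    rank = 1.0 + greater + 0.5 * ties
    auc = ((len(neg_scores) - greater) - 0.5 * ties) / len(neg_scores)
    return rank, auc


# ---------------------------------------------------------------------------
# LOOCV protocols
# ---------------------------------------------------------------------------


def _fold_weights(weights: WeightMatrix, u: int, i: int) -> np.ndarray:
    """Weights with the held-out cell demoted to its expression-derived value."""
    W = weights.W.copy()
    W[u, i] = weights.background[u, i] if weights.background is not None else 1.0
    return W


def _score_matrix(
    R_train: np.ndarray,
    weights: WeightMatrix,
    W_train: np.ndarray,
    S_norm: np.ndarray | None,
    config: ModelConfig,
    scorer: Scorer | None,
) -> np.ndarray:
    if scorer is not None:
        return np.asarray(scorer(R_train), dtype=float)
    model = fit(R_train, W_train, S_norm, config)
    if not np.isfinite(model.loss_history[-1]):
        raise RuntimeError("fold training diverged")
    return predict_scores(model)


def global_loocv(
    assoc: AssociationMatrix,
    weights: WeightMatrix,
    simnet,
    config: ModelConfig,
    n_repeats: int = 1,
    fast: bool = False,
    scorer: Scorer | None = None,
) -> EvalResult:
    """Hold out each known association and rank it against all unknown pairs.

    Candidates are every cell with R == 0, over all diseases simultaneously.
    Repeats re-randomize the model initialization (folds are exhaustive by
    construction) and the per-repeat AUCs are averaged.  ``scorer`` replaces
    model training with an arbitrary score function (used for calibration
    checks with oracle or random scorers).
    """
    R = assoc.R
    positives = assoc.positive_pairs()
    if len(positives) < 2:
        raise ValueError("global LOOCV needs at least two known associations")
    S_norm = simnet.values if simnet is not None else None
    neg_mask = R == 0

    per_repeat_auc: list[float] = []
    per_repeat_auprc: list[float] = []
    per_fold: list[tuple[tuple[str, str], float, int]] = []
    for rep in range(n_repeats):
        rep_config = config.replace(seed=config.seed + rep)
        per_fold = []
        fold_aucs = []
        pos_scores = []
        neg_scores_accum = np.zeros(int(neg_mask.sum()))
        if fast:
            scores = _score_matrix(R, weights, weights.W, S_norm, rep_config, scorer)
        for u, i in positives:
            if fast:
                fold_scores = scores
            else:
                R_train = R.copy()
                R_train[u, i] = 0.0
                fold_scores = _score_matrix(
                    R_train, weights, _fold_weights(weights, u, i),
                    S_norm, rep_config, scorer,
                )
            negs = fold_scores[neg_mask]
            rank, auc = _fold_rank_auc(fold_scores[u, i], negs)
            fold_aucs.append(auc)
            pos_scores.append(fold_scores[u, i])
            neg_scores_accum += negs
            per_fold.append(
                ((assoc.mirna_ids[u], assoc.disease_ids[i]), rank, len(negs) + 1)
            )
        per_repeat_auc.append(float(np.mean(fold_aucs)))
        pooled_scores = np.r_[pos_scores, neg_scores_accum / len(positives)]
        pooled_labels = np.r_[
            np.ones(len(pos_scores)), np.zeros(len(neg_scores_accum))
        ]
        per_repeat_auprc.append(pr_auc(pooled_scores, pooled_labels))

    return EvalResult(
        protocol="global_loocv",
        per_fold=per_fold,
        auc=float(np.mean(per_repeat_auc)),
        auprc=float(np.mean(per_repeat_auprc)),
        n_repeats=n_repeats,
        per_repeat_auc=per_repeat_auc,
    )


def local_loocv(
    assoc: AssociationMatrix,
    weights: WeightMatrix,
    simnet,
    config: ModelConfig,
    n_repeats: int = 1,
    fast: bool = False,
    scorer: Scorer | None = None,
) -> EvalResult:
    """Per-disease LOOCV: rank each held-out miRNA among that disease's unknowns.

    Diseases without both a positive and a negative miRNA are skipped with a
    warning; per-disease AUCs are combined by unweighted mean, then averaged
    over repeats.
    """
    R = assoc.R
    S_norm = simnet.values if simnet is not None else None

    evaluable = []
    for i in range(assoc.n_diseases):
        col = R[:, i]
        if col.sum() == 0:
            continue
        if (col == 0).sum() == 0:
            logger.warning(
                "disease %s has no negative miRNAs; skipped in local LOOCV",
                assoc.disease_ids[i],
            )
            continue
        evaluable.append(i)
    if not evaluable:
        raise ValueError("no disease has both positive and negative miRNAs")

    per_repeat_auc: list[float] = []
    per_repeat_auprc: list[float] = []
    per_fold: list[tuple[tuple[str, str], float, int]] = []
    for rep in range(n_repeats):
        rep_config = config.replace(seed=config.seed + rep)
        per_fold = []
        disease_aucs = []
        pooled_scores: list[np.ndarray] = []
        pooled_labels: list[np.ndarray] = []
        if fast:
            scores = _score_matrix(R, weights, weights.W, S_norm, rep_config, scorer)
        for i in evaluable:
            neg_rows = np.flatnonzero(R[:, i] == 0)
            fold_aucs = []
            for u in np.flatnonzero(R[:, i] == 1):
                if fast:
                    fold_scores = scores
                else:
                    R_train = R.copy()
                    R_train[u, i] = 0.0
                    fold_scores = _score_matrix(
                        R_train, weights, _fold_weights(weights, u, i),
                        S_norm, rep_config, scorer,
                    )
                negs = fold_scores[neg_rows, i]
                rank, auc = _fold_rank_auc(fold_scores[u, i], negs)
                fold_aucs.append(auc)
                pooled_scores.append(np.r_[fold_scores[u, i], negs])
                pooled_labels.append(np.r_[1.0, np.zeros(len(negs))])
                per_fold.append(
                    ((assoc.mirna_ids[u], assoc.disease_ids[i]), rank, len(negs) + 1)
                )
            disease_aucs.append(float(np.mean(fold_aucs)))
        per_repeat_auc.append(float(np.mean(disease_aucs)))
        per_repeat_auprc.append(
            pr_auc(np.concatenate(pooled_scores), np.concatenate(pooled_labels))
        )

    return EvalResult(
        protocol="local_loocv",
        per_fold=per_fold,
        auc=float(np.mean(per_repeat_auc)),
        auprc=float(np.mean(per_repeat_auprc)),
        n_repeats=n_repeats,
        per_repeat_auc=per_repeat_auc,
    )


def ablation_network(
    assoc: AssociationMatrix,
    weights: WeightMatrix,
    simnet,
    config: ModelConfig,
    protocol: Literal["global", "local"] = "global",
    n_repeats: int = 1,
    fast: bool = False,
) -> AblationResult:
    """Run the chosen protocol with the network term on and off.

    Both runs share seeds, so with ``lambda_s == 0`` in the input config the
    two results are identical and the difference is exactly zero.
    """
    run = global_loocv if protocol == "global" else local_loocv
    with_net = run(assoc, weights, simnet, config, n_repeats=n_repeats, fast=fast)
    without = run(
        assoc, weights, simnet, config.replace(lambda_s=0.0),
        n_repeats=n_repeats, fast=fast,
    )
    return AblationResult(with_network=with_net, without_network=without)


def top_k_candidates(
    model: LatentModel,
    assoc: AssociationMatrix,
    disease_id: str,
    k: int,
) -> list[tuple[str, float]]:
    """The k highest-scoring miRNAs not yet associated with the disease.

    Descending score; ties broken by lexicographic miRNA ID.
    """
    disease_id = normalize_id(disease_id)
    if disease_id not in assoc.disease_ids:
        raise KeyError(f"unknown disease {disease_id!r}")
    i = assoc.disease_ids.index(disease_id)
    candidates = np.flatnonzero(assoc.R[:, i] == 0)
    if k > len(candidates):
        raise ValueError(
            f"k={k} exceeds the {len(candidates)} non-associated miRNAs"
        )
    scores = predict_scores(model)[:, i]
    ranked = sorted(
        ((assoc.mirna_ids[u], float(scores[u])) for u in candidates),
        key=lambda t: (-t[1], t[0]),
    )
    return ranked[:k]
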