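"""Cross-validation protocols, ROC/AUC, parameter sweeps and case studies.

Three protocols mirror how interaction-profile link predictors are usually
benchmarked:

* **Global LOOCV** — each known association is removed in turn, the model is
  retrained (similarities recomputed from the reduced matrix), and the held
  out pair is ranked against every pair that was never associated.
* **Repeated k-fold CV** — the known associations are shuffled into k folds;
  each fold is zeroed, the model retrained, and one ROC/AUC computed with the
  fold's pairs as positives and the originally unassociated pairs as
  negatives; repeated with fresh shuffles and summarized as mean +- std.
* **Case study** — one disease's entire row is zeroed before training and
  its candidate microbes are ranked.

AUC uses the rank statistic (Mann-Whitney with midranks for ties), which
equals the trapezoidal area under the threshold-swept ROC curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Literal, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .data_model import AssociationDataset
from .kron_rls import ModelParams, predict

logger = logging.getLogger(__name__)

__all__ = [
    "CVResult",
    "SweepResult",
    "fold_split",
    "rank_auc",
    "roc_auc",
    "global_loocv",
    "kfold_cv",
    "case_study_rank",
    "parameter_sweep",
]


@dataclass(frozen=True)
class CVResult:
    """AUC summary of one evaluation protocol.

    ``auc_std`` is populated only by repeated CV; ``per_round_ranks`` holds
    ``((disease_idx, microbe_idx), rank, candidate_count)`` triples for
    leave-one-out rounds.
    """

    auc: float
    auc_std: float | None = None
    roc_points: np.ndarray | None = field(default=None, repr=False)
    per_round_ranks: list[tuple[tuple[int, int], int, int]] | None = None


@dataclass(frozen=True)
class SweepResult:
    """AUC per grid point for the coupled-sigma sweep and the w sweep."""

    protocol: str
    sigma_grid: tuple[float, ...]
    sigma_auc: tuple[float, ...]
    w_grid: tuple[float, ...]
    w_auc: tuple[float, ...]
    best_sigma: float

    def write_tsv(self, stream: IO[str]) -> None:
        stream.write("parameter\tvalue\tauc\tprotocol\n")
        for s, a in zip(self.sigma_grid, self.sigma_auc):
            stream.write(f"sigma\t{s:g}\t{a:.6f}\t{self.protocol}\n")
        for w, a in zip(self.w_grid, self.w_auc):
            stream.write(f"w\t{w:g}\t{a:.6f}\t{self.protocol}\n")


def fold_split(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Shuffle ``range(n)`` with the given seed and split into k near-equal folds."""
    order = np.random.default_rng(seed).permutation(n)
    return np.array_split(order, k)


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with midrank tie handling."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one positive and one negative")
    ranks = rankdata(scores, method="average")
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> CVResult:
    """ROC curve (unique-threshold sweep) plus the rank-statistic AUC."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    auc = rank_auc(scores, labels)
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return CVResult(auc=auc, roc_points=np.column_stack([fpr, tpr]))


def global_loocv(
    dataset: AssociationDataset,
    params: ModelParams = ModelParams(),
    aggregation: Literal["mean-rank", "pooled"] = "mean-rank",
) -> CVResult:
    """Leave-one-association-out cross-validation.

    Per round the held-out pair's score is compared against all *candidate*
    pairs (zero in the original matrix; their scores move between rounds, so
    they are recomputed every time).  ``mean-rank`` averages the per-round
    normalized rank statistic — one AUC per round against the candidate set —
    while ``pooled`` stacks every round's (test, candidates) scores into a
    single ROC.
    """
    positives = dataset.positives()
    if not positives:
        raise ValueError("global LOOCV needs at least one known association")
    candidate_mask = np.asarray(dataset.A) == 0
    round_aucs: list[float] = []
    per_round_ranks: list[tuple[tuple[int, int], int, int]] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for i, j in positives:
        A_train = np.array(dataset.A)
        A_train[i, j] = 0
        F = predict(dataset.with_matrix(A_train), params).values
        test_score = F[i, j]
        candidates = F[candidate_mask]
        below = int(np.sum(candidates < test_score))
        tied = int(np.sum(candidates == test_score))
        round_aucs.append((below + 0.5 * tied) / candidates.size)
        per_round_ranks.append(
            ((i, j), candidates.size - below - tied + 1, candidates.size)
        )
        pooled_scores.append(np.concatenate([[test_score], candidates]))
        pooled_labels.append(
            np.concatenate([[1], np.zeros(candidates.size, dtype=int)])
        )
    all_scores = np.concatenate(pooled_scores)
    all_labels = np.concatenate(pooled_labels)
    fpr, tpr, _ = roc_curve(all_labels, all_scores, drop_intermediate=True)
    if aggregation == "mean-rank":
        auc = float(np.mean(round_aucs))
    elif aggregation == "pooled":
        auc = rank_auc(all_scores, all_labels)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    logger.info("global LOOCV (%s): %d rounds, AUC = %.4f", aggregation, len(positives), auc)
    return CVResult(
        auc=auc,
        roc_points=np.column_stack([fpr, tpr]),
        per_round_ranks=per_round_ranks,
    )


def kfold_cv(
    dataset: AssociationDataset,
    params: ModelParams = ModelParams(),
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
) -> CVResult:
    """Repeated k-fold cross-validation over the known associations.

    Each repeat shuffles the positives with sub-seed ``seed + repeat`` and
    splits them into k near-equal folds.  Negatives in every fold's ROC are
    all pairs that are zero in the *original* matrix, so held-out positives
    never count as negatives.  Reported as mean +- sample std over repeats.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    positives = np.array(dataset.positives())
    if len(positives) < k:
        raise ValueError(f"need at least k={k} known associations, have {len(positives)}")
    neg_mask = np.asarray(dataset.A) == 0
    repeat_aucs = []
    roc_points = None
    for r in range(repeats):
        fold_aucs = []
        rep_scores: list[np.ndarray] = []
        rep_labels: list[np.ndarray] = []
        for fold_idx in fold_split(len(positives), k, seed + r):
            fold = positives[fold_idx]
            A_train = np.array(dataset.A)
            A_train[fold[:, 0], fold[:, 1]] = 0
            F = predict(dataset.with_matrix(A_train), params).values
            pos_scores = F[fold[:, 0], fold[:, 1]]
            neg_scores = F[neg_mask]
            scores = np.concatenate([pos_scores, neg_scores])
            labels = np.concatenate(
                [np.ones(pos_scores.size, dtype=int), np.zeros(neg_scores.size, dtype=int)]
            )
            fold_aucs.append(rank_auc(scores, labels))
            if r == 0:
                rep_scores.append(scores)
                rep_labels.append(labels)
        repeat_aucs.append(float(np.mean(fold_aucs)))
        if r == 0:
            fpr, tpr, _ = roc_curve(
                np.concatenate(rep_labels), np.concatenate(rep_scores),
                drop_intermediate=True,
            )
            roc_points = np.column_stack([fpr, tpr])
    auc = float(np.mean(repeat_aucs))
    std = float(np.std(repeat_aucs, ddof=1)) if repeats > 1 else 0.0
    logger.info("%d-fold CV x %d repeats: AUC = %.4f +- %.4f", k, repeats, auc, std)
    return CVResult(auc=auc, auc_std=std, roc_points=roc_points)


def case_study_rank(
    dataset: AssociationDataset,
    disease_id: str,
    params: ModelParams = ModelParams(),
    top_n: int = 20,
) -> list[tuple[int, str, float]]:
    """Rank candidate microbes for one disease with its row blinded.

    The disease's known associations are all zeroed before training, so the
    ranking reflects only what the rest of the network implies.  Returns
    ``(rank, microbe_id, score)`` triples, competition-ranked, ties broken by
    microbe identifier.
    """
    try:
        row = dataset.disease_ids.index(disease_id)
    except ValueError:
        raise KeyError(f"unknown disease identifier {disease_id!r}") from None
    A_train = np.array(dataset.A)
    A_train[row, :] = 0
    F = predict(dataset.with_matrix(A_train), params).values
    scores = F[row]
    order = sorted(range(dataset.nm), key=lambda j: (-scores[j], dataset.microbe_ids[j]))
    results = []
    for j in order[:top_n]:
        rank = int(np.sum(scores > scores[j])) + 1
        results.append((rank, dataset.microbe_ids[j], float(scores[j])))
    return results


def parameter_sweep(
    dataset: AssociationDataset,
    sigma_grid: Sequence[float],
    w_grid: Sequence[float],
    params: ModelParams = ModelParams(),
    protocol: Literal["loocv", "kfold"] = "kfold",
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
) -> SweepResult:
    """Sensitivity sweep: coupled sigma_G = sigma_H first, then w at the best sigma."""
    if not sigma_grid or not w_grid:
        raise ValueError("sigma_grid and w_grid must be nonempty")

    def run(p: ModelParams) -> float:
        if protocol == "loocv":
            return global_loocv(dataset, p).auc
        if protocol == "kfold":
            return kfold_cv(dataset, p, k=k, repeats=repeats, seed=seed).auc
        raise ValueError(f"unknown protocol {protocol!r}")

    sigma_auc = [run(params.with_sigma(s)) for s in sigma_grid]
    best_sigma = sigma_grid[int(np.argmax(sigma_auc))]
    base = params.with_sigma(best_sigma)
    from dataclasses import replace

    w_auc = [run(replace(base, w=w)) for w in w_grid]
    return SweepResult(
        protocol=protocol,
        sigma_grid=tuple(float(s) for s in sigma_grid),
        sigma_auc=tuple(sigma_auc),
        w_grid=tuple(float(w) for w in w_grid),
        w_auc=tuple(w_auc),
        best_sigma=float(best_sigma),
    )
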