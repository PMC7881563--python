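"""Synthetic bipartite association networks with planted block structure.

Both similarity measures used by the predictor are interaction-profile
based, so the natural testbed is a bipartite stochastic block model:
diseases and microbes are assigned to latent blocks and associate with
probability ``p_in`` inside a shared block and ``p_out`` otherwise.
Co-association blocks are exactly the "similar entities share interaction
patterns" structure the method assumes, which makes planted-link recovery a
meaningful end-to-end check.  Default dimensions mirror the scale of the
HMDAD benchmark (39 diseases x 292 microbes, a few hundred positives).

A fraction of the generated positives is withheld: flipped to zero in the
observed matrix and recorded as ground truth, so recovery can be scored as
an AUC of hidden positives versus true negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import AssociationDataset
from .evaluation import rank_auc
from .kron_rls import ModelParams, predict

__all__ = ["SyntheticSpec", "SyntheticDataset", "generate", "recovery_auc"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-block generator.

    ``p_in``/``p_out`` are the within-block and background association
    probabilities; ``hide_fraction`` of the generated positives is withheld
    as ground-truth test pairs.
    """

    nd: int = 39
    nm: int = 292
    n_blocks: int = 8
    p_in: float = 0.30
    p_out: float = 0.005
    hide_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.nd, self.nm, self.n_blocks) < 1:
            raise ValueError("nd, nm and n_blocks must be at least 1")
        if self.n_blocks > min(self.nd, self.nm):
            raise ValueError("n_blocks cannot exceed min(nd, nm)")
        if not 0.0 <= self.p_out <= self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if not 0.0 <= self.hide_fraction < 1.0:
            raise ValueError("hide_fraction must lie in [0, 1)")


@dataclass(frozen=True)
class SyntheticDataset:
    """Observed dataset plus the withheld ground truth."""

    observed: AssociationDataset
    hidden_positives: tuple[tuple[int, int], ...]
    disease_blocks: np.ndarray = field(repr=False)
    microbe_blocks: np.ndarray = field(repr=False)

    def truth_matrix(self) -> np.ndarray:
        """Full ground-truth 0/1 matrix (observed plus hidden positives)."""
        A = np.array(self.observed.A)
        for i, j in self.hidden_positives:
            A[i, j] = 1
        return A


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a planted-block dataset; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    disease_blocks = rng.integers(0, spec.n_blocks, size=spec.nd)
    microbe_blocks = rng.integers(0, spec.n_blocks, size=spec.nm)
    same_block = disease_blocks[:, None] == microbe_blocks[None, :]
    prob = np.where(same_block, spec.p_in, spec.p_out)
    A_true = (rng.random((spec.nd, spec.nm)) < prob).astype(np.int8)
    pos = np.argwhere(A_true == 1)
    n_hide = int(round(spec.hide_fraction * len(pos)))
    hidden_idx = rng.choice(len(pos), size=n_hide, replace=False) if n_hide else []
    observed = np.array(A_true)
    hidden: list[tuple[int, int]] = []
    for idx in sorted(hidden_idx):
        i, j = pos[idx]
        observed[i, j] = 0
        hidden.append((int(i), int(j)))
    disease_ids = tuple(f"d{i + 1:03d}" for i in range(spec.nd))
    microbe_ids = tuple(f"m{j + 1:03d}" for j in range(spec.nm))
    return SyntheticDataset(
        observed=AssociationDataset(disease_ids, microbe_ids, observed),
        hidden_positives=tuple(hidden),
        disease_blocks=disease_blocks,
        microbe_blocks=microbe_blocks,
    )


def recovery_auc(synth: SyntheticDataset, params: ModelParams = ModelParams()) -> float:
    """AUC of hidden positives versus true negatives under the fused model."""
    if not synth.hidden_positives:
        raise ValueError("no hidden positives: generate with hide_fraction > 0")
    truth = synth.truth_matrix()
    neg_mask = (np.asarray(synth.observed.A) == 0) & (truth == 0)
    if not neg_mask.any():
        raise ValueError("no true negatives to rank against")
    F = predict(synth.observed, params).values
    hidden = np.array(synth.hidden_positives)
    pos_scores = F[hidden[:, 0], hidden[:, 1]]
    neg_scores = F[neg_mask]
    scores = np.concatenate([pos_scores, neg_scores])
    labels = np.concatenate(
        [np.ones(pos_scores.size, dtype=int), np.zeros(neg_scores.size, dtype=int)]
    )
    return rank_auc(scores, labels)
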