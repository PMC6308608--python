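"""Magnitude pruning with retraining for the LSTM classifiers.

Pipeline: train -> threshold the smallest-magnitude weights globally to a
target sparsity -> retrain with the removed connections frozen at zero ->
re-evaluate. Biases are exempt. A single global threshold is used across
all LSTM and readout weight matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lstm_core import ClassifierParams, TrainConfig, train_classifier


@dataclass
class PruneMask:
    """Binary keep-masks per weight matrix; 0 marks a removed connection."""

    masks: dict  # {name: ndarray of {0.,1.}}
    sparsity: float

    def apply(self, params: ClassifierParams) -> None:
        """Zero the removed connections in-place."""
        for name, W in params.named_weights():
            W *= self.masks[name]

    def n_zeros(self) -> int:
        return int(sum(m.size - m.sum() for m in self.masks.values()))

    def n_weights(self) -> int:
        return int(sum(m.size for m in self.masks.values()))

    def is_subset_of(self, other: "PruneMask") -> bool:
        """True when every connection removed here is removed in ``other``."""
        return all(
            np.all(other.masks[k] <= self.masks[k]) for k in self.masks
        )


def compute_mask(params: ClassifierParams, sparsity: float) -> PruneMask:
    """Global magnitude threshold: zero the floor(sparsity * n) smallest
    |weights| over all maskable matrices, ties broken by array order."""
    if not 0 <= sparsity < 1:
        raise ValueError(f"sparsity must be in [0, 1), got {sparsity}")
    named = params.named_weights()
    flat = np.concatenate([W.ravel() for _, W in named])
    n_zero = int(np.floor(sparsity * flat.size))
    keep = np.ones(flat.size)
    if n_zero:
        order = np.argsort(np.abs(flat), kind="stable")
        keep[order[:n_zero]] = 0.0
    masks = {}
    pos = 0
    for name, W in named:
        masks[name] = keep[pos : pos + W.size].reshape(W.shape)
        pos += W.size
    return PruneMask(masks=masks, sparsity=sparsity)


def retrain_pruned(
    params: ClassifierParams,
    mask: PruneMask,
    train,
    cfg: TrainConfig,
    test=None,
) -> tuple[ClassifierParams, dict]:
    """Continue training with masked entries pinned to exactly zero.

    The mask is applied before the first step and after every optimizer
    step, so removed connections are never recreated.
    """
    for name, W in params.named_weights():
        if mask.masks[name].shape != W.shape:
            raise ValueError(f"mask/parameter shape mismatch for {name}")
    return train_classifier(train, cfg, arch=params, test=test, mask=mask)


def remaining_after_prune(initial_count: int, sparsity: float) -> dict:
    """Parameter-count bookkeeping in the thousands-rounded report format.

    remaining = round(initial * (1 - sparsity)); the report value is
    remaining/1000 rounded to two decimals (e.g. 6482 -> "6.48 x 10^3").
    """
    if initial_count <= 0:
        raise ValueError("initial_count must be positive")
    remaining = round(initial_count * (1.0 - sparsity))
    thousands = round(remaining / 1000.0, 2)
    return {
        "remaining": remaining,
        "thousands": thousands,
        "report": f"{thousands:.2f} x 10^3",
    }
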