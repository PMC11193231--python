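"""Size-weighted, class-balanced focal loss (reference implementation).

Small objects (tennis balls seen from metres away) occupy a handful of
pixels, and lab clutter classes are heavily imbalanced, so a plain
cross-entropy under-trains exactly the detections this pipeline cares about.
The remedy implemented here combines two re-weightings of the focal loss:

* a *class-balance* factor ``n_y / n`` (fraction of training samples with
  label ``y``) inside the focal term::

      loss(p, y) = -alpha * (n_y / n) * (1 - p)**gamma * ln(p)

* a *size weight* per class, ``w_j = s / h_j + eps`` with ``s`` the batch
  mean object size and ``h_j`` the class's ground-truth box height, applied
  per anchor as ``focal * sqrt(w_j / h_ij)``, so classes smaller than the
  batch average are up-weighted.

As printed, the batch-mean-size and size-weight definitions reference each
other; :func:`anchor_batch_pass` resolves the circularity with a single
sequential pass (weights initialized to 1, then recomputed once from the
resulting mean size).  The direct per-sample loss
(:func:`class_balanced_focal`) is independent of that interpretation and
usable on its own.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "FocalParams",
    "ClassFrequency",
    "AnchorBatch",
    "class_balanced_focal",
    "size_weight",
    "batch_mean_size",
    "size_scaled_focal",
    "dfl_total",
    "anchor_batch_pass",
]


@dataclass(frozen=True)
class FocalParams:
    """Focal-loss hyperparameters: weighting factor, focusing exponent, epsilon."""

    alpha: float = 0.25
    gamma: float = 2.0
    epsilon: float = 1e-7

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be non-negative, got {self.gamma}")
        if not 0 < self.epsilon <= 1e-3:
            raise ValueError(f"epsilon must lie in (0, 1e-3], got {self.epsilon}")


@dataclass(frozen=True)
class ClassFrequency:
    """Training-set label frequency: ``n_y`` samples of label y out of ``n``."""

    n_y: int
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"total sample count must be >= 1, got {self.n}")
        if not 0 <= self.n_y <= self.n:
            raise ValueError(f"need 0 <= n_y <= n, got n_y={self.n_y}, n={self.n}")

    @property
    def ratio(self) -> float:
        return self.n_y / self.n


def class_balanced_focal(p: float, cf: ClassFrequency, fp: FocalParams) -> float:
    """Class-balanced focal loss ``-alpha * (n_y/n) * (1-p)**gamma * ln(p)``.

    Natural logarithm; ``p`` is clamped into ``[epsilon, 1]`` before the log,
    so the loss is finite everywhere, zero at ``p = 1``, and strictly
    decreasing in ``p`` on (0, 1].
    """
    if not math.isfinite(p):
        raise ValueError(f"p must be finite, got {p}")
    p = min(max(p, fp.epsilon), 1.0)
    return -fp.alpha * cf.ratio * (1.0 - p) ** fp.gamma * math.log(p)


def size_weight(s: float, h_j: float, fp: FocalParams) -> float:
    """Per-class size weight ``w_j = s / h_j + epsilon``.

    Classes smaller than the batch mean size (``h_j < s``) receive weight
    above ``1 + epsilon``.
    """
    if h_j <= 0:
        raise ValueError(f"class box height must be positive, got {h_j}")
    return s / h_j + fp.epsilon


def batch_mean_size(
    heights: Sequence[float], indicators: Sequence[int], w_j: float = 1.0
) -> float:
    """Mean over indicated anchors of ``sqrt(w_j / h_ij)``.

    ``indicators`` holds the 0/1 flags marking which anchors carry the class;
    the mean is taken over all anchors of the class (``N_j = len(heights)``),
    with non-indicated anchors contributing zero.
    """
    if len(heights) != len(indicators):
        raise ValueError("heights and indicators differ in length")
    if len(heights) == 0:
        raise ValueError("no anchors for this class (N_j = 0)")
    for h in heights:
        if h <= 0:
            raise ValueError(f"anchor heights must be positive, got {h}")
    for t in indicators:
        if t not in (0, 1):
            raise ValueError(f"indicators must be 0 or 1, got {t}")
    total = sum(t * math.sqrt(w_j / h) for h, t in zip(heights, indicators))
    return total / len(heights)


def size_scaled_focal(focal_i: float, w_j: float, h_ij: float) -> float:
    """Scale a per-anchor focal loss by ``sqrt(w_j / h_ij)``."""
    if focal_i < 0:
        raise ValueError(f"focal loss must be non-negative, got {focal_i}")
    if h_ij <= 0:
        raise ValueError(f"anchor height must be positive, got {h_ij}")
    return focal_i * math.sqrt(w_j / h_ij)


def dfl_total(per_class_losses: Mapping[str, float]) -> float:
    """Final loss: arithmetic sum of the per-class losses (0 for an empty map)."""
    return float(sum(per_class_losses.values()))


@dataclass
class AnchorBatch:
    """One training batch's per-class anchor geometry.

    ``anchor_heights`` maps class label -> ground-truth heights (pixels) of
    that class's anchors; ``indicators`` maps class label -> the 0/1 flags
    marking anchors that carry the class (defaults to all ones).
    """

    anchor_heights: dict[str, list[float]]
    indicators: dict[str, list[int]] = field(default_factory=dict)

    def indicator_for(self, label: str) -> list[int]:
        return self.indicators.get(label, [1] * len(self.anchor_heights[label]))


def anchor_batch_pass(batch: AnchorBatch, fp: FocalParams) -> dict[str, float]:
    """Resolve the mean-size / size-weight circularity with one sequential pass.

    Step 1 evaluates every class's mean size with ``w_j = 1``; step 2 takes
    ``s`` as the mean of those per-class sizes and recomputes each class's
    weight ``w_j = s / h_j + eps`` with ``h_j`` the class's mean ground-truth
    anchor height.  Returns the per-class size weights.
    """
    if not batch.anchor_heights:
        return {}
    s_per_class = {
        lbl: batch_mean_size(hs, batch.indicator_for(lbl), w_j=1.0)
        for lbl, hs in batch.anchor_heights.items()
    }
    s = sum(s_per_class.values()) / len(s_per_class)
    weights: dict[str, float] = {}
    for lbl, hs in batch.anchor_heights.items():
        flagged = [h for h, t in zip(hs, batch.indicator_for(lbl)) if t == 1]
        h_j = sum(flagged) / len(flagged) if flagged else sum(hs) / len(hs)
        weights[lbl] = size_weight(s, h_j, fp)
    return weights
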