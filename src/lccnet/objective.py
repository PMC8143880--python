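"""Training objective: supervised cross-entropy, unsupervised cross-model
consistency, their weighted combination, and the exponential ramp-up of the
trade-off weight.

The total loss is ``L = L_S + lambda * L_U`` where

* ``L_S`` is the mean pixel-wise cross-entropy of the supervised path over
  the labeled pool (original plus cut-and-mix augmented slices),
* ``L_U`` is the mean, over the consistency pool, of the MSE between the
  supervised prediction (treated as a fixed target) and each auxiliary
  prediction: ``d(p_S, p_D) + d(p_S, p_N)``,
* ``lambda`` follows ``lambda(epoch) = min(lambda_max,
  lambda_max * exp(2 * epoch / stop - 1))`` — worth ``lambda_max / e`` at
  epoch 0 and saturating at ``lambda_max`` from epoch ``stop / 2`` on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn.losses import cross_entropy_from_probs, mse_consistency

__all__ = [
    "ScheduleParams",
    "LossReport",
    "supervised_loss",
    "consistency_loss",
    "lambda_schedule",
    "total_loss",
]


@dataclass(frozen=True)
class ScheduleParams:
    lambda_max: float = 0.4
    stop: int = 3000
    epoch: int = 0

    def __post_init__(self):
        if self.lambda_max < 0:
            raise ValueError("lambda_max must be nonnegative")
        if self.stop < 1:
            raise ValueError("stop must be a positive epoch count")
        if self.epoch < 0:
            raise ValueError("epoch must be nonnegative")


@dataclass(frozen=True)
class LossReport:
    loss_sup: float
    loss_unsup: float
    lam: float

    @property
    def total(self) -> float:
        return self.loss_sup + self.lam * self.loss_unsup


def supervised_loss(preds, labels):
    """Mean cross-entropy over aligned probability maps and integer label masks.

    ``preds``/``labels`` may be single arrays (batched ``(N,K,H,W)`` /
    ``(N,H,W)``) or aligned lists of them. Returns a float; per-sample
    gradients are available through :func:`lccnet.nn.cross_entropy_from_probs`.
    """
    preds, labels = _as_lists(preds, labels)
    total, count = 0.0, 0
    for p, y in zip(preds, labels):
        p, y = _batched(p, y)
        loss, _ = cross_entropy_from_probs(p, y)
        n = p.shape[0]
        total += loss * n
        count += n
    return total / count


def consistency_loss(p_s, p_d, p_n):
    """Mean of ``d(p_S, p_D) + d(p_S, p_N)`` with MSE distance.

    ``p_S`` is a fixed target: no gradient flows into the supervised path.
    """
    ps_list, pd_list = _as_lists(p_s, p_d)
    _, pn_list = _as_lists(p_s, p_n)
    total, count = 0.0, 0
    for ps, pd, pn in zip(ps_list, pd_list, pn_list):
        if ps.shape != pd.shape or ps.shape != pn.shape:
            raise ValueError("the three probability maps must share one shape")
        d1, _ = mse_consistency(pd, ps)
        d2, _ = mse_consistency(pn, ps)
        n = ps.shape[0] if ps.ndim == 4 else 1
        total += (d1 + d2) * n
        count += n
    return total / count


def lambda_schedule(p: ScheduleParams) -> float:
    """Exponential ramp-up of the consistency weight, capped at ``lambda_max``."""
    return min(p.lambda_max, p.lambda_max * math.exp(2.0 * p.epoch / p.stop - 1.0))


def total_loss(loss_sup: float, loss_unsup: float, lam: float) -> LossReport:
    """Combine the two terms; ``report.total == L_S + lambda * L_U``."""
    for name, v in (("loss_sup", loss_sup), ("loss_unsup", loss_unsup), ("lambda", lam)):
        if not math.isfinite(v):
            raise FloatingPointError(f"{name} is not finite: {v}")
    return LossReport(loss_sup=float(loss_sup), loss_unsup=float(loss_unsup), lam=float(lam))


def _as_lists(a, b):
    a_list = a if isinstance(a, (list, tuple)) else [a]
    b_list = b if isinstance(b, (list, tuple)) else [b]
    if len(a_list) != len(b_list):
        raise ValueError("prediction and target lists must be aligned")
    return list(a_list), list(b_list)


def _batched(p, y):
    p = np.asarray(p, dtype=np.float32)
    y = np.asarray(y)
    if p.ndim == 3:
        p = p[None]
        y = y[None]
    return p, y
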