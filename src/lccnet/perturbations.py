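"""Feature- and input-space perturbations for cross-consistency training.

Feature space (applied to the encoder's bottleneck output):

* spatial dropout ``P_D`` — zero a randomly drawn fraction of spatial
  positions, the same positions across all channels, with the fraction
  sampled uniformly from a configured range (default 10%-40%)
* Gaussian noise ``P_N`` — add i.i.d. zero-mean noise

Input space (applied to image/mask pairs as augmentation):

* cut-and-mix ``P_C`` — split two images into a 2x2 grid of equal blocks
  and swap one or two corresponding blocks between them, applying the same
  swap to their label masks
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FeaturePerturbConfig",
    "CutMixSpec",
    "feature_noise",
    "feature_dropout",
    "cut_and_mix",
    "make_mixed_set",
]


@dataclass(frozen=True)
class FeaturePerturbConfig:
    """Magnitudes of the two feature perturbations."""

    noise_sigma: float = 0.1
    dropout_range: tuple[float, float] = (0.10, 0.40)

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        lo, hi = self.dropout_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"dropout_range {self.dropout_range} must satisfy 0 <= lo <= hi <= 1")


@dataclass(frozen=True)
class CutMixSpec:
    """Which of the four 2x2 grid blocks to exchange.

    Block indices are row-major: 0 = top-left, 1 = top-right, 2 = bottom-left,
    3 = bottom-right.
    """

    positions: tuple[int, ...]

    def __post_init__(self):
        k = len(self.positions)
        if k not in (1, 2):
            raise ValueError("must exchange one or two blocks")
        if len(set(self.positions)) != k:
            raise ValueError("block positions must be distinct")
        if any(p not in (0, 1, 2, 3) for p in self.positions):
            raise ValueError("block positions must be in {0,1,2,3}")

    @classmethod
    def random(cls, rng: np.random.Generator) -> "CutMixSpec":
        k = int(rng.integers(1, 3))
        positions = tuple(int(p) for p in rng.choice(4, size=k, replace=False))
        return cls(positions)


def feature_noise(F: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Return ``F`` plus i.i.d. Gaussian(0, sigma^2) noise of the same shape."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return F.copy()
    return F + rng.normal(0.0, sigma, size=F.shape).astype(F.dtype)


def feature_dropout(F: np.ndarray, rate_range: tuple[float, float],
                    rng: np.random.Generator):
    """Zero a random fraction of spatial positions, shared across channels.

    The dropout rate ``r`` is drawn uniformly from ``rate_range`` and exactly
    ``round(r * h * w)`` positions are zeroed (without replacement) in every
    channel. Survivors are not rescaled. Returns ``(F_dropped, mask)`` where
    ``mask`` is the ``(h, w)`` keep-mask (broadcastable to ``F``), which is
    also the Jacobian of the operation for use in backward passes.
    """
    if F.ndim < 2 or F.shape[-1] == 0 or F.shape[-2] == 0:
        raise ValueError(f"feature map with shape {F.shape} has no spatial extent")
    lo, hi = rate_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"rate_range {rate_range} must lie within [0, 1]")
    h, w = F.shape[-2], F.shape[-1]
    r = float(rng.uniform(lo, hi))
    n_drop = int(round(r * h * w))
    mask = np.ones(h * w, dtype=F.dtype)
    if n_drop > 0:
        drop_idx = rng.choice(h * w, size=n_drop, replace=False)
        mask[drop_idx] = 0.0
    mask = mask.reshape(h, w)
    return F * mask, mask


def _blocks(shape: tuple[int, int]):
    """Slices of the four equal 2x2 grid blocks of an (h, w) image."""
    h, w = shape
    if h % 2 or w % 2:
        raise ValueError(f"image size {shape} must be even to split into 2x2 blocks")
    h2, w2 = h // 2, w // 2
    return [
        (slice(0, h2), slice(0, w2)),
        (slice(0, h2), slice(w2, w)),
        (slice(h2, h), slice(0, w2)),
        (slice(h2, h), slice(w2, w)),
    ]


def cut_and_mix(img_a: np.ndarray, img_b: np.ndarray, spec: CutMixSpec,
                mask_a: np.ndarray | None = None, mask_b: np.ndarray | None = None):
    """Swap the blocks named by ``spec`` between two images (and their masks).

    Returns ``(img_a', img_b')`` or ``(img_a', img_b', mask_a', mask_b')``.
    The same spec applied twice restores the originals (involution), and the
    multiset of pixel values of the pair is conserved.
    """
    if img_a.shape != img_b.shape:
        raise ValueError(f"image shapes differ: {img_a.shape} vs {img_b.shape}")
    if (mask_a is None) != (mask_b is None):
        raise ValueError("masks must be supplied as a pair or not at all")
    blocks = _blocks(img_a.shape[-2:])
    out_a, out_b = img_a.copy(), img_b.copy()
    pairs = [(out_a, out_b)]
    outputs = [out_a, out_b]
    if mask_a is not None:
        if mask_a.shape[-2:] != img_a.shape[-2:] or mask_b.shape[-2:] != img_b.shape[-2:]:
            raise ValueError("mask shapes must match image shapes")
        ma, mb = mask_a.copy(), mask_b.copy()
        pairs.append((ma, mb))
        outputs += [ma, mb]
    for a, b in pairs:
        for pos in spec.positions:
            sl = (..., *blocks[pos])
            a[sl], b[sl] = b[sl].copy(), a[sl].copy()
    return tuple(outputs)


def make_mixed_set(samples: list, rng: np.random.Generator) -> list:
    """Build the cut-and-mix augmented copy of a sample pool.

    ``samples`` is a list of ``(image, mask_or_None)`` tuples from a single
    pool (labeled with labeled, unlabeled with unlabeled — never across).
    Samples are randomly paired; each pair gets an independent random
    :class:`CutMixSpec`. With an odd pool the leftover sample passes through
    unmixed, so the output size always equals the input size.
    """
    if len(samples) < 2:
        raise ValueError("need at least two samples to pair for cut-and-mix")
    order = rng.permutation(len(samples))
    mixed: list = [None] * len(samples)
    n_pairs = len(samples) // 2
    for p in range(n_pairs):
        ia, ib = int(order[2 * p]), int(order[2 * p + 1])
        (img_a, msk_a), (img_b, msk_b) = samples[ia], samples[ib]
        spec = CutMixSpec.random(rng)
        if msk_a is not None and msk_b is not None:
            a2, b2, ma2, mb2 = cut_and_mix(img_a, img_b, spec, msk_a, msk_b)
            mixed[ia], mixed[ib] = (a2, ma2), (b2, mb2)
        else:
            a2, b2 = cut_and_mix(img_a, img_b, spec)
            mixed[ia], mixed[ib] = (a2, None), (b2, None)
    if len(samples) % 2:
        leftover = int(order[-1])
        img, msk = samples[leftover]
        mixed[leftover] = (img.copy(), None if msk is None else msk.copy())
    return mixed
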