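"""Synthetic cardiac short-axis phantom.

Each slice shows the three segmentation targets of short-axis cardiac MR on
a noisy dark background: a bright left-ventricular blood pool (disk,
class 3), the surrounding darker myocardium (annulus, class 2), and the
right-ventricular blood pool as a crescent hugging the annulus (class 1).
Geometry is drawn per subject and scaled smoothly across the slice stack to
mimic apex-to-base variation; intensities are class means plus Gaussian
noise clipped to [0, 1].

The generator exists so the whole pipeline — loader, splits, training,
evaluation — can run end to end without any external download, in the same
labeled-few / unlabeled-many regime the method targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_io import SliceSample, Subject

__all__ = ["PhantomParams", "generate_subject", "generate_dataset"]

LABEL_BACKGROUND, LABEL_RV, LABEL_MYO, LABEL_LV = 0, 1, 2, 3


@dataclass(frozen=True)
class PhantomParams:
    image_size: int = 64
    slices_per_subject: int = 5
    mean_background: float = 0.20
    mean_rv: float = 0.70
    mean_myo: float = 0.35
    mean_lv: float = 0.80
    noise_std: float = 0.05
    lv_radius_range: tuple[float, float] = (5.5, 9.0)
    myo_thickness_range: tuple[float, float] = (2.5, 4.0)
    rv_radius_range: tuple[float, float] = (5.0, 8.0)
    center_jitter: float = 3.0
    slice_scale_range: tuple[float, float] = (0.70, 1.10)  # apex -> base

    def __post_init__(self):
        for name in ("mean_background", "mean_rv", "mean_myo", "mean_lv"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.slices_per_subject < 1:
            raise ValueError("slices_per_subject must be >= 1")
        if self.noise_std < 0:
            raise ValueError("noise_std must be nonnegative")
        # feasibility: widest annulus plus RV crescent must fit in the frame
        max_outer = (self.lv_radius_range[1] + self.myo_thickness_range[1]) * self.slice_scale_range[1]
        reach = max_outer + 1.6 * self.rv_radius_range[1] * self.slice_scale_range[1]
        if reach + self.center_jitter >= self.image_size / 2:
            raise ValueError(
                f"phantom geometry (reach {reach:.1f} px + jitter) does not fit "
                f"in a {self.image_size}px image"
            )


def _slice_mask(size: int, cy: float, cx: float, lv_r: float, myo_t: float,
                rv_r: float, rv_angle: float) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size]
    d = np.hypot(rr - cy, cc - cx)
    outer = lv_r + myo_t
    mask = np.zeros((size, size), dtype=np.int16)
    # RV: disk overlapping the annulus from outside; heart classes take precedence
    rv_dist = outer + 0.55 * rv_r
    rv_cy = cy + rv_dist * np.sin(rv_angle)
    rv_cx = cx + rv_dist * np.cos(rv_angle)
    d_rv = np.hypot(rr - rv_cy, cc - rv_cx)
    mask[d_rv <= rv_r] = LABEL_RV
    mask[d <= outer] = LABEL_MYO
    mask[d <= lv_r] = LABEL_LV
    return mask


def generate_subject(params: PhantomParams, seed=0,
                     subject_id: str = "phantom000") -> Subject:
    """Generate one subject (stack of image+mask slices), deterministic in seed."""
    rng = np.random.default_rng(seed)
    size = params.image_size
    cy, cx = (size / 2 + rng.uniform(-params.center_jitter, params.center_jitter)
              for _ in range(2))
    lv_r = rng.uniform(*params.lv_radius_range)
    myo_t = rng.uniform(*params.myo_thickness_range)
    rv_r = rng.uniform(*params.rv_radius_range)
    rv_angle = np.pi + rng.uniform(-0.5, 0.5)  # roughly to the left, as in short-axis views
    means = np.array(
        [params.mean_background, params.mean_rv, params.mean_myo, params.mean_lv],
        dtype=np.float32,
    )
    n_slices = params.slices_per_subject
    scales = np.linspace(*params.slice_scale_range, num=n_slices)
    slices = []
    for k in range(n_slices):
        s = float(scales[k])
        mask = _slice_mask(size, cy, cx, lv_r * s, myo_t * s, rv_r * s, rv_angle)
        img = means[mask] + rng.normal(0.0, params.noise_std, size=mask.shape).astype(np.float32)
        img = np.clip(img, 0.0, 1.0).astype(np.float32)
        slices.append(SliceSample(image=img, mask=mask, phase="frame01"))
    return Subject(subject_id=subject_id, slices=slices, spacing=(1.0, 1.0, 1.0))


def generate_dataset(n_subjects: int, params: PhantomParams | None = None,
                     seed: int = 0) -> list[Subject]:
    """Generate ``n_subjects`` independent subjects from a master seed."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    params = params or PhantomParams()
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    return [
        generate_subject(params, seed=child, subject_id=f"phantom{i:03d}")
        for i, child in enumerate(children)
    ]
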