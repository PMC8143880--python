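"""Reading ACDC-style NIfTI subjects, slice preprocessing, and subject-level
labeled/unlabeled/test splits.

A *subject* is a directory of short-axis volumes, one image volume per
annotated cardiac phase (``<id>_frame<XX>.nii.gz``) with an optional
ground-truth volume (``<id>_frame<XX>_gt.nii.gz``). Volumes are split into
2D slices; label values are {0 background, 1 RV, 2 MYO, 3 LV}.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from skimage.transform import resize

__all__ = [
    "SliceSample",
    "Subject",
    "DataSplit",
    "load_acdc_subject",
    "load_dataset",
    "write_subject",
    "preprocess_slice",
    "preprocess_subject",
    "make_split",
]

VALID_LABELS = frozenset({0, 1, 2, 3})


@dataclass
class SliceSample:
    image: np.ndarray  # (H, W) float32
    mask: np.ndarray | None  # (H, W) integer classes or None
    phase: str = "frame01"


@dataclass
class Subject:
    subject_id: str
    slices: list[SliceSample]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (row, col, slice) mm

    @property
    def labeled(self) -> bool:
        return len(self.slices) > 0 and all(s.mask is not None for s in self.slices)

    def images(self) -> list[np.ndarray]:
        return [s.image for s in self.slices]


@dataclass
class DataSplit:
    labeled: list[Subject]
    unlabeled: list[Subject]
    test: list[Subject]

    @property
    def n(self) -> int:
        """Number of labeled training slices."""
        return sum(len(s.slices) for s in self.labeled)

    @property
    def m(self) -> int:
        """Number of unlabeled training slices."""
        return sum(len(s.slices) for s in self.unlabeled)

    def manifest(self) -> dict:
        return {
            "labeled": [s.subject_id for s in self.labeled],
            "unlabeled": [s.subject_id for s in self.unlabeled],
            "test": [s.subject_id for s in self.test],
        }


_FRAME_RE = re.compile(r"^(?P<sid>.+)_(?P<frame>frame\d+)(?P<gt>_gt)?\.nii(\.gz)?$")


def load_acdc_subject(path: str | Path) -> Subject:
    """Load one subject directory into per-slice samples.

    Frames with a ground-truth volume yield labeled slices; frames without
    one yield unlabeled slices. Spacing metadata is carried through from the
    NIfTI header as (row, col, slice) mm.
    """
    path = Path(path)
    if not path.is_dir():
        raise IOError(f"subject directory not found: {path}")
    frames: dict[str, dict] = {}
    for f in sorted(path.iterdir()):
        m = _FRAME_RE.match(f.name)
        if not m:
            continue
        entry = frames.setdefault(m.group("frame"), {})
        entry["gt" if m.group("gt") else "img"] = f
    if not any("img" in e for e in frames.values()):
        raise IOError(f"no image volumes found in {path}")

    slices: list[SliceSample] = []
    spacing = (1.0, 1.0, 1.0)
    for frame in sorted(frames):
        entry = frames[frame]
        if "img" not in entry:
            continue
        img_nii = nib.load(str(entry["img"]))
        vol = np.asarray(img_nii.dataobj, dtype=np.float32)
        if vol.ndim != 3:
            raise IOError(f"{entry['img']} is not a 3D volume (shape {vol.shape})")
        zooms = img_nii.header.get_zooms()[:3]
        spacing = (float(zooms[0]), float(zooms[1]), float(zooms[2]))
        gt_vol = None
        if "gt" in entry:
            gt_vol = np.rint(np.asarray(nib.load(str(entry["gt"])).dataobj)).astype(np.int16)
            if gt_vol.shape != vol.shape:
                raise IOError(f"ground truth shape {gt_vol.shape} != image shape {vol.shape}")
            bad = set(np.unique(gt_vol)) - VALID_LABELS
            if bad:
                raise IOError(f"ground truth of {path.name}/{frame} has invalid labels {sorted(bad)}")
        for k in range(vol.shape[2]):
            mask = gt_vol[:, :, k] if gt_vol is not None else None
            slices.append(SliceSample(image=vol[:, :, k], mask=mask, phase=frame))
    return Subject(subject_id=path.name, slices=slices, spacing=spacing)


def load_dataset(root: str | Path) -> list[Subject]:
    """Load every subject directory under ``root`` (sorted by name)."""
    root = Path(root)
    subjects = []
    for d in sorted(p for p in root.iterdir() if p.is_dir()):
        subjects.append(load_acdc_subject(d))
    if not subjects:
        raise IOError(f"no subject directories under {root}")
    return subjects


def write_subject(subject: Subject, root: str | Path) -> Path:
    """Write a subject back to the NIfTI directory layout the loader reads.

    Slices are grouped by phase into one volume per frame; labeled frames
    additionally get a ``_gt`` volume.
    """
    root = Path(root)
    out = root / subject.subject_id
    out.mkdir(parents=True, exist_ok=True)
    r, c, z = subject.spacing
    affine = np.diag([r, c, z, 1.0])
    phases: dict[str, list[SliceSample]] = {}
    for s in subject.slices:
        phases.setdefault(s.phase, []).append(s)
    for phase, group in phases.items():
        vol = np.stack([s.image for s in group], axis=2).astype(np.float32)
        nib.save(nib.Nifti1Image(vol, affine), str(out / f"{subject.subject_id}_{phase}.nii.gz"))
        if all(s.mask is not None for s in group):
            gt = np.stack([s.mask for s in group], axis=2).astype(np.int16)
            nib.save(nib.Nifti1Image(gt, affine), str(out / f"{subject.subject_id}_{phase}_gt.nii.gz"))
    return out


def preprocess_slice(img: np.ndarray, mask: np.ndarray | None = None, size: int = 160):
    """Resize to ``size x size`` and min-max rescale the intensities to [0, 1].

    Images are resampled bilinearly, masks nearest-neighbor. A constant
    intensity slice maps to all zeros. Idempotent: a second application is a
    no-op up to interpolation tolerance (exactly, for masks).
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {img.shape}")
    if img.shape != (size, size):
        img = resize(img.astype(np.float64), (size, size), order=1, mode="edge",
                     anti_aliasing=img.shape[0] > size, preserve_range=True)
    img = img.astype(np.float32)
    lo, hi = float(img.min()), float(img.max())
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    out_mask = None
    if mask is not None:
        mask = np.asarray(mask)
        if mask.ndim != 2:
            raise ValueError(f"expected a 2D mask, got shape {mask.shape}")
        if mask.shape != (size, size):
            mask = resize(mask, (size, size), order=0, anti_aliasing=False,
                          preserve_range=True)
        out_mask = np.rint(mask).astype(np.int16)
    return (img, out_mask) if mask is not None else (img, None)


def preprocess_subject(subject: Subject, size: int = 160) -> Subject:
    """Preprocess every slice; in-plane spacing is rescaled by original/size."""
    new_slices = []
    factor_r = factor_c = 1.0
    for s in subject.slices:
        h, w = s.image.shape
        factor_r, factor_c = h / size, w / size
        img, mask = preprocess_slice(s.image, s.mask, size=size)
        new_slices.append(SliceSample(image=img, mask=mask, phase=s.phase))
    r, c, z = subject.spacing
    return Subject(
        subject_id=subject.subject_id,
        slices=new_slices,
        spacing=(r * factor_r, c * factor_c, z),
    )


def make_split(subjects: list[Subject], K: int, test_count: int, seed: int) -> DataSplit:
    """Subject-level random split: ``test_count`` test subjects drawn first,
    then ``K`` labeled subjects, the remainder unlabeled. Deterministic in
    ``seed``."""
    if K < 1:
        raise ValueError("K must be >= 1 (a labeled pool is required for training)")
    if K + test_count > len(subjects):
        raise ValueError(f"K={K} + test_count={test_count} exceeds {len(subjects)} subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    test = [subjects[i] for i in order[:test_count]]
    labeled = [subjects[i] for i in order[test_count : test_count + K]]
    unlabeled = [subjects[i] for i in order[test_count + K :]]
    return DataSplit(labeled=labeled, unlabeled=unlabeled, test=test)


def save_manifest(split: DataSplit, seed: int, path: str | Path):
    payload = dict(split.manifest())
    payload["seed"] = int(seed)
    Path(path).write_text(json.dumps(payload, indent=2))


def split_from_manifest(subjects: list[Subject], manifest: dict) -> DataSplit:
    by_id = {s.subject_id: s for s in subjects}
    return DataSplit(
        labeled=[by_id[i] for i in manifest["labeled"]],
        unlabeled=[by_id[i] for i in manifest["unlabeled"]],
        test=[by_id[i] for i in manifest["test"]],
    )
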