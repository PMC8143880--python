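"""Segmentation evaluation: Dice coefficient and Hausdorff distance per
cardiac structure (RV, MYO, LV), per subject, with test-set means.

Dice is the standard overlap ratio ``2|X n Y| / (|X| + |Y|)``. The Hausdorff
distance is the symmetric maximum of directed point-to-set Euclidean
distances, computed over full foreground point sets with physical spacing.
Both metrics are computed on per-subject slice stacks (3D point sets).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import directed_hausdorff

__all__ = ["dice", "hausdorff", "EvalReport", "evaluate_model", "STRUCTURES"]

STRUCTURES = {1: "RV", 2: "MYO", 3: "LV"}


def dice(X: np.ndarray, Y: np.ndarray, variant: str = "standard") -> float:
    """Dice overlap of two boolean regions on the same grid, in [0, 1].

    Conventions: two empty regions agree perfectly (1.0); exactly one empty
    region gives 0.0. ``variant="union"`` computes the non-standard ratio
    ``2|X n Y| / |X u Y|`` (which exceeds 1 on partial overlap) for audit.
    """
    X = np.asarray(X, dtype=bool)
    Y = np.asarray(Y, dtype=bool)
    if X.shape != Y.shape:
        raise ValueError(f"region shapes differ: {X.shape} vs {Y.shape}")
    nx, ny = int(X.sum()), int(Y.sum())
    if nx == 0 and ny == 0:
        return 1.0
    if nx == 0 or ny == 0:
        return 0.0
    inter = int(np.logical_and(X, Y).sum())
    if variant == "standard":
        return 2.0 * inter / (nx + ny)
    if variant == "union":
        return 2.0 * inter / int(np.logical_or(X, Y).sum())
    raise ValueError(f"unknown dice variant {variant!r}")


def hausdorff(X: np.ndarray, Y: np.ndarray, spacing=None) -> float:
    """Symmetric Hausdorff distance between two nonempty boolean regions.

    Coordinates are scaled by per-axis physical ``spacing`` (mm per pixel,
    default 1.0 on every axis), so the result is in mm.
    """
    X = np.asarray(X, dtype=bool)
    Y = np.asarray(Y, dtype=bool)
    if X.shape != Y.shape:
        raise ValueError(f"region shapes differ: {X.shape} vs {Y.shape}")
    if not X.any() or not Y.any():
        raise ValueError("Hausdorff distance is undefined for an empty region")
    if spacing is None:
        spacing = np.ones(X.ndim)
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (X.ndim,) or (spacing <= 0).any():
        raise ValueError(f"spacing must be {X.ndim} positive values")
    px = np.argwhere(X) * spacing
    py = np.argwhere(Y) * spacing
    return max(directed_hausdorff(px, py)[0], directed_hausdorff(py, px)[0])


@dataclass
class EvalReport:
    """Per-subject, per-structure Dice (%) and Hausdorff (mm) with means."""

    rows: list[dict] = field(default_factory=list)

    def add(self, subject_id: str, structure: str, dice_pct: float,
            hausdorff_mm: float | None):
        self.rows.append({
            "subject": subject_id,
            "structure": structure,
            "dice_pct": dice_pct,
            "hausdorff_mm": hausdorff_mm,
        })

    def summary(self) -> dict:
        """Per-structure means over subjects plus the overall structure mean."""
        out: dict[str, dict] = {}
        for name in STRUCTURES.values():
            dices = [r["dice_pct"] for r in self.rows if r["structure"] == name]
            hds = [r["hausdorff_mm"] for r in self.rows
                   if r["structure"] == name and r["hausdorff_mm"] is not None]
            if dices:
                out[name] = {
                    "dice_pct": float(np.mean(dices)),
                    "hausdorff_mm": float(np.mean(hds)) if hds else None,
                }
        if out:
            hd_vals = [v["hausdorff_mm"] for v in out.values() if v["hausdorff_mm"] is not None]
            out["mean"] = {
                "dice_pct": float(np.mean([v["dice_pct"] for v in out.values()])),
                "hausdorff_mm": float(np.mean(hd_vals)) if hd_vals else None,
            }
        return out

    @property
    def mean_dice_pct(self) -> float:
        return self.summary()["mean"]["dice_pct"]

    def to_csv(self, path: str | Path):
        lines = ["subject,structure,dice_pct,hausdorff_mm"]
        for r in self.rows:
            hd = "" if r["hausdorff_mm"] is None else f"{r['hausdorff_mm']:.4f}"
            lines.append(f"{r['subject']},{r['structure']},{r['dice_pct']:.4f},{hd}")
        for name, v in self.summary().items():
            hd = "" if v["hausdorff_mm"] is None else f"{v['hausdorff_mm']:.4f}"
            lines.append(f"mean,{name},{v['dice_pct']:.4f},{hd}")
        Path(path).write_text("\n".join(lines) + "\n")

    def to_json(self, path: str | Path):
        Path(path).write_text(
            json.dumps({"rows": self.rows, "summary": self.summary()}, indent=2)
        )


def predict_subject(net, subject, batch_size: int = 8) -> np.ndarray:
    """Per-slice argmax predictions for one subject, stacked (slices, H, W)."""
    imgs = np.stack([s.image for s in subject.slices]).astype(np.float32)[:, None]
    preds = []
    for i in range(0, len(imgs), batch_size):
        probs = net.forward(imgs[i : i + batch_size])
        preds.append(np.argmax(probs, axis=1))
    return np.concatenate(preds, axis=0)


def evaluate_model(net, subjects, batch_size: int = 8,
                   predict_fn=None) -> EvalReport:
    """Evaluate a segmentation network on preprocessed test subjects.

    Slices are predicted independently and stacked per subject; Dice and
    Hausdorff are computed on the per-subject 3D stacks for each structure,
    with Hausdorff in mm using the subject's (slice, row, col) spacing. A
    structure with an empty region on either side has no defined Hausdorff
    and is excluded from the Hausdorff mean with a warning.
    """
    report = EvalReport()
    for subject in subjects:
        if not subject.slices:
            warnings.warn(f"subject {subject.subject_id} has no slices; skipped")
            continue
        if any(s.mask is None for s in subject.slices):
            raise ValueError(f"subject {subject.subject_id} has no ground truth")
        pred = (predict_fn(subject) if predict_fn is not None
                else predict_subject(net, subject, batch_size=batch_size))
        gt = np.stack([s.mask for s in subject.slices])
        r, c, z = subject.spacing
        spacing3 = (z, r, c)
        for cls, name in STRUCTURES.items():
            gt_bin = gt == cls
            pred_bin = pred == cls
            d = 100.0 * dice(gt_bin, pred_bin)
            if gt_bin.any() and pred_bin.any():
                hd = hausdorff(gt_bin, pred_bin, spacing=spacing3)
            else:
                hd = None
                warnings.warn(
                    f"empty {name} region for subject {subject.subject_id}; "
                    "Hausdorff reported as missing"
                )
            report.add(subject.subject_id, name, d, hd)
    return report
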