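"""Semi-supervised and supervised-only training loops.

One *epoch* is one pass over the labeled pool. Every step draws a labeled
batch for the supervised loss and, in the semi-supervised trainer, an
equal-size batch (with replacement) from the consistency pool
``D_u u D_u' u D_l'`` for the cross-consistency loss. Cut-and-mix pools are
regenerated with fresh pairings each epoch. All randomness flows through
named, independent streams derived from ``TrainConfig.seed``, so a
supervised-only run consumes exactly the same labeled-side draws as a
semi-supervised run with the same seed (this is what makes the
``lambda_max = 0`` equivalence exact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .architecture import LCCNetAssembly, UNet
from .nn import Adam
from .nn.losses import cross_entropy_from_probs, mse_consistency
from .objective import ScheduleParams, lambda_schedule
from .perturbations import feature_dropout, feature_noise, make_mixed_set

__all__ = [
    "TrainConfig",
    "lr_at_epoch",
    "augment_sample",
    "apply_geometric",
    "train_semisupervised",
    "train_supervised_baseline",
    "labeled_slices",
    "unlabeled_slices",
]


@dataclass(frozen=True)
class TrainConfig:
    lr_init: float = 5e-4
    lr_decay_factor: float = 0.5
    lr_decay_epochs: tuple[int, ...] = (200, 1000, 1500, 1800, 2100)
    batch_size: int = 4
    max_epochs: int = 3000
    lambda_max: float = 0.4
    lambda_stop: int | None = None  # None -> max_epochs
    noise_sigma: float = 0.1
    dropout_range: tuple[float, float] = (0.10, 0.40)
    aug_rotate_deg: float = 15.0
    aug_scale_range: tuple[float, float] = (0.9, 1.1)
    aug_shear_deg: float = 0.0
    aug_intensity: float = 0.1
    cutmix_labeled: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if list(self.lr_decay_epochs) != sorted(set(self.lr_decay_epochs)):
            raise ValueError("lr_decay_epochs must be strictly increasing")
        if self.lambda_stop is not None and self.lambda_stop < 1:
            raise ValueError("lambda_stop must be >= 1")

    @property
    def stop(self) -> int:
        return self.lambda_stop if self.lambda_stop is not None else self.max_epochs

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        for key in ("lr_decay_epochs", "dropout_range", "aug_scale_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Step-decayed learning rate: halved at each configured decay epoch."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    n_decays = sum(1 for e in cfg.lr_decay_epochs if e <= epoch)
    return cfg.lr_init * cfg.lr_decay_factor**n_decays


def apply_geometric(img: np.ndarray, mask: np.ndarray | None,
                    angle_deg: float, scale: float, shear_deg: float):
    """Apply one affine transform about the image center.

    The image is interpolated bilinearly, the mask nearest-neighbor, so mask
    values stay a subset of the input's values.
    """
    h, w = img.shape
    theta = math.radians(angle_deg)
    sh = math.radians(shear_deg)
    rot = np.array([[math.cos(theta), -math.sin(theta)],
                    [math.sin(theta), math.cos(theta)]])
    shear = np.array([[1.0, math.tan(sh)], [0.0, 1.0]])
    fwd = scale * (rot @ shear)
    inv = np.linalg.inv(fwd)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - inv @ center
    out_img = ndimage.affine_transform(img.astype(np.float32), inv, offset=offset,
                                       order=1, mode="nearest").astype(np.float32)
    out_mask = None
    if mask is not None:
        out_mask = ndimage.affine_transform(mask, inv, offset=offset, order=0,
                                            mode="nearest")
    return out_img, out_mask


def augment_sample(img: np.ndarray, mask: np.ndarray | None,
                   rng: np.random.Generator, cfg: TrainConfig):
    """Random affine + rotation + intensity shift (geometry shared with the mask)."""
    angle = float(rng.uniform(-cfg.aug_rotate_deg, cfg.aug_rotate_deg))
    scale = float(rng.uniform(*cfg.aug_scale_range))
    shear = float(rng.uniform(-cfg.aug_shear_deg, cfg.aug_shear_deg))
    if angle == 0.0 and scale == 1.0 and shear == 0.0:
        out_img, out_mask = img.astype(np.float32), (None if mask is None else mask.copy())
    else:
        out_img, out_mask = apply_geometric(img, mask, angle, scale, shear)
    shift = float(rng.uniform(-cfg.aug_intensity, cfg.aug_intensity))
    out_img = np.clip(out_img + shift, 0.0, 1.0).astype(np.float32)
    return out_img, out_mask


def labeled_slices(subjects) -> list[tuple[np.ndarray, np.ndarray]]:
    out = []
    for s in subjects:
        for sl in s.slices:
            if sl.mask is None:
                raise ValueError(f"subject {s.subject_id} is missing ground truth")
            out.append((sl.image, sl.mask))
    return out


def unlabeled_slices(subjects) -> list[tuple[np.ndarray, None]]:
    return [(sl.image, None) for s in subjects for sl in s.slices]


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ["mix_l", "batch_l", "aug_l", "mix_u", "batch_u", "aug_u", "perturb"]
    return {
        name: np.random.default_rng(np.random.SeedSequence([int(seed), 1000 + i]))
        for i, name in enumerate(names)
    }


def _labeled_batch(pool, order, step, cfg, rng_aug):
    idx = order[step * cfg.batch_size : (step + 1) * cfg.batch_size]
    xs, ys = [], []
    for i in idx:
        img, msk = pool[int(i)]
        img, msk = augment_sample(img, msk, rng_aug, cfg)
        xs.append(img)
        ys.append(msk)
    return np.stack(xs)[:, None], np.stack(ys)


def _check_finite(loss: float, epoch: int, what: str):
    if not math.isfinite(loss):
        raise FloatingPointError(
            f"{what} became non-finite ({loss}) at epoch {epoch}; aborting training"
        )


def train_semisupervised(split, assembly: LCCNetAssembly, cfg: TrainConfig,
                         epochs: int | None = None, log_cb=None):
    """Train the cross-consistency assembly on a labeled/unlabeled split.

    Returns ``(assembly, log)`` where ``log`` is a list of per-epoch dicts
    with keys epoch, lambda, lr, loss_sup, loss_unsup, loss.
    """
    if not split.labeled:
        raise ValueError("cannot train without labeled subjects")
    if not split.unlabeled:
        raise ValueError("semi-supervised training requires unlabeled subjects")
    epochs = epochs if epochs is not None else cfg.max_epochs
    d_l = labeled_slices(split.labeled)
    d_u = unlabeled_slices(split.unlabeled)
    streams = _streams(cfg.seed)
    opt = Adam(assembly.parameters(), lr=cfg.lr_init)
    sched = ScheduleParams(lambda_max=cfg.lambda_max, stop=cfg.stop)
    log = []
    enc, dec_s, dec_d, dec_n = assembly.encoder, assembly.dec_s, assembly.dec_d, assembly.dec_n

    for epoch in range(epochs):
        lam = lambda_schedule(ScheduleParams(sched.lambda_max, sched.stop, epoch))
        lr = lr_at_epoch(cfg, epoch)
        if cfg.cutmix_labeled and len(d_l) >= 2:
            d_l_prime = make_mixed_set(d_l, streams["mix_l"])
            pool_l = d_l + d_l_prime
        else:
            d_l_prime = []
            pool_l = list(d_l)
        d_u_prime = make_mixed_set(d_u, streams["mix_u"]) if len(d_u) >= 2 else []
        pool_u = d_u + d_u_prime + d_l_prime
        order = streams["batch_l"].permutation(len(pool_l))
        n_steps = math.ceil(len(pool_l) / cfg.batch_size)
        ep_sup, ep_unsup = 0.0, 0.0

        for step in range(n_steps):
            # supervised term on the labeled batch
            x_l, y_l = _labeled_batch(pool_l, order, step, cfg, streams["aug_l"])
            skips, h = enc(x_l)
            p_s = dec_s(h, skips)
            loss_sup, dp_s = cross_entropy_from_probs(p_s, y_l)
            _check_finite(loss_sup, epoch, "supervised loss")
            d_bottom, d_skips = dec_s.backward(dp_s)
            enc.backward(d_bottom, d_skips)

            # consistency term on the unlabeled-pool batch
            u_idx = streams["batch_u"].integers(0, len(pool_u), size=cfg.batch_size)
            xs = []
            for i in u_idx:
                img, _ = pool_u[int(i)]
                img, _ = augment_sample(img, None, streams["aug_u"], cfg)
                xs.append(img)
            x_u = np.stack(xs)[:, None]
            skips_u, h_u = enc(x_u)
            p_target = dec_s(h_u, skips_u)  # fixed target: no backward through D_S
            h_d, keep = feature_dropout(h_u, cfg.dropout_range, streams["perturb"])
            p_d = dec_d(h_d, skips_u)
            h_n = feature_noise(h_u, cfg.noise_sigma, streams["perturb"])
            p_n = dec_n(h_n, skips_u)
            d1, dp_d = mse_consistency(p_d, p_target)
            d2, dp_n = mse_consistency(p_n, p_target)
            loss_unsup = d1 + d2
            _check_finite(loss_unsup, epoch, "consistency loss")
            db_d, dsk_d = dec_d.backward(np.float32(lam) * dp_d)
            db_n, dsk_n = dec_n.backward(np.float32(lam) * dp_n)
            enc.backward(db_d * keep + db_n,
                         [a + b for a, b in zip(dsk_d, dsk_n)])

            opt.step(lr)
            assembly.zero_grad()
            ep_sup += loss_sup
            ep_unsup += loss_unsup

        entry = {
            "epoch": epoch,
            "lambda": lam,
            "lr": lr,
            "loss_sup": ep_sup / n_steps,
            "loss_unsup": ep_unsup / n_steps,
        }
        entry["loss"] = entry["loss_sup"] + lam * entry["loss_unsup"]
        log.append(entry)
        if log_cb is not None:
            log_cb(entry)
    return assembly, log


def train_supervised_baseline(split, net: UNet, cfg: TrainConfig,
                              epochs: int | None = None, log_cb=None):
    """Train a single segmentation network on the labeled pool only.

    Never touches ``split.unlabeled``. Labeled-side randomness (mixing,
    shuffling, augmentation) comes from the same named streams as the
    semi-supervised trainer.
    """
    if not split.labeled:
        raise ValueError("cannot train without labeled subjects")
    epochs = epochs if epochs is not None else cfg.max_epochs
    d_l = labeled_slices(split.labeled)
    streams = _streams(cfg.seed)
    opt = Adam(net.parameters(), lr=cfg.lr_init)
    log = []

    for epoch in range(epochs):
        lr = lr_at_epoch(cfg, epoch)
        if cfg.cutmix_labeled and len(d_l) >= 2:
            pool_l = d_l + make_mixed_set(d_l, streams["mix_l"])
        else:
            pool_l = list(d_l)
        order = streams["batch_l"].permutation(len(pool_l))
        n_steps = math.ceil(len(pool_l) / cfg.batch_size)
        ep_sup = 0.0
        for step in range(n_steps):
            x_l, y_l = _labeled_batch(pool_l, order, step, cfg, streams["aug_l"])
            p = net.forward(x_l)
            loss_sup, dp = cross_entropy_from_probs(p, y_l)
            _check_finite(loss_sup, epoch, "supervised loss")
            net.backward(dp)
            opt.step(lr)
            net.zero_grad()
            ep_sup += loss_sup
        entry = {
            "epoch": epoch,
            "lambda": 0.0,
            "lr": lr,
            "loss_sup": ep_sup / n_steps,
            "loss_unsup": 0.0,
            "loss": ep_sup / n_steps,
        }
        log.append(entry)
        if log_cb is not None:
            log_cb(entry)
    return net, log
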