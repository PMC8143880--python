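"""Single-file checkpoints: config + weights + optimizer state + seeds."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .architecture import BackboneConfig, LCCNetAssembly, UNet, build_backbone, build_lccnet
from .nn import Adam
from .perturbations import FeaturePerturbConfig

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(path, model, train_cfg_dict: dict | None = None,
                    optimizer: Adam | None = None, epoch: int = 0, seed: int = 0):
    """Serialize a network or assembly (plus metadata) to one ``.npz`` file."""
    if isinstance(model, LCCNetAssembly):
        kind = "lccnet"
    elif isinstance(model, UNet):
        kind = "unet"
    else:
        raise TypeError(f"cannot checkpoint {type(model).__name__}")
    meta = {
        "kind": kind,
        "backbone": model.cfg.to_dict(),
        "train_cfg": train_cfg_dict,
        "epoch": int(epoch),
        "seed": int(seed),
    }
    if isinstance(model, LCCNetAssembly):
        meta["perturb"] = {
            "noise_sigma": model.perturb.noise_sigma,
            "dropout_range": list(model.perturb.dropout_range),
        }
    arrays = {f"w::{k}": v for k, v in model.state_dict().items()}
    if optimizer is not None:
        state = optimizer.state_dict()
        meta["adam_t"] = state["t"]
        for i, (m, v) in enumerate(zip(state["m"], state["v"])):
            arrays[f"adam_m::{i}"] = m
            arrays[f"adam_v::{i}"] = v
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(str(path), **arrays)
    return Path(path)


def load_checkpoint(path):
    """Rebuild the checkpointed model; returns ``(model, meta)``.

    A reloaded model evaluates bit-identically to the saved one.
    """
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        cfg = BackboneConfig.from_dict(meta["backbone"])
        if meta["kind"] == "lccnet":
            perturb = FeaturePerturbConfig(
                noise_sigma=meta["perturb"]["noise_sigma"],
                dropout_range=tuple(meta["perturb"]["dropout_range"]),
            )
            model = build_lccnet(cfg, seed=meta["seed"], perturb=perturb)
        else:
            model = build_backbone(cfg, seed=meta["seed"])
        state = {k[len("w::"):]: data[k] for k in data.files if k.startswith("w::")}
        model.load_state_dict(state)
        meta["adam_state"] = None
        if "adam_t" in meta:
            n = sum(1 for k in data.files if k.startswith("adam_m::"))
            meta["adam_state"] = {
                "t": meta["adam_t"],
                "m": [data[f"adam_m::{i}"] for i in range(n)],
                "v": [data[f"adam_v::{i}"] for i in range(n)],
            }
    return model, meta
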