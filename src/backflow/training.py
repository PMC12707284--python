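"""Desk-scale training loop for the trunk under the flow-matching objective.

Each step draws a batch of structures; every sample gets an independent flow
time t ~ Uniform(0, 1), a noise-scheme draw (the coordinate perturbation and
the matching noise token always agree), a 50/50 spatial-interface/contiguous
crop, and the masked-position cross-entropy of the trunk's logits against the
native sequence.  AdamW with linear learning-rate warmup and global-norm
gradient clipping; fully seed-deterministic on one device.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .backbone_io import BackboneStructure, add_backbone_noise, build_frames, crop_example
from .featurize import featurize
from .flow import SamplerConfig, corrupt, design_sequences, fm_loss
from .nn import AdamW
from .trunk import TrunkModel
from .utils import seed_stream, string_to_tokens

__all__ = ["TrainConfig", "TrainResult", "lr_schedule", "train", "evaluate_recovery"]

# noise scheme name -> (sigma choices, matching noise tokens), drawn 50/50
NOISE_SCHEMES = {
    "half_clean_half_0.2": ((0.0, 0.2), ("clean", "high")),
    "half_0.02_half_0.2": ((0.02, 0.2), ("low", "high")),
}


@dataclass
class TrainConfig:
    """Optimization recipe; defaults follow the published schedule at toy scale."""

    lr_peak: float = 1e-3
    warmup_steps: int = 100       # published run used 1000; toy training scales down
    batch_size: int = 8
    noise_scheme: str = "half_clean_half_0.2"
    crop_size: int = 64           # published run used 256 (then 512)
    max_steps: int = 600
    masked_loss_only: bool = True
    clip_norm: float = 1.0
    weight_decay: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if min(self.lr_peak, self.warmup_steps, self.batch_size,
               self.crop_size, self.max_steps) <= 0:
            raise ValueError("all training settings must be positive")
        if self.noise_scheme not in NOISE_SCHEMES:
            raise ValueError(f"noise_scheme must be one of {sorted(NOISE_SCHEMES)}")


@dataclass
class TrainResult:
    model: TrunkModel
    loss_curve: list[float] = field(default_factory=list)
    lr_curve: list[float] = field(default_factory=list)
    wall_time_s: float = 0.0

    def save_loss_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("step,loss,lr\n")
            for i, (lo, lr) in enumerate(zip(self.loss_curve, self.lr_curve)):
                fh.write(f"{i},{lo:.6f},{lr:.8f}\n")


def lr_schedule(step: int, cfg: TrainConfig) -> float:
    """Linear warmup from 0 to lr_peak over warmup_steps, constant afterwards."""
    if step < 0:
        raise ValueError("step must be >= 0")
    if step >= cfg.warmup_steps:
        return cfg.lr_peak
    return cfg.lr_peak * step / cfg.warmup_steps


def _prepare_sample(bb: BackboneStructure, cfg: TrainConfig, rng: np.random.Generator):
    """Crop, noise and corrupt one structure; returns everything the loss needs."""
    if len(bb) > cfg.crop_size:
        mode = "spatial_interface" if rng.uniform() < 0.5 else "contiguous"
        bb = crop_example(bb, cfg.crop_size, mode=mode, seed=int(rng.integers(2**31 - 1)))
    sigmas, tokens = NOISE_SCHEMES[cfg.noise_scheme]
    pick = int(rng.uniform() < 0.5)
    sigma, noise_token = sigmas[pick], tokens[pick]
    noisy = add_backbone_noise(bb, sigma, seed=int(rng.integers(2**31 - 1)))
    t = float(rng.uniform())
    state = corrupt(bb.sequence, t, rng=rng)
    return noisy, state, noise_token, string_to_tokens(bb.sequence)


def train(model: TrunkModel, dataset: list[BackboneStructure],
          cfg: TrainConfig | None = None) -> TrainResult:
    """Optimize ``model`` in place on ``dataset``; returns the loss curve."""
    cfg = cfg or TrainConfig()
    if not dataset:
        raise ValueError("dataset is empty")
    if any(bb.sequence is None for bb in dataset):
        raise ValueError("every training structure needs a native sequence")
    opt = AdamW(model.parameters(), lr=0.0, weight_decay=cfg.weight_decay,
                clip_norm=cfg.clip_norm)
    master = seed_stream(cfg.seed, "train")
    result = TrainResult(model=model)
    t_start = time.time()
    for step in range(cfg.max_steps):
        rng = np.random.default_rng(master.integers(2**31 - 1))
        idx = rng.integers(0, len(dataset), size=cfg.batch_size)
        model.zero_grad()
        step_loss = 0.0
        for i in idx:
            noisy, state, noise_token, native = _prepare_sample(dataset[i], cfg, rng)
            feats = featurize(noisy, state, noise_token, model.feat_config)
            logits = model.forward(feats, build_frames(noisy))
            mask = state.masked if cfg.masked_loss_only else None
            loss = fm_loss(logits, native, mask) * (1.0 / cfg.batch_size)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at step {step} (sample {i}, t={state.t:.3f})")
            loss.backward()
            step_loss += float(loss.data)
        opt.lr = lr_schedule(step, cfg)
        opt.step()
        result.loss_curve.append(step_loss)
        result.lr_curve.append(opt.lr)
    result.wall_time_s = time.time() - t_start
    return result


def evaluate_recovery(model: TrunkModel, backbones: list[BackboneStructure],
                      temperature: float = 0.1, n_steps: int = 10,
                      seed: int = 0) -> float:
    """Mean native-sequence recovery of one design per held-out backbone."""
    from .design_metrics import sequence_recovery

    total = 0.0
    for i, bb in enumerate(backbones):
        cfg = SamplerConfig(n_steps=n_steps, temperature=temperature, seed=seed + i)
        res = design_sequences(bb, model, 1, cfg)
        total += sequence_recovery(res.sequences[0], bb.sequence)
    return total / len(backbones)
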