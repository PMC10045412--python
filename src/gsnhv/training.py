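"""Training loop: Adam on the joint loss over synthetic patches.

Weights are Kaiming-initialised and bias-free; the optimizer is Adam
with L2 weight decay.  A single seed drives initialisation, shuffling
and augmentation, so a run is reproducible end to end.  Each step's
loss breakdown is appended to an in-memory history and, optionally, a
JSONL log file.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .nn import Tensor, Adam
from .blocks import StageSpec
from .losses import LossWeights, joint_loss
from .network import GSNHVNet, NetworkOutputs
from .postprocess import (PostprocessParams, InstancePrediction,
                          instance_segment, assign_types)
from .synthetic import LabeledPatch, augment
from .targets import make_training_targets

logger = logging.getLogger(__name__)

__all__ = ["train_model", "infer_patch", "patch_batches"]


def _stack_targets(patches: list[LabeledPatch], n_types: int) -> dict:
    per = [make_training_targets(p.instances, p.types, n_types) for p in patches]
    return {key: np.stack([t[key] for t in per]) for key in per[0]}


def patch_batches(n: int, batch_size: int, rng: np.random.Generator):
    """Shuffled index batches covering all n patches (last may be short)."""
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]


def train_model(patches: list[LabeledPatch],
                n_types: int = 3,
                spec: StageSpec = StageSpec(),
                weights: LossWeights = LossWeights(),
                epochs: int = 10,
                batch_size: int = 4,
                lr: float = 1e-4,
                weight_decay: float = 0.1,
                seed: int = 0,
                augment_ops: list[str] | None = None,
                with_classification: bool = True,
                log_path: str | Path | None = None,
                net: GSNHVNet | None = None) -> tuple[GSNHVNet, list[dict]]:
    """Train a network on labelled patches and return it with the
    per-step loss history.

    Raises RuntimeError with the offending breakdown if the loss ever
    turns non-finite.
    """
    if not patches:
        raise ValueError("no training patches supplied")
    rng = np.random.default_rng(seed)
    if net is None:
        net = GSNHVNet(n_types=n_types, spec=spec,
                       with_classification=with_classification,
                       seed=int(rng.integers(2 ** 31)))
    net.train()
    optimizer = Adam(net.parameters(), lr=lr, weight_decay=weight_decay)
    images = np.stack([p.image.transpose(2, 0, 1) for p in patches])
    targets = _stack_targets(patches, n_types)

    history: list[dict] = []
    log_file = open(log_path, "a") if log_path is not None else None
    step = 0
    try:
        for epoch in range(epochs):
            for idx in patch_batches(len(patches), batch_size, rng):
                if augment_ops:
                    aug = [augment(patches[i], augment_ops,
                                   int(rng.integers(2 ** 31))) for i in idx]
                    batch_imgs = np.stack(
                        [p.image.transpose(2, 0, 1) for p in aug])
                    batch_tg = _stack_targets(aug, n_types)
                else:
                    batch_imgs = images[idx]
                    batch_tg = {k: v[idx] for k, v in targets.items()}
                net.zero_grad()
                outputs = net(Tensor(batch_imgs))
                loss, breakdown = joint_loss(outputs, batch_tg, weights)
                if not np.isfinite(breakdown["total"]):
                    raise RuntimeError(
                        f"non-finite loss at step {step}: {breakdown}")
                loss.backward()
                optimizer.step()
                record = {"step": step, "epoch": epoch, **breakdown}
                history.append(record)
                if log_file is not None:
                    log_file.write(json.dumps(record) + "\n")
                step += 1
            logger.info("epoch %d/%d  joint loss %.4f",
                        epoch + 1, epochs, history[-1]["total"])
    finally:
        if log_file is not None:
            log_file.close()
    return net, history


def infer_patch(net: GSNHVNet, image: np.ndarray,
                params: PostprocessParams = PostprocessParams()
                ) -> tuple[InstancePrediction, NetworkOutputs]:
    """Segment (and type, if the network classifies) one (H, W, 3) image."""
    outputs = net.predict(image.transpose(2, 0, 1)[None])
    q_fg = outputs.foreground[0]
    instances = instance_segment(q_fg, outputs.hv(), params)
    type_map = outputs.type_map()
    if type_map is not None:
        prediction = assign_types(instances, type_map)
    else:
        prediction = InstancePrediction(instances=instances)
    return prediction, outputs
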