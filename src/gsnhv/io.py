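"""Checkpoints and prediction files.

Checkpoints are ``.npz`` archives holding the flat state dict plus a
JSON metadata string (network hyper-parameters), so a network can be
rebuilt without the original config.  Instance maps travel as 16-bit
single-channel PNG with label 0 = background — the bit-exact contract
the evaluator relies on.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import imageio.v3 as iio

from .blocks import StageSpec
from .network import GSNHVNet
from .postprocess import InstancePrediction

__all__ = ["save_checkpoint", "load_checkpoint", "write_prediction",
           "read_instance_map", "write_instance_map"]


def save_checkpoint(net: GSNHVNet, path: str | Path) -> None:
    meta = {
        "n_types": net.n_types,
        "with_classification": net.with_classification,
        "rgs_counts": list(net.spec.rgs_counts),
        "stage_channels": list(net.spec.stage_channels),
        "dgm_counts": list(net.spec.dgm_counts),
        "growth": net.spec.growth,
    }
    state = net.state_dict()
    state["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path: str | Path) -> GSNHVNet:
    archive = np.load(path)
    meta = json.loads(bytes(archive["__meta__"]).decode())
    spec = StageSpec(rgs_counts=tuple(meta["rgs_counts"]),
                     stage_channels=tuple(meta["stage_channels"]),
                     dgm_counts=tuple(meta["dgm_counts"]),
                     growth=meta["growth"])
    net = GSNHVNet(n_types=meta["n_types"], spec=spec,
                   with_classification=meta["with_classification"])
    net.load_state_dict({k: archive[k] for k in archive.files
                         if k != "__meta__"})
    return net


def write_instance_map(instances: np.ndarray, path: str | Path) -> None:
    inst = np.asarray(instances)
    if inst.max() > np.iinfo(np.uint16).max:
        raise ValueError("instance labels exceed 16-bit range")
    iio.imwrite(Path(path), inst.astype(np.uint16))


def read_instance_map(path: str | Path) -> np.ndarray:
    return iio.imread(Path(path)).astype(np.int32)


def write_prediction(pred: InstancePrediction, stem: Path) -> None:
    """Write ``<stem>.png`` (16-bit instance map) and ``<stem>.json``
    (per-instance label, type, confidence, centroid, area)."""
    write_instance_map(pred.instances, stem.with_suffix(".png"))
    records = []
    for label in np.unique(pred.instances):
        if label == 0:
            continue
        ys, xs = np.nonzero(pred.instances == label)
        records.append({
            "label": int(label),
            "type": pred.types.get(int(label)),
            "confidence": pred.type_confidence.get(int(label)),
            "centroid": [float(xs.mean()), float(ys.mean())],
            "area": int(ys.size),
        })
    stem.with_suffix(".json").write_text(json.dumps(records, indent=2))
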