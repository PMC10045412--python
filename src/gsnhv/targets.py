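"""Training targets derived from instance/type rasters.

The three decoder branches learn from three rasters computed here:

* a binary nuclei mask (semantic segmentation branch),
* the HV map — per-pixel signed horizontal/vertical offsets from each
  pixel to the mass centre of its nucleus, normalised per instance to
  [-1, 1] (regression branch),
* a per-pixel one-hot type raster including a background channel
  (classification branch).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

__all__ = ["compute_hv_map", "binarize", "type_target",
           "make_training_targets", "save_hv_map", "load_hv_map"]


def compute_hv_map(instances: np.ndarray) -> np.ndarray:
    """Horizontal/vertical signed-distance map to instance mass centres.

    For each labelled instance, channel 0 holds (x - cx) and channel 1
    (y - cy), each divided by the instance's maximum absolute offset on
    that axis so values span [-1, 1]; background pixels are 0.  The mass
    centre is the unweighted centroid of the instance's pixel coordinates
    (x = column, y = row, 0-based).

    Parameters
    ----------
    instances : 2-D integer array, 0 background, positive labels.

    Returns
    -------
    (H, W, 2) float32 array.
    """
    instances = np.asarray(instances)
    hv = np.zeros(instances.shape + (2,), dtype=np.float32)
    for label in np.unique(instances):
        if label == 0:
            continue
        ys, xs = np.nonzero(instances == label)
        dx = xs - xs.mean()
        dy = ys - ys.mean()
        mx = np.abs(dx).max()
        my = np.abs(dy).max()
        hv[ys, xs, 0] = dx / mx if mx > 0 else 0.0
        hv[ys, xs, 1] = dy / my if my > 0 else 0.0
    return hv


def binarize(instances: np.ndarray) -> np.ndarray:
    """Binary nuclei mask: 1 where any instance is present."""
    return (np.asarray(instances) > 0).astype(np.uint8)


def type_target(types: np.ndarray, n_types: int) -> np.ndarray:
    """Per-pixel one-hot raster of shape (H, W, n_types + 1).

    Channel 0 is background; channel t is nucleus type t.  Raises on
    type values outside {0..n_types}.
    """
    types = np.asarray(types)
    if types.min() < 0 or types.max() > n_types:
        raise ValueError(
            f"type values must lie in [0, {n_types}], got range "
            f"[{types.min()}, {types.max()}]")
    onehot = np.zeros(types.shape + (n_types + 1,), dtype=np.float32)
    h, w = types.shape
    onehot[np.arange(h)[:, None], np.arange(w)[None, :], types] = 1.0
    return onehot


def make_training_targets(instances: np.ndarray, types: np.ndarray,
                          n_types: int) -> dict:
    """Bundle all branch targets in channel-first layout.

    Returns a dict with `mask_onehot` (2, H, W), `hv` (2, H, W),
    `type_onehot` (n_types+1, H, W), and the binary `mask` (H, W).
    """
    mask = binarize(instances)
    mask_onehot = np.stack([1 - mask, mask]).astype(np.float32)
    hv = compute_hv_map(instances).transpose(2, 0, 1)
    tgt_types = type_target(types, n_types).transpose(2, 0, 1)
    return {"mask_onehot": mask_onehot, "hv": hv,
            "type_onehot": tgt_types, "mask": mask.astype(np.float32)}


def save_hv_map(hv: np.ndarray, path: str | Path) -> None:
    """Cache an (H, W, 2) HV map as a 2-channel 32-bit float TIFF."""
    hv = np.asarray(hv, dtype=np.float32)
    if hv.ndim != 3 or hv.shape[-1] != 2:
        raise ValueError("expected an (H, W, 2) HV map")
    tifffile.imwrite(Path(path), hv)


def load_hv_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.float32)
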