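"""The joint multi-task loss.

L_Join = L_NSS + L_HV + L_NC with

* L_NSS = lambda_a * BCE(q, X) + lambda_b * Dice(q, X)
* L_HV  = lambda_c * MSE(p, Gamma) + lambda_d * MSGE(p, Gamma; mask)
* L_NC  = lambda_e * BCE(r, T) + lambda_f * Dice(r, T)

BCE is the mean binary cross-entropy over every pixel and channel;
Dice aggregates intersections and sums over the whole tensor with an
epsilon guarding empty denominators; MSE is the mean squared HV error;
MSGE is the mean squared difference of the Sobel gradients of the HV
maps (horizontal derivative on the horizontal channel, vertical on the
vertical channel), restricted to nuclei pixels — it sharpens exactly
the sign flips the watershed later thresholds.

All functions accept autodiff tensors (training) or plain arrays
(evaluation) and return a scalar tensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor
from .postprocess import sobel_kernels

__all__ = ["LossWeights", "bce_loss", "dice_loss", "mse_loss", "msge_loss",
           "joint_loss"]

_CLIP = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Per-term weights; the defaults are the tuned values (1,1,1,1,2,1)
    with the Dice epsilon 1e-4."""

    lambda_a: float = 1.0   # BCE, segmentation branch
    lambda_b: float = 1.0   # Dice, segmentation branch
    lambda_c: float = 1.0   # MSE, HV branch
    lambda_d: float = 1.0   # MSGE, HV branch
    lambda_e: float = 2.0   # BCE, classification branch
    lambda_f: float = 1.0   # Dice, classification branch
    epsilon: float = 1e-4

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        for name in ("lambda_a", "lambda_b", "lambda_c", "lambda_d",
                     "lambda_e", "lambda_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def bce_loss(y, x) -> Tensor:
    """Mean over all pixels and channels of
    -[X log Y + (1 - X) log(1 - Y)], with Y clamped away from {0, 1}."""
    y, x = _as_tensor(y), _as_tensor(x)
    if y.shape != x.shape:
        raise ValueError("prediction and target shapes differ")
    yc = y.clamp(_CLIP, 1.0 - _CLIP)
    ll = x * yc.log() + (1.0 - x) * (1.0 - yc).log()
    return -ll.mean()


def dice_loss(y, x, epsilon: float = 1e-4) -> Tensor:
    """1 - (2 sum(YX) + eps) / (sum(Y) + sum(X) + eps), aggregated over
    the whole tensor; the epsilon makes two empty masks score 0."""
    y, x = _as_tensor(y), _as_tensor(x)
    if y.shape != x.shape:
        raise ValueError("prediction and target shapes differ")
    inter = (y * x).sum()
    return 1.0 - (2.0 * inter + epsilon) / (y.sum() + x.sum() + epsilon)


def mse_loss(p, gamma) -> Tensor:
    """Mean squared HV regression error over all pixels and channels."""
    p, gamma = _as_tensor(p), _as_tensor(gamma)
    if p.shape != gamma.shape:
        raise ValueError("prediction and target shapes differ")
    return ((p - gamma) ** 2).mean()


def msge_loss(p, gamma, mask, sobel_ksize: int = 5) -> Tensor:
    """Mean squared gradient error of the HV maps on nuclei pixels.

    The horizontal Sobel response of (p_h - Gamma_h) plus the vertical
    response of (p_v - Gamma_v), squared and averaged over the mask.
    Reflect padding keeps a constant offset exactly gradient-free; an
    empty mask yields 0.

    Parameters
    ----------
    p, gamma : (N, 2, H, W) HV prediction and target.
    mask : (N, H, W) binary nuclei mask from the ground truth.
    """
    p, gamma = _as_tensor(p), _as_tensor(gamma)
    mask = np.asarray(mask.data if isinstance(mask, Tensor) else mask)
    m = float(mask.sum())
    if m == 0:
        return Tensor(np.zeros(()))
    kx, ky = sobel_kernels(sobel_ksize)
    pad = kx.shape[0] // 2
    diff = p - gamma
    # fixed-kernel depthwise convolution: one Sobel kernel per channel
    weight = Tensor(np.stack([kx, ky])[:, None].astype(np.float64
                    if diff.dtype == np.float64 else np.float32))
    grads = diff.pad_reflect2d(pad).depthwise_conv2d(weight)
    masked = grads * Tensor(mask[:, None])
    return (masked ** 2).sum() / m


def joint_loss(outputs, targets: dict, weights: LossWeights = LossWeights(),
               sobel_ksize: int = 5) -> tuple[Tensor, dict]:
    """Weighted sum of all branch losses plus a per-term breakdown.

    Parameters
    ----------
    outputs : NetworkOutputs (r may be None for segmentation-only).
    targets : dict with 'mask_onehot' (N,2,H,W), 'hv' (N,2,H,W),
        'mask' (N,H,W) and, when classifying, 'type_onehot' (N,K+1,H,W).

    Returns
    -------
    (total, breakdown) — scalar tensor and a float dict for logging.
    """
    w = weights
    terms = {
        "bce_q": bce_loss(outputs.q, targets["mask_onehot"]),
        "dice_q": dice_loss(outputs.q, targets["mask_onehot"], w.epsilon),
        "mse": mse_loss(outputs.p, targets["hv"]),
        "msge": msge_loss(outputs.p, targets["hv"], targets["mask"],
                          sobel_ksize),
    }
    total = (w.lambda_a * terms["bce_q"] + w.lambda_b * terms["dice_q"]
             + w.lambda_c * terms["mse"] + w.lambda_d * terms["msge"])
    if outputs.r is not None:
        terms["bce_r"] = bce_loss(outputs.r, targets["type_onehot"])
        terms["dice_r"] = dice_loss(outputs.r, targets["type_onehot"],
                                    w.epsilon)
        total = total + w.lambda_e * terms["bce_r"] + w.lambda_f * terms["dice_r"]
    breakdown = {name: float(t.data) for name, t in terms.items()}
    breakdown["total"] = float(total.data)
    return total, breakdown
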