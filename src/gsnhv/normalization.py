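"""Switchable normalization (SN).

SN normalizes each feature map with a learned convex mixture of the
statistics used by instance normalization (per sample-channel, over
H,W), layer normalization (per sample, over C,H,W), and batch
normalization (per channel, over N,H,W):

    x_hat = gamma * (x - sum_k w_k mu_k) / sqrt(sum_k w'_k var_k + eps) + beta

with w = softmax(mean_logits), w' = softmax(var_logits) over
k in {IN, LN, BN}.  Because the mixture can shift weight away from the
minibatch statistics, the layer stays stable at batch size 1 where
plain BN degenerates.  Each layer owns its logits, so different depths
can settle on different normalizers.
"""

from __future__ import annotations

import numpy as np

from .nn import Module, Parameter, Tensor

__all__ = ["SwitchableNorm2d"]


def _softmax3(logits: Tensor) -> Tensor:
    shifted = logits - Tensor(logits.data.max())
    e = shifted.exp()
    return e / e.sum()


class SwitchableNorm2d(Module):
    """SN over NCHW feature maps.

    Parameters: per-channel scale gamma and shift beta, plus three
    mixture logits each for the mean and the variance.  Running BN
    moments (momentum 0.9) supply the minibatch statistics in
    inference mode.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones((1, channels, 1, 1), dtype=np.float32))
        self.beta = Parameter(np.zeros((1, channels, 1, 1), dtype=np.float32))
        # logit order: (IN, LN, BN)
        self.mean_logits = Parameter(np.zeros(3, dtype=np.float32))
        self.var_logits = Parameter(np.zeros(3, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        mu_in = x.mean(axis=(2, 3), keepdims=True)
        var_in = ((x - mu_in) ** 2).mean(axis=(2, 3), keepdims=True)
        mu_ln = x.mean(axis=(1, 2, 3), keepdims=True)
        var_ln = ((x - mu_ln) ** 2).mean(axis=(1, 2, 3), keepdims=True)
        if self.training:
            mu_bn = x.mean(axis=(0, 2, 3), keepdims=True)
            var_bn = ((x - mu_bn) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (m * self.running_mean
                                 + (1 - m) * mu_bn.data.reshape(-1))
            self.running_var = (m * self.running_var
                                + (1 - m) * var_bn.data.reshape(-1))
        else:
            mu_bn = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var_bn = Tensor(self.running_var.reshape(1, -1, 1, 1))

        w = _softmax3(self.mean_logits)
        wv = _softmax3(self.var_logits)
        mu = w[0] * mu_in + w[1] * mu_ln + w[2] * mu_bn
        var = wv[0] * var_in + wv[1] * var_ln + wv[2] * var_bn
        x_hat = (x - mu) / (var + self.eps).sqrt()
        return self.gamma * x_hat + self.beta
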