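"""The multi-task encoder-decoder for joint nuclei segmentation and
classification.

Encoder: CSR stem -> four residual-ghost stages (1, 2, 3, 1 RGS; stages
2-4 downsample x2, so the bottleneck sits at 1/8 resolution) -> a 1x1
bottleneck convolution.

Decoder: three structurally identical branches — NSS (2-channel softmax
nuclei probability), HV (2-channel tanh regression of the signed
distances to mass centres), NC (K+1-channel softmax type probability).
Each branch takes three nearest-neighbour x2 up-sampling steps back to
input resolution, concatenates the matching encoder stage feature at
each step (skip connections), and runs a dense-ghost module with 8 and
4 DGS after the first and second step respectively.

Everything is fully convolutional: any input whose sides are divisible
by 8 produces output maps of the same spatial size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Module, Conv2d, Tensor, concat, softmax, no_grad
from .blocks import (StageSpec, CSR, ResidualGhostModule, DenseGhostModule)

__all__ = ["NetworkOutputs", "DecoderBranch", "GSNHVNet", "build_network"]


@dataclass
class NetworkOutputs:
    """Branch outputs, channel-first.

    q : (N, 2, H, W) softmax nuclei probability (channel 1 = foreground)
    p : (N, 2, H, W) tanh-bounded HV regression (channel 0 horizontal)
    r : (N, K+1, H, W) softmax type probability, or None for a
        segmentation-only build
    """

    q: Tensor
    p: Tensor
    r: Tensor | None

    @property
    def foreground(self) -> np.ndarray:
        return self.q.data[:, 1]

    def hv(self) -> np.ndarray:
        """HV map of sample 0 in (H, W, 2) layout for post-processing."""
        return self.p.data[0].transpose(1, 2, 0)

    def type_map(self) -> np.ndarray | None:
        """Type probabilities of sample 0 in (H, W, K+1) layout."""
        return None if self.r is None else self.r.data[0].transpose(1, 2, 0)


class DecoderBranch(Module):
    """One up-sampling branch with skip concatenation and dense modules."""

    def __init__(self, spec: StageSpec, out_channels: int, rng,
                 head_activation: str):
        super().__init__()
        ch = spec.stage_channels
        g = spec.growth
        self.head_activation = head_activation
        # step 1: 1/8 -> 1/4, merge encoder stage 3, dense module of 8
        self.reduce1 = CSR(ch[3] + ch[2], ch[2], 1, rng)
        self.dgm1 = DenseGhostModule(ch[2], spec.dgm_counts[0], g, rng)
        self.squeeze1 = CSR(self.dgm1.out_channels, ch[1], 1, rng)
        # step 2: 1/4 -> 1/2, merge encoder stage 2, dense module of 4
        self.reduce2 = CSR(ch[1] + ch[1], ch[1], 1, rng)
        self.dgm2 = DenseGhostModule(ch[1], spec.dgm_counts[1], g, rng)
        self.squeeze2 = CSR(self.dgm2.out_channels, ch[0], 1, rng)
        # step 3: 1/2 -> 1/1, merge encoder stage 1
        self.fuse3 = CSR(ch[0] + ch[0], ch[0], 3, rng)
        self.head = Conv2d(ch[0], out_channels, 1, rng=rng)

    def forward(self, bottleneck: Tensor, skips: list[Tensor]) -> Tensor:
        x = bottleneck.upsample2()
        x = self.squeeze1(self.dgm1(self.reduce1(concat([x, skips[2]], axis=1))))
        x = x.upsample2()
        x = self.squeeze2(self.dgm2(self.reduce2(concat([x, skips[1]], axis=1))))
        x = x.upsample2()
        x = self.fuse3(concat([x, skips[0]], axis=1))
        logits = self.head(x)
        if self.head_activation == "softmax":
            return softmax(logits, axis=1)
        return logits.tanh()


class GSNHVNet(Module):
    """Encoder-decoder with NSS, HV and (optionally) NC branches."""

    def __init__(self, n_types: int = 3, spec: StageSpec = StageSpec(),
                 with_classification: bool = True, seed: int = 0):
        super().__init__()
        if n_types < 1:
            raise ValueError("n_types must be >= 1")
        rng = np.random.default_rng(seed)
        self.n_types = n_types
        self.spec = spec
        self.with_classification = with_classification
        ch = spec.stage_channels
        self.stem = CSR(3, ch[0], 3, rng)
        self.stage1 = ResidualGhostModule(ch[0], ch[0], spec.rgs_counts[0],
                                          rng, stride=1)
        self.stage2 = ResidualGhostModule(ch[0], ch[1], spec.rgs_counts[1],
                                          rng, stride=2)
        self.stage3 = ResidualGhostModule(ch[1], ch[2], spec.rgs_counts[2],
                                          rng, stride=2)
        self.stage4 = ResidualGhostModule(ch[2], ch[3], spec.rgs_counts[3],
                                          rng, stride=2)
        self.bottleneck = Conv2d(ch[3], ch[3], 1, rng=rng)
        self.nss = DecoderBranch(spec, 2, rng, "softmax")
        self.hv_branch = DecoderBranch(spec, 2, rng, "tanh")
        self.nc = (DecoderBranch(spec, n_types + 1, rng, "softmax")
                   if with_classification else None)

    def forward(self, image: Tensor | np.ndarray) -> NetworkOutputs:
        x = image if isinstance(image, Tensor) else Tensor(image)
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("expected an (N, 3, H, W) image tensor")
        if x.shape[2] % 8 or x.shape[3] % 8:
            raise ValueError("spatial size must be divisible by 8")
        s1 = self.stage1(self.stem(x))
        s2 = self.stage2(s1)
        s3 = self.stage3(s2)
        s4 = self.stage4(s3)
        bottleneck = self.bottleneck(s4)
        skips = [s1, s2, s3]
        q = self.nss(bottleneck, skips)
        p = self.hv_branch(bottleneck, skips)
        r = self.nc(bottleneck, skips) if self.nc is not None else None
        return NetworkOutputs(q=q, p=p, r=r)

    def predict(self, image: np.ndarray) -> NetworkOutputs:
        """Inference-mode forward without building the autodiff graph."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                return self.forward(image)
        finally:
            self.train(was_training)


def build_network(n_types: int, spec: StageSpec = StageSpec(),
                  with_classification: bool = True, seed: int = 0) -> GSNHVNet:
    """Construct the network (thin functional wrapper)."""
    return GSNHVNet(n_types=n_types, spec=spec,
                    with_classification=with_classification, seed=seed)
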