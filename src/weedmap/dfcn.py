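"""Dilated fully convolutional networks for 3-class field labeling.

The segmentation trunk is a residual (ResNet-style) or VGG-style classifier
adapted to dense prediction: the last two downsampling strides are removed
(output stride 8 instead of 32) and the convolutions of the affected stages
are dilated (rate 2 in the fourth stage, rate 4 in the fifth) so their field
of view is unchanged.  The classifier head is replaced by one or more
parallel dilated 3x3 score convolutions ("ASPP" head) producing one channel
per class, fused by summation; the coarse score map (1/8 resolution, e.g.
125 x 125 for a 1000 x 1000 tile) is bilinearly upsampled to full resolution.

An FCN-8s-style skip variant of the VGG trunk is provided for comparison:
score maps from the 1/8, 1/16 and 1/32 feature levels are fused by repeated
2x upsampling and summation, then upsampled to full resolution.

``width_scale`` and ``block_counts`` scale the channel widths and stage
depths so the full topology can be exercised on one CPU; the spatial
behaviour (output stride, score-map sizes) is independent of both.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import functional as F
from .nn.layers import (
    ASPPHead,
    BilinearUpsample,
    Bottleneck,
    Conv2d,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
)

CLASS_NAMES = ("others", "rice", "weeds")

# named ASPP presets: single standard conv, single rate-12 branch,
# four small rates, four large rates
ASPP_PRESETS: dict[str, tuple[int, ...]] = {
    "aspp-1": (1,),
    "aspp-12": (12,),
    "aspp-s": (2, 4, 8, 12),
    "aspp-l": (6, 12, 18, 24),
}


class SpecError(ValueError):
    """Raised for an inconsistent network specification."""


@dataclass(frozen=True)
class ASPPConfig:
    """Head configuration: dilation rates of the parallel 3x3 score branches."""

    rates: tuple[int, ...] = (1,)

    @classmethod
    def preset(cls, name: str) -> "ASPPConfig":
        try:
            return cls(rates=ASPP_PRESETS[name.lower()])
        except KeyError:
            raise SpecError(f"unknown ASPP preset {name!r}; known: {sorted(ASPP_PRESETS)}")

    def __post_init__(self) -> None:
        if len(self.rates) < 1 or any(int(r) < 1 for r in self.rates):
            raise SpecError(f"ASPP rates must be >= 1 and non-empty, got {self.rates}")


# full-width stage channels of the 101-layer residual trunk:
# (bottleneck mid width, output width) per stage
_RESNET_STAGES = ((64, 256), (128, 512), (256, 1024), (512, 2048))
_VGG_STAGES = (64, 128, 256, 512, 512)


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of a segmentation network.

    ``stage_strides``/``stage_rates`` refer to the four residual stages
    (or the five VGG pool layers) after the stem.  The product of all
    downsampling strides must be 8 for the adapted families and 32 for the
    pre-adaptation baseline.
    """

    family: str = "resnet_adapted"
    width_scale: float = 1.0
    block_counts: tuple[int, ...] = (3, 4, 23, 3)
    stage_strides: tuple[int, ...] = (1, 2, 1, 1)
    stage_rates: tuple[int, ...] = (1, 1, 2, 4)
    head: ASPPConfig = field(default_factory=ASPPConfig)
    n_classes: int = 3

    def stride_product(self) -> int:
        if self.family in ("resnet_adapted", "resnet_baseline"):
            stem = 4  # 7x7/2 conv + stride-2 max pool
            return stem * int(np.prod(self.stage_strides))
        # VGG families: strides are the five pool strides
        return int(np.prod(self.stage_strides))

    def __post_init__(self) -> None:
        if self.family not in ("resnet_adapted", "resnet_baseline", "vgg16_adapted", "fcn8s"):
            raise SpecError(f"unknown family {self.family!r}")
        if self.width_scale <= 0:
            raise SpecError("width_scale must be positive")
        expect_blocks = 4 if self.family.startswith("resnet") else 5
        if len(self.block_counts) != expect_blocks:
            raise SpecError(
                f"{self.family} needs {expect_blocks} stage block counts, got {self.block_counts}"
            )
        if len(self.stage_strides) != len(self.block_counts) or len(self.stage_rates) != len(
            self.block_counts
        ):
            raise SpecError("stage_strides/stage_rates must match block_counts in length")
        sp = self.stride_product()
        if self.family in ("resnet_adapted", "vgg16_adapted") and sp != 8:
            raise SpecError(f"adapted families require downsampling stride product 8, got {sp}")
        if self.family in ("resnet_baseline", "fcn8s") and sp != 32:
            raise SpecError(f"baseline families require stride product 32, got {sp}")


def resnet_spec(
    adapted: bool = True,
    width_scale: float = 1.0,
    block_counts: tuple[int, int, int, int] = (3, 4, 23, 3),
    head: ASPPConfig | None = None,
    n_classes: int = 3,
) -> NetworkSpec:
    """Residual-trunk spec; ``adapted=False`` keeps the stride-32 baseline."""
    if adapted:
        return NetworkSpec(
            family="resnet_adapted",
            width_scale=width_scale,
            block_counts=block_counts,
            stage_strides=(1, 2, 1, 1),
            stage_rates=(1, 1, 2, 4),
            head=head or ASPPConfig(),
            n_classes=n_classes,
        )
    return NetworkSpec(
        family="resnet_baseline",
        width_scale=width_scale,
        block_counts=block_counts,
        stage_strides=(1, 2, 2, 2),
        stage_rates=(1, 1, 1, 1),
        head=head or ASPPConfig(),
        n_classes=n_classes,
    )


def vgg16_spec(
    width_scale: float = 1.0,
    block_counts: tuple[int, ...] = (2, 2, 3, 3, 3),
    head: ASPPConfig | None = None,
    n_classes: int = 3,
) -> NetworkSpec:
    """Adapted VGG-16 spec: pool4/pool5 stride 1, fifth stage dilated (rate 2)."""
    return NetworkSpec(
        family="vgg16_adapted",
        width_scale=width_scale,
        block_counts=block_counts,
        stage_strides=(2, 2, 2, 1, 1),
        stage_rates=(1, 1, 1, 1, 2),
        head=head or ASPPConfig(),
        n_classes=n_classes,
    )


def fcn8s_spec(
    width_scale: float = 1.0,
    block_counts: tuple[int, ...] = (2, 2, 3, 3, 3),
    n_classes: int = 3,
) -> NetworkSpec:
    """FCN-8s skip variant on the stride-32 VGG trunk."""
    return NetworkSpec(
        family="fcn8s",
        width_scale=width_scale,
        block_counts=block_counts,
        stage_strides=(2, 2, 2, 2, 2),
        stage_rates=(1, 1, 1, 1, 1),
        head=ASPPConfig(),
        n_classes=n_classes,
    )


@dataclass
class ScoreMap:
    """Per-class raw scores at reduced resolution (h, w, C)."""

    scores: np.ndarray
    stride_to_input: int = 8

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.scores.shape[0], self.scores.shape[1]


@dataclass
class ProbabilityMap:
    """Per-pixel class probabilities at full resolution (H, W, C)."""

    probs: np.ndarray


def _scale(c: int, width_scale: float) -> int:
    return max(1, int(round(c * width_scale)))


class SegmentationModel(Module):
    """Trunk + head; forward maps (N, 3, H, W) floats to score maps."""

    def __init__(self, spec: NetworkSpec, rng: np.random.Generator) -> None:
        super().__init__()
        self.spec = spec
        ws = spec.width_scale
        if spec.family.startswith("resnet"):
            self.stem = self.add_child(
                "stem",
                Sequential(
                    Conv2d(3, _scale(64, ws), 7, stride=2, rng=rng),
                    ReLU(),
                    MaxPool2d(3, 2),
                ),
            )
            c_in = _scale(64, ws)
            stages = []
            for s_idx, (n_blocks, stride, rate) in enumerate(
                zip(spec.block_counts, spec.stage_strides, spec.stage_rates)
            ):
                mid = _scale(_RESNET_STAGES[s_idx][0], ws)
                out = _scale(_RESNET_STAGES[s_idx][1], ws)
                blocks = []
                for b in range(n_blocks):
                    blocks.append(
                        Bottleneck(
                            c_in if b == 0 else out,
                            mid,
                            out,
                            stride=stride if b == 0 else 1,
                            rate=rate,
                            rng=rng,
                        )
                    )
                c_in = out
                stages.append(Sequential(*blocks))
            self.trunk = self.add_child("trunk", Sequential(*stages))
            self.head = self.add_child(
                "head", ASPPHead(c_in, spec.n_classes, spec.head.rates, rng=rng)
            )
            self._skip_levels = None
        else:
            # VGG-style trunk: per-stage [3x3 conv]*n + pool
            c_in = 3
            stages = []
            for s_idx, (n_blocks, stride, rate) in enumerate(
                zip(spec.block_counts, spec.stage_strides, spec.stage_rates)
            ):
                out = _scale(_VGG_STAGES[s_idx], ws)
                mods: list[Module] = []
                for _ in range(n_blocks):
                    mods.append(Conv2d(c_in, out, 3, rate=rate, rng=rng))
                    mods.append(ReLU())
                    c_in = out
                mods.append(MaxPool2d(2, stride))
                stages.append(Sequential(*mods))
            self.stages = stages
            self.trunk = self.add_child("trunk", Sequential(*stages))
            if spec.family == "fcn8s":
                # score convs on the 1/8 (pool3) and 1/16 (pool4) levels
                self.head = self.add_child(
                    "head", Conv2d(c_in, spec.n_classes, 3, rng=rng)
                )
                self.score_pool3 = self.add_child(
                    "score_pool3", Conv2d(_scale(_VGG_STAGES[2], ws), spec.n_classes, 1, rng=rng)
                )
                self.score_pool4 = self.add_child(
                    "score_pool4", Conv2d(_scale(_VGG_STAGES[3], ws), spec.n_classes, 1, rng=rng)
                )
            else:
                self.head = self.add_child(
                    "head", ASPPHead(c_in, spec.n_classes, spec.head.rates, rng=rng)
                )

    # -- forward -----------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.spec.family.startswith("resnet"):
            return self.head(self.trunk(self.stem(x)))
        if self.spec.family == "fcn8s":
            return self._forward_fcn8s(x)
        return self.head(self.trunk(x))

    def _forward_fcn8s(self, x: np.ndarray) -> np.ndarray:
        h_in, w_in = x.shape[2], x.shape[3]
        feats = x
        taps = {}
        for idx, stage in enumerate(self.stages):
            feats = stage(feats)
            taps[idx] = feats
        s32 = self.head(feats)  # 1/32
        s16 = self.score_pool4(taps[3])  # 1/16
        s8 = self.score_pool3(taps[2])  # 1/8
        up16, _ = F.bilinear_upsample_forward(s32, s16.shape[2], s16.shape[3])
        f16 = up16 + s16
        up8, _ = F.bilinear_upsample_forward(f16, s8.shape[2], s8.shape[3])
        f8 = up8 + s8
        out, _ = F.bilinear_upsample_forward(f8, h_in, w_in)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.spec.family.startswith("resnet"):
            return self.stem.backward(self.trunk.backward(self.head.backward(dy)))
        if self.spec.family == "fcn8s":
            raise NotImplementedError("training the skip variant is not supported")
        return self.trunk.backward(self.head.backward(dy))

    # -- inference helpers ---------------------------------------------------
    def score_map(self, image: np.ndarray) -> ScoreMap:
        """Forward a single H x W x 3 image (uint8 or float in [0,1])."""
        x = _to_input(image)
        scores = self.forward(x)[0].transpose(1, 2, 0)
        return ScoreMap(scores=scores, stride_to_input=self.spec.stride_product())


def _to_input(image: np.ndarray) -> np.ndarray:
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {image.shape}")
    x = image.astype(np.float64)
    if image.dtype == np.uint8:
        x = x / 255.0
    return x.transpose(2, 0, 1)[None]


def build_network(spec: NetworkSpec, seed: int = 0) -> SegmentationModel:
    """Instantiate a trainable model from a spec (deterministic given seed)."""
    return SegmentationModel(spec, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# reference-level operations
# ---------------------------------------------------------------------------

def effective_kernel_size(k: int, rate: int) -> int:
    """Field of view K1 = (K - 1)(r - 1) + K of a K x K kernel at dilation r."""
    return F.effective_kernel_size(k, rate)


def atrous_convolve(x: np.ndarray, w: np.ndarray, rate: int = 1) -> np.ndarray:
    """Reference dilated convolution of a 2-D signal ("valid" region).

    Direct summation semantics: y[i, j] = sum_{k,l} x[i + r*k, j + r*l] w[k, l]
    with taps spaced ``rate`` pixels apart.  Rate 1 is the standard
    convolution.  This corner-anchored form is the ground-truth oracle for
    the padded/centered convolution used inside the network layers.
    """
    if rate < 1:
        raise ValueError(f"rate must be a positive integer, got {rate}")
    x = np.asarray(x, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    if x.ndim != 2 or w.ndim != 2:
        raise ValueError("atrous_convolve expects 2-D signal and kernel")
    kh, kw = w.shape
    eff_h = effective_kernel_size(kh, rate)
    eff_w = effective_kernel_size(kw, rate)
    out_h = x.shape[0] - eff_h + 1
    out_w = x.shape[1] - eff_w + 1
    if out_h < 1 or out_w < 1:
        raise ValueError(
            f"signal {x.shape} smaller than effective kernel ({eff_h}, {eff_w})"
        )
    y = np.zeros((out_h, out_w))
    for k in range(kh):
        for l in range(kw):
            y += w[k, l] * x[rate * k : rate * k + out_h, rate * l : rate * l + out_w]
    return y


def bilinear_upsample(scores: ScoreMap | np.ndarray, out_size: tuple[int, int]) -> np.ndarray:
    """Channelwise bilinear interpolation of an (h, w, C) field to ``out_size``.

    Parameter-free; half-pixel sample centers.
    """
    arr = scores.scores if isinstance(scores, ScoreMap) else np.asarray(scores, dtype=np.float64)
    if out_size[0] < arr.shape[0] or out_size[1] < arr.shape[1]:
        raise ValueError("bilinear_upsample only enlarges")
    x = arr.transpose(2, 0, 1)[None]
    y, _ = F.bilinear_upsample_forward(x, out_size[0], out_size[1])
    return y[0].transpose(1, 2, 0)


def softmax_probabilities(scores: np.ndarray) -> ProbabilityMap:
    """Per-pixel softmax over the class axis of an (H, W, C) score field."""
    scores = np.asarray(scores, dtype=np.float64)
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN")
    return ProbabilityMap(probs=F.softmax(scores, axis=-1))


def predict_labels(prob: ProbabilityMap | np.ndarray) -> np.ndarray:
    """Per-pixel argmax; ties break toward the lowest class index."""
    p = prob.probs if isinstance(prob, ProbabilityMap) else np.asarray(prob)
    return np.argmax(p, axis=-1)


def predict_probabilities(model: SegmentationModel, image: np.ndarray) -> ProbabilityMap:
    """Full inference path: trunk scores -> bilinear upsample -> softmax."""
    sm = model.score_map(image)
    if sm.spatial_shape == image.shape[:2]:
        full = sm.scores
    else:
        full = bilinear_upsample(sm, image.shape[:2])
    return softmax_probabilities(full)
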