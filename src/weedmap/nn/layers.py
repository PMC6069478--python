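"""Layer objects with explicit forward/backward passes.

A :class:`Module` owns parameter arrays and gradient buffers and may contain
child modules; ``named_parameters`` flattens the tree into dotted names, which
is also the checkpoint format.  Backward passes consume the upstream gradient
and return the gradient with respect to the input, accumulating parameter
gradients in place.
"""

from __future__ import annotations

import numpy as np

from . import functional as F


class Module:
    """Base class: parameter/child bookkeeping plus the forward contract."""

    def __init__(self) -> None:
        self._params: dict[str, np.ndarray] = {}
        self._grads: dict[str, np.ndarray] = {}
        self._children: dict[str, "Module"] = {}

    # -- tree plumbing -----------------------------------------------------
    def add_child(self, name: str, module: "Module") -> "Module":
        self._children[name] = module
        return module

    def named_parameters(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, child in self._children.items():
            out.update(child.named_parameters(prefix + name + "."))
        return out

    def named_grads(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: v for k, v in self._grads.items()}
        for name, child in self._children.items():
            out.update(child.named_grads(prefix + name + "."))
        return out

    def zero_grad(self) -> None:
        for k, v in self._params.items():
            self._grads[k] = np.zeros_like(v)
        for child in self._children.values():
            child.zero_grad()

    def n_parameters(self) -> int:
        return sum(v.size for v in self.named_parameters().values())

    def set_parameter(self, name: str, value: np.ndarray) -> None:
        parts = name.split(".")
        mod = self
        for p in parts[:-1]:
            mod = mod._children[p]
        leaf = parts[-1]
        if leaf not in mod._params:
            raise KeyError(name)
        if mod._params[leaf].shape != value.shape:
            raise ValueError(
                f"shape mismatch for {name}: "
                f"{mod._params[leaf].shape} vs {value.shape}"
            )
        mod._params[leaf] = value.copy()

    # -- compute contract --------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Conv2d(Module):
    """Dilated convolution layer; He-normal init scaled by fan-in."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        stride: int = 1,
        rate: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        self._params["w"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, k, k))
        if bias:
            self._params["b"] = np.zeros(c_out)
        self.stride = stride
        self.rate = rate
        self.has_bias = bias
        self._cache: dict | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b = self._params.get("b")
        y, self._cache = F.conv2d_forward(x, self._params["w"], b, self.stride, self.rate)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx, dw, db = F.conv2d_backward(dy, self._cache)
        self._grads["w"] = self._grads.get("w", 0) + dw
        if self.has_bias:
            self._grads["b"] = self._grads.get("b", 0) + db
        return dx


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2d(Module):
    def __init__(self, k: int = 3, stride: int = 2) -> None:
        super().__init__()
        self.k = k
        self.stride = stride

    def forward(self, x: np.ndarray) -> np.ndarray:
        y, self._cache = F.maxpool2d_forward(x, self.k, self.stride)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return F.maxpool2d_backward(dy, self._cache)


class Sequential(Module):
    def __init__(self, *modules: Module) -> None:
        super().__init__()
        self.modules = list(modules)
        for idx, m in enumerate(self.modules):
            self.add_child(str(idx), m)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self.modules:
            x = m(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for m in reversed(self.modules):
            dy = m.backward(dy)
        return dy


class Bottleneck(Module):
    """Residual bottleneck: 1x1 reduce -> 3x3 (dilated) -> 1x1 expand + shortcut.

    A 1x1 projection shortcut is inserted when the spatial stride or the
    channel count changes.  The 3x3 convolution carries both the stride and
    the dilation rate of the block.
    """

    def __init__(
        self,
        c_in: int,
        c_mid: int,
        c_out: int,
        stride: int = 1,
        rate: int = 1,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv1 = self.add_child("conv1", Conv2d(c_in, c_mid, 1, rng=rng))
        self.relu1 = ReLU()
        self.conv2 = self.add_child("conv2", Conv2d(c_mid, c_mid, 3, stride=stride, rate=rate, rng=rng))
        self.relu2 = ReLU()
        self.conv3 = self.add_child("conv3", Conv2d(c_mid, c_out, 1, rng=rng))
        self.proj: Conv2d | None = None
        if stride != 1 or c_in != c_out:
            self.proj = self.add_child("proj", Conv2d(c_in, c_out, 1, stride=stride, rng=rng))
        self.relu_out = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.conv3(self.relu2(self.conv2(self.relu1(self.conv1(x)))))
        s = self.proj(x) if self.proj is not None else x
        return self.relu_out(y + s)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dsum = self.relu_out.backward(dy)
        dx_main = self.conv1.backward(
            self.relu1.backward(
                self.conv2.backward(self.relu2.backward(self.conv3.backward(dsum)))
            )
        )
        dx_short = self.proj.backward(dsum) if self.proj is not None else dsum
        return dx_main + dx_short


class ASPPHead(Module):
    """Parallel dilated 3x3 score branches fused by elementwise sum.

    Each branch maps the trunk features directly to ``n_classes`` channels;
    branch outputs are summed, preserving the class dimensionality.  With a
    single branch of rate 1 this is a plain 3x3 score layer.
    """

    def __init__(
        self,
        c_in: int,
        n_classes: int,
        rates: tuple[int, ...],
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        if len(rates) < 1 or any(r < 1 for r in rates):
            raise ValueError(f"ASPP rates must be a non-empty list of ints >= 1, got {rates}")
        self.branches = [
            self.add_child(f"branch{idx}", Conv2d(c_in, n_classes, 3, rate=r, rng=rng))
            for idx, r in enumerate(rates)
        ]

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = self.branches[0](x)
        for br in self.branches[1:]:
            out = out + br(x)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = self.branches[0].backward(dy)
        for br in self.branches[1:]:
            dx = dx + br.backward(dy)
        return dx


class BilinearUpsample(Module):
    """Parameter-free bilinear resize to a fixed output size (NCHW)."""

    def __init__(self, out_hw: tuple[int, int]) -> None:
        super().__init__()
        self.out_hw = out_hw

    def forward(self, x: np.ndarray) -> np.ndarray:
        y, self._cache = F.bilinear_upsample_forward(x, *self.out_hw)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return F.bilinear_upsample_backward(dy, self._cache)
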