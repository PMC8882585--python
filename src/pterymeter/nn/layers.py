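"""Layers and parameter containers built on the autodiff tensors."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, upsample2

__all__ = ["Module", "Conv2d", "ConvBlock", "AttentionGate"]


class Module:
    """Lightweight layer container with named-parameter traversal."""

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}

        def visit(name: str, attr):
            if isinstance(attr, Tensor) and attr.requires_grad:
                params[name] = attr
            elif isinstance(attr, Module):
                params.update(attr.named_parameters(name))
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    visit(f"{name}.{i}", item)

        for name, attr in vars(self).items():
            visit(f"{prefix}.{name}" if prefix else name, attr)
        return params

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True):
        params = self.named_parameters()
        missing = set(params) - set(state)
        if strict and missing:
            raise KeyError(f"missing parameters: {sorted(missing)}")
        for k, v in state.items():
            if k in params:
                params[k].data[...] = v
            elif strict:
                raise KeyError(f"unexpected parameter: {k}")


class Conv2d(Module):
    """Stride-1 'same' convolution with He-normal initialization.

    Parameters are float32 by default; the engine preserves dtypes, so a
    float32 model on float32 inputs runs entirely in single precision.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        fan_in = in_ch * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(out_ch, in_ch, kernel, kernel)).astype(dtype),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class ConvBlock(Module):
    """Two 3x3 convolutions, each followed by ReLU."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng, dtype)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng, dtype)

    def __call__(self, x: Tensor) -> Tensor:
        return self.conv2(self.conv1(x).relu()).relu()


class AttentionGate(Module):
    """Additive attention gate for skip-connection features.

    The gating signal ``g`` (coarser, half the spatial size of the skip
    feature ``x_l``) and a strided-pooled ``x_l`` are each projected by 1x1
    convolutions to ``f_int`` channels, summed, passed through ReLU, projected
    to one channel, squashed by a sigmoid into a weight map ``alpha`` in
    [0, 1], bilinearly upsampled to the skip resolution, and multiplied onto
    ``x_l``.  ``force_alpha`` (0.0 or 1.0) bypasses the computation for
    diagnostics: with 1.0 the gate is exactly transparent.
    """

    def __init__(self, f_g: int, f_l: int, f_int: int,
                 rng: np.random.Generator, dtype=np.float32):
        self.w_g = Conv2d(f_g, f_int, 1, rng, dtype)
        self.w_x = Conv2d(f_l, f_int, 1, rng, dtype)
        self.psi = Conv2d(f_int, 1, 1, rng, dtype)
        self.force_alpha: float | None = None

    def alpha(self, x_l: Tensor, g: Tensor) -> Tensor:
        gh, gw = g.data.shape[2:]
        xh, xw = x_l.data.shape[2:]
        if (xh, xw) != (2 * gh, 2 * gw):
            raise ValueError(
                f"gating signal must be half the skip resolution: got g {g.data.shape} "
                f"for x_l {x_l.data.shape}"
            )
        x_down = _avg_pool2(x_l)
        a = self.psi((self.w_g(g) + self.w_x(x_down)).relu()).sigmoid()
        return upsample2(a, mode="bilinear")

    def __call__(self, x_l: Tensor, g: Tensor) -> Tensor:
        if self.force_alpha is not None:
            if self.force_alpha == 1.0:
                return x_l
            return x_l * float(self.force_alpha)
        return self.alpha(x_l, g) * x_l


def _avg_pool2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    y = xr.mean(axis=(3, 5))
    out = Tensor._make(y, (x,), None)

    def backward(grad):
        g = np.repeat(np.repeat(grad, 2, axis=2), 2, axis=3) / 4.0
        return (g,)

    out._backward = backward
    return out
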