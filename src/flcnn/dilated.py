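"""Multi-granularity dilated 1-D convolutions over span embeddings.

A basic convolution layer lifts the span embeddings W_F into channel space;
parallel branches with different dilation rates (default [1, 2, 4]) then
extract multi-token co-occurrence features at growing receptive fields.
Branch outputs are channel-concatenated, fused with a residual projection of
the branch input into the co-occurrence features W_C, and [W_F; W_C] is
finally projected back to model width.

Shape arithmetic: a kernel of size k at dilation rate lam covers an
effective window K = k + (k-1)(lam-1); with stride s and padding p the
output length is floor((w - K + 2p)/s) + 1.  All layers here use
same-length padding p = (k-1)*lam/2, so sequence length is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Parameter, Tensor, concat

__all__ = [
    "ConvSpec",
    "effective_kernel_size",
    "conv_output_length",
    "same_padding",
    "DilatedConv1d",
    "BasicConvLayer",
    "MultiDilationBlock",
    "ConcatFusion",
]


@dataclass
class ConvSpec:
    """Kernel/dilation/channel settings of the convolution stack."""

    kernel_size: int = 3
    dilations: list[int] = field(default_factory=lambda: [1, 2, 4])
    stride: int = 1
    channels: int = 160
    dropout: float = 0.0
    scope: str = "spans"  # run over the full span sequence or chars only

    def __post_init__(self):
        if self.kernel_size < 1 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and positive")
        if any(l < 1 for l in self.dilations):
            raise ValueError("dilation rates must be positive")
        if self.scope not in ("spans", "chars"):
            raise ValueError(f"unknown cnn scope {self.scope!r}")


def effective_kernel_size(k: int, lam: int) -> int:
    """Actual kernel extent after dilation: K = k + (k-1)(lam-1)."""
    if k < 1 or lam < 1:
        raise ValueError("kernel size and dilation rate must be positive")
    return k + (k - 1) * (lam - 1)


def conv_output_length(w: int, k: int, lam: int, s: int = 1, p: int = 0) -> int:
    """Output length: floor((w - k - (k-1)(lam-1) + 2p) / s) + 1."""
    num = w - k - (k - 1) * (lam - 1) + 2 * p
    if num < 0:
        raise ValueError("input shorter than receptive field")
    return num // s + 1


def same_padding(k: int, lam: int) -> int:
    """Padding preserving length at stride 1; requires odd k."""
    if k % 2 == 0:
        raise ValueError("same-length padding is ambiguous for even kernel size")
    return (k - 1) * lam // 2


class DilatedConv1d:
    """One 1-D convolution branch (stride 1) on (B, L, Cin).

    ``padding=None`` selects same-length padding (k-1)*lam/2; an explicit
    integer (e.g. 0) yields the general output length of the closed form.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int,
        lam: int,
        rng: np.random.Generator,
        dtype=np.float32,
        padding: int | None = None,
    ):
        self.k, self.lam = k, lam
        self.padding = padding
        scale = (k * c_in) ** -0.5
        self.w = Parameter((rng.standard_normal((k * c_in, c_out)) * scale).astype(dtype))
        self.b = Parameter(np.zeros(c_out, dtype=dtype))
        self.dtype = dtype

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        B, L, c_in = x.shape
        p = self.padding if self.padding is not None else same_padding(self.k, self.lam)
        out_len = conv_output_length(L, self.k, self.lam, 1, p)
        if p > 0:
            pad = Tensor(np.zeros((B, p, c_in), dtype=self.dtype))
            xp = concat([pad, x, pad], axis=1)  # (B, L + 2p, Cin)
        else:
            xp = x
        # window index: tap t of output position l reads padded row l + t*lam
        idx = np.arange(out_len)[:, None] + self.lam * np.arange(self.k)[None, :]
        win = xp[:, idx, :]  # (B, out_len, k, Cin)
        win = win.reshape(B, out_len, self.k * c_in)
        return win @ self.w + self.b


class BasicConvLayer:
    """Initial lambda=1 convolution mapping d_model to channel space, with
    rectifier and optional dropout."""

    def __init__(self, d_in: int, spec: ConvSpec, rng: np.random.Generator, dtype=np.float32):
        self.spec = spec
        self.conv = DilatedConv1d(d_in, spec.channels, spec.kernel_size, 1, rng, dtype)

    def parameters(self) -> list[Parameter]:
        return self.conv.parameters()

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        return self.conv(x).relu().dropout(self.spec.dropout, rng)


class MultiDilationBlock:
    """Parallel dilation branches, channel concatenation, residual fusion.

    Produces W_C of width ``|dilations| * channels`` per position: branch
    outputs (each rectified, same length) are concatenated channel-wise and
    a residual linear projection of the block input is added.
    """

    def __init__(self, spec: ConvSpec, rng: np.random.Generator, dtype=np.float32):
        self.spec = spec
        C = spec.channels
        self.branches = [
            DilatedConv1d(C, C, spec.kernel_size, lam, rng, dtype)
            for lam in spec.dilations
        ]
        n = len(spec.dilations)
        self.w_res = Parameter(
            (rng.standard_normal((C, n * C)) * C**-0.5).astype(dtype)
        )

    def parameters(self) -> list[Parameter]:
        out = [self.w_res]
        for br in self.branches:
            out += br.parameters()
        return out

    @property
    def out_width(self) -> int:
        return len(self.spec.dilations) * self.spec.channels

    def branch_activations(self, x: Tensor) -> list[np.ndarray]:
        """Rectified per-branch outputs (for heatmap export), as numpy."""
        return [br(x).relu().data.copy() for br in self.branches]

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        outs = [br(x).relu().dropout(self.spec.dropout, rng) for br in self.branches]
        cat = concat(outs, axis=-1)  # (B, L, n*C)
        return cat + x @ self.w_res


class ConcatFusion:
    """[W_F; W_C] concatenation followed by a learned map back to d_model."""

    def __init__(self, d_model: int, channels: int, rng: np.random.Generator, dtype=np.float32):
        fan = d_model + channels
        self.w = Parameter((rng.standard_normal((fan, d_model)) * fan**-0.5).astype(dtype))
        self.b = Parameter(np.zeros(d_model, dtype=dtype))

    def parameters(self) -> list[Parameter]:
        return [self.w, self.b]

    def __call__(self, w_f: Tensor, w_c: Tensor) -> Tensor:
        if w_f.shape[:-1] != w_c.shape[:-1]:
            raise ValueError("W_F and W_C must agree on leading dimensions")
        return concat([w_f, w_c], axis=-1) @ self.w + self.b
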