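"""SimpleNet: an 8-layer, 3×3, residual convolutional network, in pure numpy.

The network maps a normalized [0, 1] image to a same-sized image through a
residual branch of eight pre-activation blocks (rectifier, then convolution):
1→C channels, six C→C blocks, and a final C→1 block, with ``output = input +
branch``.  With all weights zero the network is exactly the identity map, and
because every layer is 3×3/stride-1/pad-1 it is fully convolutional — the
same parameters apply to any spatial size.

Convolutions are evaluated as im2col matrix products so a single BLAS call
carries each layer; gradients are computed analytically (the transposed
convolution for the input, the patch-matrix product for the weights).  The
optimiser (Adam) lives in :mod:`ossr.train`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class NetworkError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    n_layers: int = 8
    channels: int = 128
    kernel: tuple[int, int] = (3, 3)
    stride: tuple[int, int] = (1, 1)
    padding: tuple[int, int] = (1, 1)
    residual_skip: bool = True

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise NetworkError("need at least input and output conv layers")
        if self.kernel != (3, 3) or self.stride != (1, 1) or self.padding != (1, 1):
            raise NetworkError("only 3x3/stride-1/pad-1 layers preserve size here")

    def layer_channels(self) -> list[tuple[int, int]]:
        """(in, out) channel counts per layer: 1→C, C→C…, C→1."""
        chans = [(1, self.channels)]
        chans += [(self.channels, self.channels)] * (self.n_layers - 2)
        chans += [(self.channels, 1)]
        return chans


@dataclass
class NetworkParams:
    """Per-layer weights ``(C_out, C_in, 3, 3)`` and biases ``(C_out,)``."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: NetworkConfig
    seed: int | None = None

    def copy(self) -> "NetworkParams":
        return NetworkParams([w.copy() for w in self.weights],
                             [b.copy() for b in self.biases],
                             self.config, self.seed)

    def flat(self) -> list[np.ndarray]:
        return self.weights + self.biases


def init_params(cfg: NetworkConfig, seed: int | None = None,
                zero: bool = False, dtype=np.float32) -> NetworkParams:
    """Kaiming fan-in initialisation (zero biases); ``zero=True`` gives the
    exact identity network."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for cin, cout in cfg.layer_channels():
        if zero:
            w = np.zeros((cout, cin, 3, 3), dtype=dtype)
        else:
            std = np.sqrt(2.0 / (cin * 9))
            w = (std * rng.standard_normal((cout, cin, 3, 3))).astype(dtype)
        weights.append(w)
        biases.append(np.zeros(cout, dtype=dtype))
    return NetworkParams(weights, biases, cfg, seed)


def _im2col(x: np.ndarray) -> np.ndarray:
    """(C, H, W) -> (H*W, C*9) patch matrix for a 3x3/pad-1 convolution."""
    c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    cols = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (C, H, W, 3, 3)
    return cols.transpose(1, 2, 0, 3, 4).reshape(h * w, c * 9)


def _conv3x3(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Forward convolution via im2col; x (Cin,H,W), w (Cout,Cin,3,3) -> (Cout,H,W)."""
    cout = w.shape[0]
    _, h, wid = x.shape
    wmat = w.reshape(cout, -1).T           # (Cin*9, Cout)
    y = _im2col(x) @ wmat + b              # (H*W, Cout)
    return y.T.reshape(cout, h, wid)


def _conv3x3_input_grad(dy: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Gradient w.r.t. the input: correlation of dy with the flipped kernel."""
    cout, cin = w.shape[:2]
    _, h, wid = dy.shape
    # (Cout,Cin,3,3) -> flip spatial -> (Cout*9, Cin)
    wrot = w[:, :, ::-1, ::-1].transpose(0, 2, 3, 1).reshape(cout * 9, cin)
    dx = _im2col(dy) @ wrot
    return dx.T.reshape(cin, h, wid)


def forward(params: NetworkParams, img: np.ndarray) -> np.ndarray:
    """Network output for a 2-D normalized image; spatial size preserved."""
    y, _ = forward_with_cache(params, img, keep_cache=False)
    return y


def forward_with_cache(params: NetworkParams, img: np.ndarray,
                       keep_cache: bool = True):
    """Forward pass; optionally keep per-layer activations for backprop."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise NetworkError(f"expected a 2-D image, got ndim={img.ndim}")
    dtype = params.weights[0].dtype
    x = img.astype(dtype, copy=False)[None]  # (1, H, W)
    h = x
    cache = []
    for w, b in zip(params.weights, params.biases):
        a = np.maximum(h, 0)                 # pre-activation rectifier
        if keep_cache:
            cache.append((h > 0, a))
        h = _conv3x3(a, w, b)
    branch = h[0].astype(np.float64)
    # residual add in float64 on the original image so the zero network is
    # exactly the identity map whatever the parameter dtype
    out = img.astype(np.float64) + branch if params.config.residual_skip else branch
    return out, (cache, h) if keep_cache else None


def backward(params: NetworkParams, cache, dloss_dout: np.ndarray):
    """Gradients of a scalar loss w.r.t. all weights and biases.

    ``cache`` is the second return of :func:`forward_with_cache`;
    ``dloss_dout`` has the image's shape.
    """
    layer_cache, _ = cache
    dtype = params.weights[0].dtype
    dh = np.asarray(dloss_dout, dtype=dtype)[None]  # residual add passes grad through
    dws, dbs = [None] * len(params.weights), [None] * len(params.weights)
    for li in range(len(params.weights) - 1, -1, -1):
        w = params.weights[li]
        mask, a = layer_cache[li]
        cout = w.shape[0]
        dymat = dh.reshape(cout, -1).T               # (H*W, Cout)
        dws[li] = (_im2col(a).T @ dymat).T.reshape(w.shape)
        dbs[li] = dymat.sum(axis=0)
        da = _conv3x3_input_grad(dh, w)
        dh = da * mask                               # rectifier gate
    return dws, dbs
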