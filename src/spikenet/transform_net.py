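"""Color-transform network: learns per-band scale factors that map wheat
canopy images from different growth stages toward a common color regime.

Two stages of the pipeline:

* **AFAM** (adaptive feature adapter): a stride-4 convolutional stem, a
  short stack of residual blocks, and a channel-attention *domain adapter*
  whose two fully connected branches (a softmax branch and a plain branch,
  multiplied together) produce per-channel weights sensitive to the stage
  appearance.
* **TPGM** (transform parameter generation): a bag-of-visual-words pooling
  layer maps the adapted feature grid to a fixed-length codeword histogram,
  and a fully connected softmax head emits the three band factors
  ``alpha = softmax(W h)`` with ``sum(alpha) = 1``.

The transformed image is ``I' = rescale * alpha_c * I_c`` per band, clamped
to the pixel range.  Because the three factors sum to 1, a fixed rescale
constant (default 3) makes an untrained network approximate the identity.
``alpha`` is computed per image, not per batch.
"""

from __future__ import annotations

import numpy as np

from . import nn

__all__ = ["ResidualBlock", "DomainAdapter", "BVWP", "TransformNet", "apply_color_transform"]


class ResidualBlock(nn.Module):
    """Two 3x3 convolutions with a ReLU between them and a skip connection:
    ``out = x + W2 * relu(W1 * x)``.  Spatial size is preserved."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(channels, channels, 3, rng=rng)
        self.conv2 = nn.Conv2d(channels, channels, 3, rng=rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        return self.conv2(self.conv1(x).relu()) + x


class DomainAdapter(nn.Module):
    """Channel attention with two branches over globally pooled features.

    ``avg = GAP(x)``; the softmax branch ``F2 = softmax(W2 avg)`` (positive,
    sums to 1 over channels) and the plain branch ``F3 = W3 relu(avg)`` are
    multiplied into per-channel weights ``F1 = F2 * F3``, and the output is
    the channel-wise product ``F1 . x``.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        self.fc2 = nn.Linear(channels, channels, rng=rng)
        self.fc3 = nn.Linear(channels, channels, rng=rng)
        # start near pass-through: the softmax branch averages ~1/C, so a
        # plain-branch bias of C makes F1 ~ 1 per channel at initialization
        self.fc3.bias.data[:] = float(channels)

    def weights(self, x: nn.Tensor) -> nn.Tensor:
        avg = x.mean(axis=(2, 3))                  # (N, C)
        f2 = self.fc2(avg).softmax(axis=-1)
        f3 = self.fc3(avg.relu())
        return f2 * f3

    def __call__(self, x: nn.Tensor):
        f1 = self.weights(x)
        n, c = f1.shape
        out = x * f1.reshape(n, c, 1, 1)
        return out, f1


class BVWP(nn.Module):
    """Bag-of-visual-words pooling to a fixed-length histogram.

    Each spatial location's channel vector gets a soft membership over
    ``n_codewords`` learnable codewords,
    ``phi_k = softmax_k(-||x - Y_k|| / m_k)`` (Euclidean distance, positive
    learnable scale ``m_k`` stored in log space), and the histogram is the
    membership averaged over locations — entries in [0, 1], summing to 1.
    """

    def __init__(self, channels: int, n_codewords: int = 32, rng: np.random.Generator = None):
        if n_codewords < 2:
            raise ValueError("need at least 2 codewords")
        rng = rng or np.random.default_rng(0)
        self.codewords = nn.Tensor(
            rng.normal(0.0, 1.0, (n_codewords, channels)).astype(np.float32), requires_grad=True)
        # m_k ~ a quarter of the typical channel-vector distance (~sqrt(C)):
        # large enough that memberships stay soft and gradients flow, small
        # enough that the pooled histogram remains strongly input-dependent
        init = 0.5 * np.log(channels) + np.log(0.25)
        self.log_scales = nn.Tensor(np.full(n_codewords, init, dtype=np.float32),
                                    requires_grad=True)

    @property
    def scales(self) -> np.ndarray:
        return np.exp(self.log_scales.data)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        n, c, h, w = x.shape
        flat = x.transpose(0, 2, 3, 1).reshape(n, h * w, c)
        # ||x - y||^2 = ||x||^2 + ||y||^2 - 2 x.y, cheaper than full broadcast
        x2 = (flat**2).sum(axis=-1, keepdims=True)
        y2 = (self.codewords**2).sum(axis=-1)
        cross = flat.matmul(self.codewords.transpose(1, 0))
        d2 = (x2 + y2 - 2.0 * cross).relu()
        dist = (d2 + 1e-12).sqrt()
        inv_m = (-self.log_scales).exp()           # 1 / m_k > 0
        logits = -dist * inv_m
        phi = logits.softmax(axis=-1)              # (N, HW, Nk)
        return phi.mean(axis=1)                    # (N, Nk)


def bvwp_pool(features: np.ndarray, codewords: np.ndarray, scales: np.ndarray) -> np.ndarray:
    """Functional bag-of-visual-words pooling on plain arrays.

    ``features`` is (C, H, W) or (N, C, H, W); raises on non-positive scales.
    """
    scales = np.asarray(scales, dtype=float)
    if np.any(scales <= 0):
        raise ValueError("all codeword scales m_k must be positive")
    f = np.asarray(features, dtype=float)
    if f.ndim == 3:
        f = f[None]
    if codewords.shape[1] != f.shape[1]:
        raise ValueError(
            f"codeword dimension {codewords.shape[1]} != channel count {f.shape[1]}")
    n, c, h, w = f.shape
    flat = f.transpose(0, 2, 3, 1).reshape(n, h * w, c)
    dist = np.linalg.norm(flat[:, :, None, :] - codewords[None, None], axis=-1)
    logits = -dist / scales
    logits -= logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    phi = e / e.sum(axis=-1, keepdims=True)
    hist = phi.mean(axis=1)
    return hist[0] if features.ndim == 3 else hist


class TransformNet(nn.Module):
    """AFAM + TPGM: RGB image in, per-band transform factors ``alpha`` out."""

    def __init__(self, channels: int = 16, n_blocks: int = 3, n_codewords: int = 32,
                 rescale: float = 3.0, rng: np.random.Generator = None):
        rng = rng or np.random.default_rng(0)
        self.stem = nn.Conv2d(3, channels, 4, stride=4, pad=0, rng=rng)
        self.blocks = [ResidualBlock(channels, rng) for _ in range(n_blocks)]
        self.adapter = DomainAdapter(channels, rng)
        self.pool = BVWP(channels, n_codewords, rng)
        self.head = nn.Linear(n_codewords, 3, rng=rng)
        self.rescale = float(rescale)

    def compute_alpha(self, img: nn.Tensor) -> nn.Tensor:
        """Per-image band factors, shape (N, 3); each row on the 3-simplex."""
        if img.shape[1] != 3:
            raise ValueError(f"expected a 3-band image, got {img.shape[1]} channels")
        x = self.stem(img).relu()
        for blk in self.blocks:
            x = blk(x)
        x, _ = self.adapter(x)
        hist = self.pool(x)
        return self.head(hist).softmax(axis=-1)

    def __call__(self, img: nn.Tensor) -> tuple:
        alpha = self.compute_alpha(img)
        return apply_color_transform(img, alpha, self.rescale), alpha


def apply_color_transform(img, alpha, rescale: float = 3.0):
    """``I'_c = clamp(rescale * alpha_c * I_c)`` per band.

    Works on tensors (differentiable, pixel range [0, 1]) and on uint8
    arrays (range [0, 255]); ``alpha`` is (3,) or (N, 3).
    """
    if isinstance(img, nn.Tensor):
        a = alpha if isinstance(alpha, nn.Tensor) else nn.Tensor(np.asarray(alpha))
        n = img.shape[0]
        return (img * (a.reshape(n, 3, 1, 1) * rescale)).clip(0.0, 1.0)
    arr = np.asarray(img, dtype=float)
    a = np.asarray(alpha, dtype=float).reshape(3)
    out = arr * (rescale * a)[None, None, :]
    return np.clip(out, 0, 255).astype(np.uint8)
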