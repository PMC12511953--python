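"""Framework-free forward passes of the detector-side attention operators.

These are deterministic array operators with injectable weights — the
inference math of three feature-map enhancements used inside a YOLO-style
detector backbone:

* ``simam_attend`` — SimAM-style energy attention computed independently on
  the four spatial quadrants of each channel plane;
* ``sws_forward`` — SimAM attention composed with a plain convolution;
* ``mca_forward`` — a three-branch cooperative attention over the width,
  height and channel dimensions, each branch built from a rotation, a
  squeeze (mean pool), an excitation (1-D convolution) and a sigmoid gate.

No training, no gradients: the surrounding detector learns the weights; here
they are plain arrays so every operator is exactly testable.

Feature maps are 3-D float arrays indexed (channel C, height H, width W).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import correlate1d
from scipy.signal import correlate2d

from .errors import InvalidArgumentError

__all__ = [
    "simam_attend",
    "sws_forward",
    "rotate",
    "rotate_back",
    "mca_branch",
    "mca_forward",
]

_DELTA = np.array([1.0])  # identity excitation kernel


def _as_feature_map(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise InvalidArgumentError(f"feature map must be 3-D (C, H, W), got shape {x.shape}")
    if x.size == 0:
        raise InvalidArgumentError("feature map must have C, H, W >= 1")
    if not np.all(np.isfinite(x)):
        raise InvalidArgumentError("feature map entries must be finite")
    return x


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def simam_attend(x, lam: float = 1e-4) -> np.ndarray:
    """Quadrant-wise SimAM energy attention.

    Each channel plane is split into 2x2 spatial quadrants at
    (floor(H/2), floor(W/2)).  Per quadrant, with u the quadrant mean and
    n = (#elements - 1), the energy is

        y = (x - u)^2 / (4 * (sum((x - u)^2) / n + lam)) + 0.5

    and the output is sigmoid(y) * x, quadrants re-concatenated.  Since
    y >= 0.5 everywhere, all attention weights lie in (0.62, 1).  The +lam
    regulariser guards single-element quadrants (n = 0) against division by
    zero.
    """
    x = _as_feature_map(x)
    if lam <= 0:
        raise InvalidArgumentError(f"lam must be positive, got {lam}")
    _, h, w = x.shape
    if h < 2 or w < 2:
        raise InvalidArgumentError(
            f"need H >= 2 and W >= 2 so that four sub-blocks exist, got H={h}, W={w}"
        )
    hs, ws = h // 2, w // 2
    out = np.empty_like(x)
    for rows in (slice(0, hs), slice(hs, h)):
        for cols in (slice(0, ws), slice(ws, w)):
            block = x[:, rows, cols]
            u = block.mean(axis=(1, 2), keepdims=True)
            dev_sq = (block - u) ** 2
            n = block.shape[1] * block.shape[2] - 1
            denom = 4.0 * (dev_sq.sum(axis=(1, 2), keepdims=True) / max(n, 1) + lam)
            energy = dev_sq / denom + 0.5
            out[:, rows, cols] = _sigmoid(energy) * block
    return out


def sws_forward(x, kernel, lam: float = 1e-4) -> np.ndarray:
    """SimAM attention followed by a same-padded cross-correlation.

    ``kernel`` has shape (C_out, C_in, kh, kw) with odd spatial size; C_in
    must equal the input channel count.  Padding is zero-fill, so the output
    spatial shape equals the input's.
    """
    x = _as_feature_map(x)
    kernel = np.asarray(kernel, dtype=float)
    if kernel.ndim != 4:
        raise InvalidArgumentError(
            f"kernel must be 4-D (C_out, C_in, kh, kw), got shape {kernel.shape}"
        )
    c_out, c_in, kh, kw = kernel.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise InvalidArgumentError(f"kernel spatial size must be odd, got {kh}x{kw}")
    if c_in != x.shape[0]:
        raise InvalidArgumentError(
            f"kernel expects {c_in} input channels, feature map has {x.shape[0]}"
        )
    attended = simam_attend(x, lam=lam)
    out = np.zeros((c_out,) + x.shape[1:], dtype=float)
    for o in range(c_out):
        for c in range(c_in):
            # symmetric padding keeps constant maps constant under averaging
            out[o] += correlate2d(attended[c], kernel[o, c], mode="same", boundary="symm")
    return out


def rotate(x, axis: str) -> np.ndarray:
    """Layout permutation used by the attention branches.

    ``axis='H'`` swaps the C and W dimensions; ``axis='W'`` swaps the C and H
    dimensions.  ``rotate_back`` with the same axis restores the original
    layout exactly (the permutations are involutions).
    """
    x = _as_feature_map(x)
    if axis == "H":
        return np.swapaxes(x, 0, 2).copy()
    if axis == "W":
        return np.swapaxes(x, 0, 1).copy()
    raise InvalidArgumentError(f"axis must be 'H' or 'W', got {axis!r}")


def rotate_back(x, axis: str) -> np.ndarray:
    """Inverse of :func:`rotate` (the permutations are self-inverse)."""
    return rotate(x, axis)


def _excite(pooled: np.ndarray, weights) -> np.ndarray:
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 1 or weights.size == 0:
        raise InvalidArgumentError("excitation weights must be a non-empty 1-D array")
    if weights.size % 2 == 0:
        raise InvalidArgumentError(f"excitation kernel length must be odd, got {weights.size}")
    if weights.size > pooled.size:
        raise InvalidArgumentError(
            f"excitation kernel (length {weights.size}) longer than pooled vector "
            f"(length {pooled.size})"
        )
    return correlate1d(pooled, weights, mode="reflect")


def mca_branch(x, axis: str, excite=None) -> np.ndarray:
    """One attention branch: rotate -> squeeze -> excite -> gate -> rotate back.

    ``axis`` names the dimension the branch attends to: 'W' (rotate along H),
    'H' (rotate along W) or 'C' (identity mapping).  The squeeze is a mean
    pool over the two trailing dimensions of the rotated map; the excitation
    is a same-padded (reflect) 1-D cross-correlation over the pooled vector
    with ``excite`` (default: the identity delta kernel).  Sigmoid weights
    are broadcast-multiplied with the rotated map and the layout is restored,
    so the output shape equals the input shape.
    """
    x = _as_feature_map(x)
    if axis == "W":
        rotated = rotate(x, "H")
    elif axis == "H":
        rotated = rotate(x, "W")
    elif axis == "C":
        rotated = x.copy()
    else:
        raise InvalidArgumentError(f"axis must be one of 'W', 'H', 'C', got {axis!r}")
    pooled = rotated.mean(axis=(1, 2))
    gate = _sigmoid(_excite(pooled, _DELTA if excite is None else excite))
    weighted = gate[:, None, None] * rotated
    if axis == "W":
        return rotate_back(weighted, "H")
    if axis == "H":
        return rotate_back(weighted, "W")
    return weighted


def mca_forward(x, excite_w=None, excite_h=None, excite_c=None) -> np.ndarray:
    """Elementwise mean of the width, height and channel attention branches."""
    x = _as_feature_map(x)
    return (
        mca_branch(x, "W", excite_w)
        + mca_branch(x, "H", excite_h)
        + mca_branch(x, "C", excite_c)
    ) / 3.0
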