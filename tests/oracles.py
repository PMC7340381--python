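"""Independent brute-force oracles, kept deliberately naive.

These recompute starlet quantities from first principles (explicit zero
insertion, dense 2-D convolution via scipy.signal on a symmetric-padded
array) through a code path sharing nothing with the package's separable
ndimage implementation.
"""

import numpy as np
from scipy import signal

BASE = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


def dilated_taps(level: int) -> np.ndarray:
    """Insert 2**(level-1) - 1 zeros between adjacent B3 taps, one by one."""
    gap = 2 ** (level - 1) - 1
    taps = []
    for i, t in enumerate(BASE):
        taps.append(t)
        if i < len(BASE) - 1:
            taps.extend([0.0] * gap)
    return np.array(taps)


def dense_smooth(img: np.ndarray, level: int) -> np.ndarray:
    """Full 2-D convolution with the dilated outer-product kernel,
    symmetric (edge-repeated mirror) boundary extension."""
    taps = dilated_taps(level)
    kernel = np.outer(taps, taps)
    r = len(taps) // 2
    padded = np.pad(img, r, mode="symmetric")
    return signal.convolve2d(padded, kernel, mode="valid")


def dense_decompose(img: np.ndarray, depth: int):
    """Reference starlet decomposition: list of details plus approximation."""
    a = img.astype(float)
    details = []
    for j in range(1, depth + 1):
        a_next = dense_smooth(a, j)
        details.append(a - a_next)
        a = a_next
    return details, a
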