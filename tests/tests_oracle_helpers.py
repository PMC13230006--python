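"""Shared independent oracles used by the test suite."""

import numpy as np


def _upsample(f: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return f.copy()
    up = np.zeros((f.size - 1) * factor + 1)
    up[::factor] = f
    return up


def equivalent_filter(level: int) -> np.ndarray:
    """Level-l equivalent rescaled Haar wavelet filter, built here by an
    explicit upsample-and-convolve cascade so the oracle is independent
    of the implementation's pyramid recursion."""
    h = np.array([0.5, -0.5])
    g = np.array([0.5, 0.5])
    filt = _upsample(h, 2 ** (level - 1))
    for j in range(level - 1, 0, -1):
        filt = np.convolve(filt, _upsample(g, 2 ** (j - 1)))
    return filt


def direct_modwt(x: np.ndarray, levels: int) -> list[np.ndarray]:
    """MODWT detail vectors by direct circular convolution with the
    explicitly upsampled level-l equivalent Haar filters."""
    N = x.size
    out = []
    for l in range(1, levels + 1):
        f = equivalent_filter(l)
        out.append(
            np.array(
                [sum(f[n] * x[(t - n) % N] for n in range(f.size)) for t in range(N)]
            )
        )
    return out
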