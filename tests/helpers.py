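"""Independent brute-force oracles used by the test suite only."""

import numpy as np

from mwppg.fusion import wavelet_function


def riemann_cwt(x: np.ndarray, scales: np.ndarray, wavelet: str = "cgau1") -> np.ndarray:
    """Direct Riemann-sum evaluation of the CWT integral.

    WT(a, b) = sum_m x[m] * conj(psi((m - b)/a)) / sqrt(a), evaluated with
    explicit nested loops over scales and translations — O(S * N^2), no
    convolution tricks — as an independent check of the fast FFT path.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    m = np.arange(n)
    out = np.empty((len(scales), n), dtype=complex)
    for i, a in enumerate(scales):
        for b in range(n):
            out[i, b] = np.sum(x * np.conj(wavelet_function((m - b) / a, wavelet))) / np.sqrt(a)
    return out
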