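"""CWT scalograms and four-wavelength fusion into the 12-channel model input.

Each 5 s window is correlated with scaled/translated copies of the
first-order complex Gaussian wavelet ("cgau1"),

    WT_x(a, b) = |a|^{-1/2} * integral x(t) psi*((t - b)/a) dt,

discretised on the sample grid with the scale ``a`` expressed in samples
(the PyWavelets convention, so pseudo-frequency = fc * fs / a with fc the
wavelet centre frequency).  The wavelet is complex, so the scalogram is
the magnitude |WT_x| (rendered with amplitude row scaling |WT|/sqrt(a),
the display convention).  The transform is evaluated by FFT cross-correlation
with the sampled wavelet; a brute-force Riemann-sum evaluation of the same
integral is the independent oracle in the test suite, and PyWavelets'
``cwt`` serves as a second, external cross-check.

Each wavelength's scalogram is min–max normalised, mapped through a fixed
perceptually-uniform colormap to an RGB image, and resized; the four RGB
images are stacked along depth into one H x W x 12 tensor (blocks
[0:3]=Channel 1 ... [9:12]=Channel 4).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pywt
from matplotlib import colormaps
from skimage.transform import resize as _sk_resize

from .errors import ConfigError, ShapeError
from .signal_io import N_CHANNELS

DEFAULT_WAVELET = "cgau1"
#: 16 scales per octave over the 0.5-8 Hz passband (4 octaves); 65 points
#: put the octave frequencies 0.5, 1, 2, 4, 8 Hz exactly on the grid.
DEFAULT_N_SCALES = 65
DEFAULT_BAND = (0.5, 8.0)       # Hz; matches the preprocessing passband
DEFAULT_IMAGE_SIZE = (64, 64)
DEFAULT_COLORMAP = "viridis"

_WAVEFUN_PRECISION = 12          # 2**12 sample points over the wavelet support


@lru_cache(maxsize=8)
def _wavelet_table(wavelet: str):
    w = pywt.ContinuousWavelet(wavelet)
    if not w.complex_cwt:
        raise ConfigError(f"wavelet {wavelet!r} is not complex-valued")
    psi, grid = w.wavefun(_WAVEFUN_PRECISION)
    return np.asarray(psi, dtype=complex), np.asarray(grid, dtype=float)


def wavelet_function(u: np.ndarray, wavelet: str = DEFAULT_WAVELET) -> np.ndarray:
    """Sample the (complex) mother wavelet at points ``u``; zero off-support."""
    psi, grid = _wavelet_table(wavelet)
    re = np.interp(u, grid, psi.real, left=0.0, right=0.0)
    im = np.interp(u, grid, psi.imag, left=0.0, right=0.0)
    return re + 1j * im


@lru_cache(maxsize=8)
def central_frequency(wavelet: str = DEFAULT_WAVELET) -> float:
    """Centre frequency of the wavelet in cycles per unit of its argument.

    Located as the magnitude peak of the wavelet's zero-padded FFT, which
    resolves it far beyond the coarse grid PyWavelets' own helper uses
    (for cgau1 the analytic value is 1/pi ~ 0.3183).
    """
    psi, grid = _wavelet_table(wavelet)
    dt = grid[1] - grid[0]
    nfft = 1 << 20
    spectrum = np.abs(np.fft.fft(psi, nfft))
    freqs = np.fft.fftfreq(nfft, d=dt)
    return float(abs(freqs[np.argmax(spectrum)]))


def default_scales(
    fs: float,
    n_scales: int = DEFAULT_N_SCALES,
    fmin: float = DEFAULT_BAND[0],
    fmax: float = DEFAULT_BAND[1],
    wavelet: str = DEFAULT_WAVELET,
) -> np.ndarray:
    """Log-spaced scales whose pseudo-frequencies span [fmin, fmax] Hz.

    Returned in increasing-scale (decreasing-frequency) order.
    """
    if not 0 < fmin < fmax:
        raise ConfigError("need 0 < fmin < fmax")
    freqs = np.logspace(np.log10(fmax), np.log10(fmin), n_scales)
    return central_frequency(wavelet) * fs / freqs


def pseudo_frequencies(
    scales: np.ndarray, fs: float, wavelet: str = DEFAULT_WAVELET
) -> np.ndarray:
    """Pseudo-frequency (Hz) of each scale: fc * fs / a."""
    return central_frequency(wavelet) * fs / np.asarray(scales, dtype=float)


@dataclass
class Scalogram:
    """|CWT| magnitudes on a scales x time grid (rows by increasing scale)."""

    magnitudes: np.ndarray
    scales: np.ndarray
    wavelet_name: str = DEFAULT_WAVELET
    fs: float = 200.0

    def __post_init__(self) -> None:
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        self.scales = np.asarray(self.scales, dtype=float)
        if self.magnitudes.shape[0] != self.scales.size:
            raise ShapeError("one magnitude row per scale required")
        if np.any(self.magnitudes < 0):
            raise ShapeError("scalogram magnitudes must be non-negative")
        if np.any(np.diff(self.scales) <= 0):
            raise ConfigError("scales must be strictly increasing")


@lru_cache(maxsize=16)
def _cwt_plan(wavelet: str, scales_key: tuple, n: int):
    """Precompute FFT'd correlation kernels for a (scales, signal length) pair."""
    from scipy.fft import next_fast_len

    scales = np.asarray(scales_key, dtype=float)
    psi, grid = _wavelet_table(wavelet)
    support = max(abs(grid[0]), abs(grid[-1]))
    half = int(np.ceil(scales.max() * support))
    klen = 2 * half + 1
    nfft = next_fast_len(n + klen - 1)
    kernels_f = np.empty((scales.size, nfft), dtype=complex)
    m = np.arange(-half, half + 1)
    for i, a in enumerate(scales):
        # correlation kernel k[m] = psi*(m/a)/sqrt(a); reversed for convolution
        k = np.conj(wavelet_function(m / a, wavelet)) / np.sqrt(a)
        kernels_f[i] = np.fft.fft(k[::-1], nfft)
    return kernels_f, half, nfft


def cwt(
    window: np.ndarray,
    scales: np.ndarray,
    wavelet: str = DEFAULT_WAVELET,
) -> np.ndarray:
    """Complex CWT coefficients, shape (n_scales, n_samples).

    Scale is expressed in samples; coefficients follow the discretised
    integral  WT(a, b) = sum_m x[m] psi*((m - b)/a) / sqrt(a).
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ShapeError("cwt expects a 1-D window of length >= 2")
    scales = np.atleast_1d(np.asarray(scales, dtype=float))
    if np.any(scales <= 0):
        raise ConfigError("all scales must be positive")
    kernels_f, half, nfft = _cwt_plan(wavelet, tuple(scales.tolist()), x.size)
    xf = np.fft.fft(x, nfft)
    full = np.fft.ifft(xf[None, :] * kernels_f, axis=1)
    return full[:, half : half + x.size]


def cwt_scalogram(
    window: np.ndarray,
    fs: float,
    scales: np.ndarray | None = None,
    wavelet: str = DEFAULT_WAVELET,
) -> Scalogram:
    """Magnitude scalogram of one window on the default 0.5–8 Hz scale grid."""
    if scales is None:
        scales = default_scales(fs, wavelet=wavelet)
    scales = np.atleast_1d(np.asarray(scales, dtype=float))
    coeffs = cwt(window, scales, wavelet)
    # Amplitude (L1) row scaling: dividing |WT| by sqrt(a) makes a tone's
    # response peak at the scale matching its pseudo-frequency and gives
    # constant-amplitude tones scale-independent image intensity — the
    # usual convention for scalogram displays.
    mags = np.abs(coeffs) / np.sqrt(scales)[:, None]
    return Scalogram(magnitudes=mags, scales=scales, wavelet_name=wavelet, fs=fs)


def scalogram_to_rgb(
    s: Scalogram,
    size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
    colormap: str = DEFAULT_COLORMAP,
) -> np.ndarray:
    """Render a scalogram as an H x W x 3 image with values in [0, 1].

    Magnitudes are min–max normalised per window (so a positive scalar
    rescaling of the window leaves the image unchanged), mapped through the
    named colormap, and bilinearly resized with no anti-aliasing (fixed,
    reproducible convention).  A constant-magnitude scalogram maps to the
    uniform image colormap(0).
    """
    mags = s.magnitudes
    span = mags.max() - mags.min()
    if span == 0:
        norm = np.zeros_like(mags)
    else:
        norm = (mags - mags.min()) / span
    rgb = colormaps[colormap](norm)[..., :3]
    if rgb.shape[:2] != tuple(size):
        rgb = _sk_resize(
            rgb, (*size, 3), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    return np.clip(rgb, 0.0, 1.0)


@dataclass
class FusedTensor:
    """H x W x 12 depth stack of the four wavelengths' RGB scalograms.

    Depth blocks [0:3], [3:6], [6:9], [9:12] hold Channels 1..4 in fixed
    order; ``block(k)`` recovers channel ``k``'s image exactly.
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3 * N_CHANNELS:
            raise ShapeError(
                f"fused tensor must have shape (H, W, 12); got {self.pixels.shape}"
            )

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def block(self, k: int) -> np.ndarray:
        """RGB image of channel ``k`` (0-based)."""
        if not 0 <= k < N_CHANNELS:
            raise ConfigError(f"channel index must be in [0, 3]; got {k}")
        return self.pixels[:, :, 3 * k : 3 * k + 3]


def fuse_channels(images: list[np.ndarray] | tuple[np.ndarray, ...]) -> FusedTensor:
    """Stack four H x W x 3 images depth-wise into one H x W x 12 tensor."""
    if len(images) != N_CHANNELS:
        raise ConfigError(f"exactly 4 images required; got {len(images)}")
    images = [np.asarray(im, dtype=float) for im in images]
    shape = images[0].shape
    if any(im.shape != shape for im in images):
        raise ShapeError(f"all images must share one shape; got {[im.shape for im in images]}")
    if len(shape) != 3 or shape[2] != 3:
        raise ShapeError(f"each image must be H x W x 3; got {shape}")
    return FusedTensor(pixels=np.concatenate(images, axis=2))


def window_to_rgb(
    window: np.ndarray,
    fs: float,
    size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
    scales: np.ndarray | None = None,
    wavelet: str = DEFAULT_WAVELET,
    colormap: str = DEFAULT_COLORMAP,
) -> np.ndarray:
    """One-step window → scalogram → RGB image."""
    return scalogram_to_rgb(cwt_scalogram(window, fs, scales, wavelet), size, colormap)


def fuse_window(
    channel_windows: np.ndarray,
    fs: float,
    size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
    scales: np.ndarray | None = None,
    wavelet: str = DEFAULT_WAVELET,
    colormap: str = DEFAULT_COLORMAP,
) -> FusedTensor:
    """Fuse one aligned four-channel window (shape (4, win_len)) to a tensor."""
    channel_windows = np.asarray(channel_windows, dtype=float)
    if channel_windows.ndim != 2 or channel_windows.shape[0] != N_CHANNELS:
        raise ShapeError("expected aligned windows of shape (4, win_len)")
    images = [
        window_to_rgb(channel_windows[k], fs, size, scales, wavelet, colormap)
        for k in range(N_CHANNELS)
    ]
    return fuse_channels(images)
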