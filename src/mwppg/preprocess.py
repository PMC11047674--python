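"""Filtering, quality screening, normalisation and windowing of MWPPG records.

Pipeline order (per record): 0.5–8 Hz zero-phase Butterworth band-pass →
per-channel z-score normalisation → simultaneous four-channel segmentation
into 5 s windows sliding by 1 s → rule-based rejection of abnormal windows.
All four channels are cut on identical sample boundaries and a window is
dropped for *all* channels if *any* channel fails a quality rule, so the
four wavelength views always stay aligned.  Each retained window inherits
its record's cuff (SBP, DBP) label unchanged — the cuff is read once per
one-minute acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (
    ConfigError,
    DegenerateInputError,
    LengthError,
    SamplingError,
    ShapeError,
)
from .signal_io import MWPPGRecord, N_CHANNELS

DEFAULT_BAND = (0.5, 8.0)   # Hz
DEFAULT_ORDER = 2
WINDOW_SECONDS = 5.0
STRIDE_SECONDS = 1.0


def bandpass_filter(
    x: np.ndarray,
    fs: float,
    low: float = DEFAULT_BAND[0],
    high: float = DEFAULT_BAND[1],
    order: int = DEFAULT_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (default 0.5–8 Hz, order 2).

    Applied forward and backward (``sosfiltfilt``), which preserves pulse
    landmark timing; the effective magnitude response is the squared
    single-pass response.  Output has the input's length; DC is removed.
    """
    if not fs > 2 * high:
        raise SamplingError(
            f"fs={fs} Hz cannot represent the {high} Hz band edge (need fs > {2 * high})"
        )
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ShapeError("bandpass_filter expects a 1-D signal")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    min_len = 3 * (2 * order) + 1
    if x.size <= min_len:
        raise LengthError(f"signal too short to filter (need > {min_len} samples)")
    return sps.sosfiltfilt(sos, x)


def normalize(x: np.ndarray) -> np.ndarray:
    """Z-score a signal to zero mean, unit variance.

    Affine-invariant: ``normalize(a*x + b) == normalize(x)`` for a > 0.
    Raises :class:`DegenerateInputError` for (near-)constant input.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("cannot z-score a constant signal")
    return (x - x.mean()) / sd


def segment_windows(
    x: np.ndarray,
    fs: float,
    win: float = WINDOW_SECONDS,
    stride: float = STRIDE_SECONDS,
) -> np.ndarray:
    """Cut a signal into ``win``-second windows sliding by ``stride`` seconds.

    Returns an array of shape ``(n_windows, win*fs)`` with
    ``n_windows = floor((len/fs - win)/stride) + 1``; no padding is used.
    """
    x = np.asarray(x, dtype=float)
    win_len = int(round(win * fs))
    stride_len = int(round(stride * fs))
    if win_len <= 0 or stride_len <= 0:
        raise ConfigError("win and stride must be positive")
    if x.size < win_len:
        raise LengthError(
            f"signal of {x.size} samples shorter than one {win} s window ({win_len} samples)"
        )
    n_win = (x.size - win_len) // stride_len + 1
    starts = np.arange(n_win) * stride_len
    return np.stack([x[s : s + win_len] for s in starts])


@dataclass(frozen=True)
class QualityRule:
    """Thresholds for abnormal-window rejection.

    max_flatline_fraction
        Largest tolerated fraction of samples in runs of (numerically)
        unchanging signal — catches sensor dropouts and clipping plateaus.
    amplitude_z_limit
        Largest tolerated |sample - window mean| in window-SD units —
        catches isolated spikes.
    min_periodicity
        Smallest tolerated autocorrelation peak in the physiologic beat-lag
        range (40–180 bpm) — catches windows with no cardiac rhythm.
    """

    max_flatline_fraction: float = 0.3
    amplitude_z_limit: float = 6.0
    min_periodicity: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_flatline_fraction <= 1.0:
            raise ConfigError("max_flatline_fraction must lie in [0, 1]")
        if self.amplitude_z_limit <= 0:
            raise ConfigError("amplitude_z_limit must be positive")
        if not 0.0 <= self.min_periodicity <= 1.0:
            raise ConfigError("min_periodicity must lie in [0, 1]")


def _flatline_fraction(w: np.ndarray) -> float:
    scale = np.ptp(w)
    if scale == 0:
        return 1.0
    return float(np.mean(np.abs(np.diff(w)) < 1e-4 * scale))


def _max_abs_z(w: np.ndarray) -> float:
    sd = w.std()
    if sd == 0:
        return np.inf
    return float(np.max(np.abs(w - w.mean())) / sd)


def _periodicity(w: np.ndarray, fs: float) -> float:
    w = w - w.mean()
    denom = float(np.dot(w, w))
    if denom == 0:
        return 0.0
    ac = sps.correlate(w, w, mode="full")[w.size - 1 :] / denom
    lo = int(fs * 60.0 / 180.0)   # 180 bpm
    hi = min(int(fs * 60.0 / 40.0), w.size - 1)  # 40 bpm
    if lo >= hi:
        return 0.0
    return float(ac[lo:hi].max())


def window_quality_flags(w: np.ndarray, fs: float, rule: QualityRule) -> list[str]:
    """Names of the rules a single-channel window violates (empty = clean)."""
    reasons = []
    if _flatline_fraction(w) > rule.max_flatline_fraction:
        reasons.append("flatline")
    if _max_abs_z(w) > rule.amplitude_z_limit:
        reasons.append("amplitude")
    if _periodicity(w, fs) < rule.min_periodicity:
        reasons.append("aperiodic")
    return reasons


@dataclass
class WindowSet:
    """Aligned 5 s windows for all four channels of one record.

    ``windows`` has shape (4, n_windows, win_len); window ``i`` covers the
    same sample indices in every channel.  The record's cuff label is
    broadcast to every window.
    """

    windows: np.ndarray
    subject_id: str
    fs: float
    window_indices: np.ndarray
    sbp: float | None = None
    dbp: float | None = None

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3 or self.windows.shape[0] != N_CHANNELS:
            raise ShapeError(
                f"windows must have shape (4, n_windows, win_len); got {self.windows.shape}"
            )
        self.window_indices = np.asarray(self.window_indices, dtype=int)
        if self.window_indices.shape != (self.windows.shape[1],):
            raise ShapeError("window_indices must match the number of windows")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[1]

    @property
    def win_len(self) -> int:
        return self.windows.shape[2]


def make_window_set(
    record: MWPPGRecord,
    win: float = WINDOW_SECONDS,
    stride: float = STRIDE_SECONDS,
    band: tuple[float, float] = DEFAULT_BAND,
    order: int = DEFAULT_ORDER,
) -> WindowSet:
    """Filter, normalise and segment one record into aligned windows."""
    chans = []
    for k in range(N_CHANNELS):
        y = bandpass_filter(record.samples[k], record.fs, band[0], band[1], order)
        y = normalize(y)
        chans.append(segment_windows(y, record.fs, win, stride))
    return WindowSet(
        windows=np.stack(chans),
        subject_id=record.subject_id,
        fs=record.fs,
        window_indices=np.arange(chans[0].shape[0]),
        sbp=record.sbp,
        dbp=record.dbp,
    )


def reject_abnormal(
    ws: WindowSet, rule: QualityRule | None = None
) -> tuple[WindowSet, pd.DataFrame]:
    """Drop windows violating the quality rule in *any* channel.

    Returns the retained (still four-channel-aligned) window set plus a
    drop log with one row per (window, channel, reason).  An empty result
    is allowed; it appears in the log rather than raising.
    """
    if ws.n_windows == 0:
        raise ShapeError("reject_abnormal requires a non-empty window set")
    rule = rule if rule is not None else QualityRule()
    keep = np.ones(ws.n_windows, dtype=bool)
    log_rows = []
    for i in range(ws.n_windows):
        for k in range(N_CHANNELS):
            reasons = window_quality_flags(ws.windows[k, i], ws.fs, rule)
            if reasons:
                keep[i] = False
                for reason in reasons:
                    log_rows.append(
                        {
                            "subject_id": ws.subject_id,
                            "window_index": int(ws.window_indices[i]),
                            "channel": k + 1,
                            "reason": reason,
                        }
                    )
    if not keep.any():
        log_rows.append(
            {
                "subject_id": ws.subject_id,
                "window_index": -1,
                "channel": 0,
                "reason": "all_windows_rejected",
            }
        )
    log = pd.DataFrame(
        log_rows, columns=["subject_id", "window_index", "channel", "reason"]
    )
    retained = WindowSet(
        windows=ws.windows[:, keep],
        subject_id=ws.subject_id,
        fs=ws.fs,
        window_indices=ws.window_indices[keep],
        sbp=ws.sbp,
        dbp=ws.dbp,
    )
    return retained, log


def preprocess_record(
    record: MWPPGRecord,
    rule: QualityRule | None = None,
    win: float = WINDOW_SECONDS,
    stride: float = STRIDE_SECONDS,
) -> tuple[WindowSet, pd.DataFrame]:
    """Full preprocessing for one record: filter → normalise → cut → screen."""
    ws = make_window_set(record, win=win, stride=stride)
    return reject_abnormal(ws, rule)
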