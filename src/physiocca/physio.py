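"""Cleaning of respiratory/cardiac recordings and frame-level physiological measures.

The respiratory belt and pulse-oximetry traces arrive as raw one-channel
recordings (400 Hz in the study this pipeline targets).  This module turns
them into the measures used downstream, all defined on the fMRI frame grid:

* RVT — respiration volume per time, the difference between the upper and
  lower envelopes of the belt trace (breathing depth x rate).
* ENV — windowed envelope of the rectified trace (default 10 s window).
* RV  — windowed standard deviation of the trace (default 6 s window).
* HR  — instantaneous heart rate, 60 / inter-beat interval in bpm.

All filtering is zero-phase (forward-backward Butterworth): phase
distortion would bias the lag estimation performed later in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .errors import DegenerateInputError, InvalidArgumentError

# MATLAB-style scaled MAD: outliers are |x - med| > 3 * 1.4826 * MAD.
_MAD_SCALE = 1.4826


@dataclass
class PhysioTrace:
    """A physiological recording at a fixed sampling rate.

    Parameters
    ----------
    samples : 1-D array of belt/oximeter readings, arbitrary units.
    fs : sampling rate in Hz.
    kind : ``"respiratory"`` or ``"cardiac"``.
    state : ``"raw"`` or ``"cleaned"``.
    meta : free-form provenance (e.g. the generator's inter-beat intervals).
    """

    samples: np.ndarray
    fs: float
    kind: Literal["respiratory", "cardiac"]
    state: Literal["raw", "cleaned"] = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise InvalidArgumentError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs


@dataclass
class FrameSeries:
    """One value per fMRI frame (TR-spaced), e.g. RVT, HR or the global signal."""

    values: np.ndarray
    tr_s: float
    measure: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.tr_s <= 0:
            raise InvalidArgumentError("TR must be positive")

    def __len__(self) -> int:
        return self.values.size


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("zero-variance trace")
    return (x - x.mean()) / sd


def _replace_local_outliers(x: np.ndarray, window: int) -> np.ndarray:
    """Replace samples > 3 scaled-MAD from the local (centered) median by
    linear interpolation.  MAD == 0 segments are treated as outlier-free."""
    window = max(int(window), 3)
    med = ndimage.median_filter(x, size=window, mode="nearest")
    mad = ndimage.median_filter(np.abs(x - med), size=window, mode="nearest")
    thresh = 3.0 * _MAD_SCALE * mad
    bad = (np.abs(x - med) > thresh) & (mad > 0)
    if not bad.any():
        return x.copy()
    good = ~bad
    if good.sum() < 2:
        raise DegenerateInputError("almost all samples flagged as outliers")
    idx = np.arange(x.size)
    out = x.copy()
    out[bad] = np.interp(idx[bad], idx[good], x[good])
    return out


def _butter_filtfilt(x: np.ndarray, fs: float, btype: str, cutoff) -> np.ndarray:
    sos = signal.butter(2, cutoff, btype=btype, fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def clean_respiratory_trace(raw: PhysioTrace, *, lowpass_hz: float = 5.0,
                            outlier_window_s: float = 0.3) -> PhysioTrace:
    """Clean a raw belt trace.

    Pipeline order: z-score -> linear detrend -> local-median outlier
    replacement (3 scaled MAD, centered window of ``outlier_window_s``,
    i.e. 120 samples at 400 Hz) -> zero-phase order-2 Butterworth low-pass
    at ``lowpass_hz`` -> z-score.  Output has mean 0 and SD 1.
    """
    if raw.kind != "respiratory":
        raise InvalidArgumentError("expected a respiratory trace")
    x = raw.samples
    if x.size < 16:
        raise InvalidArgumentError("trace shorter than filter warm-up")
    x = _zscore(x)
    x = signal.detrend(x, type="linear")
    x = _replace_local_outliers(x, round(outlier_window_s * raw.fs))
    x = _butter_filtfilt(x, raw.fs, "lowpass", lowpass_hz)
    x = _zscore(x)
    return replace(raw, samples=x, state="cleaned")


def clean_cardiac_trace(raw: PhysioTrace, *, band_hz: tuple[float, float] = (0.3, 10.0)) -> PhysioTrace:
    """z-score then zero-phase order-2 Butterworth band-pass (0.3-10 Hz)."""
    if raw.kind != "cardiac":
        raise InvalidArgumentError("expected a cardiac trace")
    x = raw.samples
    if x.size < 16:
        raise InvalidArgumentError("trace shorter than filter warm-up")
    x = _zscore(x)
    x = _butter_filtfilt(x, raw.fs, "bandpass", list(band_hz))
    return replace(raw, samples=x, state="cleaned")


def _envelope(x: np.ndarray, extrema_idx: np.ndarray) -> np.ndarray:
    # Linear interpolation between extrema; edges clamp to nearest extremum.
    idx = np.arange(x.size)
    return np.interp(idx, extrema_idx, x[extrema_idx])


def derive_respiration_measure(trace: PhysioTrace, measure: str,
                               window_s: float | None = None,
                               *, min_breath_s: float = 1.0,
                               env_mode: str = "max") -> np.ndarray:
    """Derive RVT, ENV or RV from a cleaned belt trace, at the trace's rate.

    RVT: upper minus lower signal envelope, each built by peak/trough
    detection (minimum distance ``min_breath_s``, breathing being slower
    than 1 Hz) and linear interpolation.  ENV: sliding-window maximum of
    the rectified trace (default 10 s window); ``env_mode="hilbert"``
    instead smooths the analytic-signal magnitude over the window.  RV:
    sliding-window standard deviation (default 6 s window).  Sliding
    windows shrink at the boundaries rather than padding.
    """
    if trace.state != "cleaned":
        raise InvalidArgumentError("derive measures from a cleaned trace")
    if trace.duration_s < 10:
        raise InvalidArgumentError("trace shorter than 10 s")
    x = trace.samples
    fs = trace.fs
    measure = measure.upper()
    if measure == "RVT":
        dist = max(int(min_breath_s * fs), 1)
        peaks, _ = signal.find_peaks(x, distance=dist)
        troughs, _ = signal.find_peaks(-x, distance=dist)
        if peaks.size < 3 or troughs.size < 3:
            raise DegenerateInputError("fewer than 3 detected breaths")
        upper = _envelope(x, peaks)
        lower = _envelope(x, troughs)
        return np.maximum(upper - lower, 0.0)
    if window_s is None:
        window_s = 10.0 if measure == "ENV" else 6.0
    win = max(int(round(window_s * fs)), 2)
    if measure == "ENV":
        if env_mode == "hilbert":
            mag = np.abs(signal.hilbert(x))
            return ndimage.uniform_filter1d(mag, size=win, mode="nearest")
        return ndimage.maximum_filter1d(np.abs(x), size=win, mode="nearest")
    if measure == "RV":
        rv = pd.Series(x).rolling(win, center=True, min_periods=2).std().to_numpy()
        # endpoints where <2 samples fall in the shrunk window
        if np.isnan(rv).any():
            idx = np.arange(rv.size)
            ok = ~np.isnan(rv)
            rv = np.interp(idx, idx[ok], rv[ok])
        return rv
    raise InvalidArgumentError(f"unknown respiration measure {measure!r}")


def compute_heart_rate(trace: PhysioTrace, *, min_ibi_s: float = 0.3,
                       hr_range_bpm: tuple[float, float] = (30.0, 180.0),
                       outlier_window_s: float = 30.0) -> np.ndarray:
    """Instantaneous heart rate (bpm) on the trace's sample grid.

    Peaks are detected with a minimum separation of ``min_ibi_s``; HR is
    60 / inter-beat-interval, assigned to the interval midpoint and
    linearly interpolated to the sample grid.  Beat-level outliers (beyond
    3 scaled MAD from the local 30 s median, or outside the physiological
    ``hr_range_bpm``) are replaced by interpolation across beats.
    """
    if trace.kind != "cardiac":
        raise InvalidArgumentError("expected a cardiac trace")
    x = trace.samples
    fs = trace.fs
    peaks, _ = signal.find_peaks(x, distance=max(int(min_ibi_s * fs), 1),
                                 prominence=0.5 * x.std())
    if peaks.size < 2:
        raise DegenerateInputError("fewer than 2 detected beats")
    ibi = np.diff(peaks) / fs
    hr = 60.0 / ibi
    mid = (peaks[:-1] + peaks[1:]) / 2.0  # sample index of interval midpoint

    # beat-domain outlier replacement; window converted from seconds to beats
    n_beats_win = max(int(round(outlier_window_s / max(ibi.mean(), 1e-6))), 3)
    med = ndimage.median_filter(hr, size=n_beats_win, mode="nearest")
    mad = ndimage.median_filter(np.abs(hr - med), size=n_beats_win, mode="nearest")
    bad = ((np.abs(hr - med) > 3.0 * _MAD_SCALE * mad) & (mad > 0)) | \
        (hr < hr_range_bpm[0]) | (hr > hr_range_bpm[1])
    if bad.all():
        raise DegenerateInputError("no physiologically plausible beats")
    if bad.any():
        hr = hr.copy()
        hr[bad] = np.interp(mid[bad], mid[~bad], hr[~bad])
    return np.interp(np.arange(x.size), mid, hr)


def resample_to_frames(series: np.ndarray, fs: float, n_frames: int,
                       tr_s: float, measure: str = "") -> FrameSeries:
    """Block-average a sample-rate series onto the TR grid.

    Frame ``k`` is the mean of the samples whose time falls in
    ``[k*tr, (k+1)*tr)``.  The series must cover ``n_frames * tr`` of
    signal, with a one-frame tolerance (the last frame may be partial).
    """
    series = np.asarray(series, dtype=float).ravel()
    if fs * tr_s < 1:
        raise InvalidArgumentError("need at least one sample per TR")
    needed = n_frames * tr_s
    if series.size / fs < needed - tr_s:
        raise InvalidArgumentError(
            f"series covers {series.size / fs:.2f} s but {needed:.2f} s required")
    edges = np.floor(np.arange(n_frames + 1) * fs * tr_s).astype(int)
    edges = np.minimum(edges, series.size)
    if edges[-2] >= series.size:
        raise InvalidArgumentError("series too short for requested frame count")
    out = np.empty(n_frames)
    for k in range(n_frames):
        lo, hi = edges[k], edges[k + 1]
        out[k] = series[lo:hi].mean() if hi > lo else series[lo - 1]
    return FrameSeries(out, tr_s, measure=measure)
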