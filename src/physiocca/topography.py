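"""Global signal, lag optimization, and per-participant coupling topographies.

The global signal (GS) is the unweighted mean BOLD time series across all
ROIs of a run.  A coupling topography is the per-ROI Fisher-z Pearson
correlation between a reference frame series (the GS itself, or a lagged
and possibly sign-flipped physiological measure) and each ROI's time
series, averaged across a participant's runs:

* GSCORR  — reference is the GS at zero lag,
* RVTCORR — reference is RVT, flipped and shifted backward by the group
  lag (16 frames = 11.5 s at TR 0.72 s in the study conditions),
* HRCORR / ENVCORR / RVCORR — same construction for HR, ENV, RV.

"Shifted backward by L" means the physiological sample at time t - L is
paired with BOLD at time t.  Lags are searched on the integer frame grid
over +/- ``max_lag_s`` (72 s); the selected lag maximizes the absolute
group-averaged cross-correlation, and ``flip`` records whether the
correlation there is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateInputError, InvalidArgumentError
from .physio import FrameSeries

R_CLIP = 1.0 - 1e-7  # |r| ceiling before atanh


@dataclass
class RunSeries:
    """One run's ROI x frame BOLD matrix."""

    bold: np.ndarray
    tr_s: float
    roi_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.bold = np.atleast_2d(np.asarray(self.bold, dtype=float))
        if self.roi_ids is None:
            self.roi_ids = [f"roi{i:04d}" for i in range(self.bold.shape[0])]
        if len(self.roi_ids) != self.bold.shape[0]:
            raise InvalidArgumentError("roi_ids length mismatch")

    @property
    def n_roi(self) -> int:
        return self.bold.shape[0]

    @property
    def n_frames(self) -> int:
        return self.bold.shape[1]


@dataclass
class Topography:
    """Per-ROI Fisher-z coupling values for one participant."""

    values: np.ndarray
    measure: str
    n_runs_averaged: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()


@dataclass
class LagEstimate:
    """Optimal cross-correlation lag between GS and a physiological series."""

    lag_frames: int
    lag_s: float
    flip: bool
    xcorr_profile: np.ndarray  # mean correlation per lag
    lags: np.ndarray           # lag grid in frames


def compute_global_signal(run: RunSeries) -> FrameSeries:
    """Unweighted mean across ROI rows, one value per frame."""
    if run.n_roi == 0:
        raise InvalidArgumentError("empty ROI set")
    return FrameSeries(run.bold.mean(axis=0), run.tr_s, measure="GS")


def truncate(obj, n_edge: int = 10):
    """Drop the first and last ``n_edge`` frames of a FrameSeries/RunSeries/array."""
    if n_edge < 0:
        raise InvalidArgumentError("n_edge must be non-negative")
    if isinstance(obj, FrameSeries):
        n = len(obj)
    elif isinstance(obj, RunSeries):
        n = obj.n_frames
    else:
        n = np.asarray(obj).shape[-1]
    if n <= 2 * n_edge:
        raise InvalidArgumentError(f"length {n} too short for truncation by {n_edge}")
    if n_edge == 0:
        return obj
    sl = slice(n_edge, n - n_edge)
    if isinstance(obj, FrameSeries):
        return replace(obj, values=obj.values[sl])
    if isinstance(obj, RunSeries):
        return replace(obj, bold=obj.bold[:, sl])
    return np.asarray(obj)[..., sl]


def _lagged_pair(a: np.ndarray, b: np.ndarray, lag: int):
    """Overlapping segments pairing a[t] with b[t - lag] (no padding)."""
    n = min(a.shape[-1], b.shape[-1])
    a = a[..., :n]
    b = b[..., :n]
    if lag > 0:
        return a[..., lag:], b[..., : n - lag]
    if lag < 0:
        return a[..., : n + lag], b[..., -lag:]
    return a, b

def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt((a @ a) * (b @ b))
    if den == 0:
        return np.nan
    return float(a @ b / den)


def _lag_profile(pairs, lags: np.ndarray) -> np.ndarray:
    """Mean cross-correlation per lag over (gs, physio) run pairs.

    ``pairs`` is a list of participants, each a list of (gs, physio) arrays;
    correlations are averaged across runs within a participant first, then
    across participants.
    """
    per_participant = []
    for runs in pairs:
        prof = np.full((len(runs), lags.size), np.nan)
        for i, (g, p) in enumerate(runs):
            for j, lag in enumerate(lags):
                ga, pa = _lagged_pair(g, p, int(lag))
                if ga.size < 3:
                    raise InvalidArgumentError(
                        f"overlap shorter than 3 frames at lag {lag}")
                prof[i, j] = _pearson(ga, pa)
        per_participant.append(np.nanmean(prof, axis=0))
    return np.nanmean(np.asarray(per_participant), axis=0)


def _as_nested(gs_by_run, physio_by_run):
    """Accept flat lists (one participant per run) or lists of per-participant lists."""
    def vals(x):
        return x.values if isinstance(x, FrameSeries) else np.asarray(x, float)
    if len(gs_by_run) != len(physio_by_run):
        raise InvalidArgumentError("gs and physio lists must pair up")
    nested = []
    for g, p in zip(gs_by_run, physio_by_run):
        if isinstance(g, (list, tuple)):
            nested.append([(vals(gi), vals(pi)) for gi, pi in zip(g, p)])
        else:
            nested.append([(vals(g), vals(p))])
    return nested


def estimate_group_lag(gs_by_run, physio_by_run, max_lag_s: float = 72.0,
                       tr_s: float | None = None) -> LagEstimate:
    """Group-level lag of maximal |mean cross-correlation|.

    Ties in |correlation| break toward the smaller |lag| (then toward the
    negative lag).  ``flip`` is True when the mean correlation at the
    selected lag is negative.
    """
    nested = _as_nested(gs_by_run, physio_by_run)
    if tr_s is None:
        first = gs_by_run[0]
        while isinstance(first, (list, tuple)):
            first = first[0]
        if not isinstance(first, FrameSeries):
            raise InvalidArgumentError("tr_s required when passing bare arrays")
        tr_s = first.tr_s
    max_lag = int(round(max_lag_s / tr_s))
    lags = np.arange(-max_lag, max_lag + 1)
    profile = _lag_profile(nested, lags)
    if np.isnan(profile).all():
        raise DegenerateInputError("all lag correlations undefined")
    order = np.lexsort((lags, np.abs(lags), -np.abs(profile)))
    best = order[0]
    lag = int(lags[best])
    return LagEstimate(lag_frames=lag, lag_s=lag * tr_s,
                       flip=bool(profile[best] < 0),
                       xcorr_profile=profile, lags=lags)


def estimate_individual_lag(gs, physio, max_lag_s: float = 72.0,
                            tr_s: float | None = None) -> LagEstimate:
    """Per-participant lag: identical machinery, averaging over that
    participant's runs only.  ``gs``/``physio`` may be a single FrameSeries
    or a list of runs."""
    if not isinstance(gs, (list, tuple)):
        gs, physio = [gs], [physio]
    return estimate_group_lag([list(gs)], [list(physio)], max_lag_s, tr_s)


def fisher_z(r: np.ndarray) -> np.ndarray:
    """atanh with |r| clipped to 1 - 1e-7 so averaging stays finite."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def _roi_correlations(bold: np.ndarray, ref: np.ndarray) -> np.ndarray:
    b = bold - bold.mean(axis=1, keepdims=True)
    r = ref - ref.mean()
    denom = np.sqrt((b * b).sum(axis=1) * (r @ r))
    with np.errstate(invalid="ignore", divide="ignore"):
        rr = (b @ r) / denom
    rr[denom == 0] = np.nan
    return rr


def compute_coupling_map(runs, reference_by_run, lag: LagEstimate | int | None = None,
                         flip: bool | None = None, measure: str = "GSCORR") -> Topography:
    """Per-ROI Fisher-z correlation with a (lagged, optionally flipped)
    reference, averaged across runs.

    ``lag`` may be a :class:`LagEstimate` (its flip is used unless ``flip``
    overrides), an integer frame shift, or ``None``/0 for zero lag.
    Zero-variance ROIs yield NaN for that run and are excluded from the
    run average; a ROI missing in every run raises.
    """
    if isinstance(lag, LagEstimate):
        lag_frames = lag.lag_frames
        do_flip = lag.flip if flip is None else flip
    else:
        lag_frames = int(lag or 0)
        do_flip = bool(flip)
    zs = []
    for run, ref in zip(runs, reference_by_run):
        ref_v = ref.values if isinstance(ref, FrameSeries) else np.asarray(ref, float)
        if do_flip:
            ref_v = -ref_v
        bold_a, ref_a = _lagged_pair(run.bold, ref_v, lag_frames)
        if np.nanstd(ref_a) == 0:
            raise DegenerateInputError("zero-variance reference series")
        zs.append(fisher_z(_roi_correlations(bold_a, ref_a)))
    z = np.asarray(zs)
    if np.isnan(z).all(axis=0).any():
        raise DegenerateInputError("some ROI is undefined in every run")
    with np.errstate(invalid="ignore"):
        avg = np.nanmean(z, axis=0)
    return Topography(avg, measure=measure, n_runs_averaged=len(zs))
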