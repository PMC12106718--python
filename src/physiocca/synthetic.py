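"""Synthetic cohorts with known ground truth for every pipeline stage.

The generator emulates the statistical structure of a resting-state twin
cohort with concurrent physiological recordings:

* a shared low-frequency (< 0.1 Hz) global BOLD component ``g(t)`` — an
  AR(1) process (phi = 0.9) band-limited below 0.1 Hz — loading onto ROIs
  with heterogeneous per-participant weights;
* a quasi-periodic respiratory belt trace (carrier ~0.3 Hz) whose
  infra-slow (~0.03 Hz) amplitude modulation defines RVT; the *flipped*
  RVT, delayed by ``true_lag_frames`` (default 16 frames = 11.5 s at TR
  0.72 s), couples into BOLD through a per-participant spatial map;
* a pulsatile cardiac trace (~70 bpm) whose slow heart-rate variability
  couples weakly into BOLD at a 1-frame positive lag;
* a behavior battery carrying a planted canonical mode: a participant
  latent that also tilts the topography along a fixed spatial direction,
  with the brain/behavior latents correlated at ``true_canonical_r``;
* family blocks (MZ pairs, DZ pairs, singletons) implemented as a shared
  family-level random effect on the latents, and ~0.93% missing
  behavioral cells.

All randomness flows through one seeded ``numpy`` generator, so identical
seed and configuration reproduce the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InvalidArgumentError
from .physio import PhysioTrace
from .topography import RunSeries

NETWORKS = ["LN", "DMN", "SN", "CN", "SMN", "TPN", "DAN", "VN"]


@dataclass
class GroundTruth:
    global_loadings: np.ndarray          # base per-ROI weight of g(t)
    resp_coupling_map: np.ndarray        # base per-ROI weight of -RVT(t - lag)
    true_lag_frames: int
    true_flip: bool
    true_canonical_r: float
    behavior_loadings: np.ndarray        # per-measure weight of the latent mode
    mode_topography: np.ndarray          # unit spatial direction of the mode
    latent_brain: np.ndarray             # z_p per participant
    latent_behavior: np.ndarray          # u_p per participant
    family_blocks: dict[str, str] = field(default_factory=dict)
    mz_pairs: list[tuple[str, str]] = field(default_factory=list)
    hr_lag_frames: int = 1
    participant_loadings: np.ndarray | None = None  # (n, roi) realized loadings
    participant_resp_maps: np.ndarray | None = None


@dataclass
class SyntheticCohort:
    participants: list[str]
    runs: dict[str, list[RunSeries]]
    rvt_frames: dict[str, list[np.ndarray]]   # planted RVT on the frame grid
    hr_frames: dict[str, list[np.ndarray]]
    resp_traces: dict[str, list[PhysioTrace]] | None
    cardiac_traces: dict[str, list[PhysioTrace]] | None
    behavior: pd.DataFrame
    confounds: pd.DataFrame
    family: pd.DataFrame                      # participant, family_id, zygosity
    atlas: pd.DataFrame                       # roi, network
    tr_s: float
    physio_fs: float
    truth: GroundTruth

    @property
    def n_roi(self) -> int:
        return len(self.atlas)

    @property
    def n_frames(self) -> int:
        return self.runs[self.participants[0]][0].n_frames


def generate_respiratory_trace(duration_s: float, fs: float,
                               carrier_hz: float = 0.3, mod_hz: float = 0.03,
                               mod_depth: float = 0.5, noise_sd: float = 0.05,
                               seed: int | None = None) -> PhysioTrace:
    """Amplitude-modulated sinusoid emulating a respiratory belt trace:
    ``(1 + mod_depth sin(2 pi mod_hz t)) sin(2 pi carrier_hz t) + noise``."""
    if duration_s <= 0 or fs <= 0:
        raise InvalidArgumentError("duration and fs must be positive")
    if fs <= 2 * carrier_hz:
        raise InvalidArgumentError("fs must exceed twice the carrier frequency")
    if not 0 <= mod_depth < 1:
        raise InvalidArgumentError("mod_depth must lie in [0, 1)")
    n = round(duration_s * fs)
    t = np.arange(n) / fs
    x = (1 + mod_depth * np.sin(2 * np.pi * mod_hz * t)) * np.sin(2 * np.pi * carrier_hz * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        x = x + noise_sd * rng.standard_normal(n)
    return PhysioTrace(x, fs, kind="respiratory", state="raw",
                       meta={"carrier_hz": carrier_hz, "mod_hz": mod_hz,
                             "mod_depth": mod_depth})


def _pulse_waveform(beat_times: np.ndarray, duration_s: float, fs: float,
                    width_s: float = 0.25) -> np.ndarray:
    """Raised-cosine pulse train at the given beat times."""
    n = round(duration_s * fs)
    x = np.zeros(n)
    half = int(width_s * fs / 2)
    shape = np.hanning(2 * half + 1)  # peak at the beat time
    for bt in beat_times:
        c = round(bt * fs)
        lo, hi = c - half, c + half + 1
        slo, shi = max(lo, 0), min(hi, n)
        if shi <= slo:
            continue
        x[slo:shi] += shape[slo - lo: shi - lo]
    return x


def generate_cardiac_trace(duration_s: float, fs: float,
                           mean_hr_bpm: float = 70.0, hr_sd_bpm: float = 3.0,
                           seed: int | None = None) -> PhysioTrace:
    """Pulse-oximetry-like waveform with inter-beat intervals drawn around
    60 / mean_hr_bpm; the sampled IBI sequence is stored in ``meta``."""
    if duration_s <= 0 or mean_hr_bpm <= 0:
        raise InvalidArgumentError("duration and mean heart rate must be positive")
    if fs < 50:
        raise InvalidArgumentError("cardiac traces need fs >= 50 Hz")
    if hr_sd_bpm < 0:
        raise InvalidArgumentError("hr_sd_bpm must be non-negative")
    rng = np.random.default_rng(seed)
    beats = [30.0 / mean_hr_bpm]  # first beat half an interval in, so its
    ibis = []                     # pulse shape is fully inside the recording
    # HRV as an AR(1) walk (phi=0.9) with unit marginal variance: real
    # beat-to-beat variability is autocorrelated, not white
    phi = 0.9
    state = rng.standard_normal()
    while beats[-1] < duration_s:
        hr = max(mean_hr_bpm + hr_sd_bpm * state, 20.0)
        state = phi * state + np.sqrt(1 - phi ** 2) * rng.standard_normal()
        ibi = 60.0 / hr
        ibis.append(ibi)
        beats.append(beats[-1] + ibi)
    x = _pulse_waveform(np.asarray(beats[:-1]), duration_s, fs)
    return PhysioTrace(x, fs, kind="cardiac", state="raw",
                       meta={"ibis_s": np.asarray(ibis[:-1]),
                             "beat_times_s": np.asarray(beats[:-2])})


def _band_limited_noise(n: int, fs: float, band: tuple[float, float],
                        rng: np.random.Generator) -> np.ndarray:
    """z-scored band-pass filtered white noise (order-2 Butterworth, zero phase)."""
    lo = max(band[0], 1e-4)
    hi = min(band[1], 0.49 * fs)
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    pad = int(4 * fs / lo)
    x = signal.sosfiltfilt(sos, rng.standard_normal(n + 2 * pad))[pad:pad + n]
    return (x - x.mean()) / x.std()


def _global_component(n: int, fs: float, rng: np.random.Generator,
                      phi: float = 0.9, cutoff_hz: float = 0.1) -> np.ndarray:
    """AR(1) innovation process band-limited below ``cutoff_hz``, z-scored."""
    burn = 50
    e = rng.standard_normal(n + burn)
    g = signal.lfilter([1.0], [1.0, -phi], e)[burn:]
    sos = signal.butter(2, cutoff_hz, btype="lowpass", fs=fs, output="sos")
    g = signal.sosfiltfilt(sos, g)
    return (g - g.mean()) / g.std()


def _make_families(n: int, mz_frac: float, dz_frac: float,
                   rng: np.random.Generator):
    """Assign participants to MZ pairs, DZ pairs and singletons."""
    pids = [f"P{i:04d}" for i in range(n)]
    n_mz = int(n * mz_frac / 2)
    n_dz = int(n * dz_frac / 2)
    rows = []
    mz_pairs = []
    fam = 0
    i = 0
    for _ in range(n_mz):
        a, b = pids[i], pids[i + 1]
        rows += [(a, f"F{fam:04d}", "MZ"), (b, f"F{fam:04d}", "MZ")]
        mz_pairs.append((a, b))
        fam += 1
        i += 2
    for _ in range(n_dz):
        rows += [(pids[i], f"F{fam:04d}", "DZ"), (pids[i + 1], f"F{fam:04d}", "DZ")]
        fam += 1
        i += 2
    while i < n:
        rows.append((pids[i], f"F{fam:04d}", "NT"))
        fam += 1
        i += 1
    table = pd.DataFrame(rows, columns=["participant", "family_id", "zygosity"])
    return pids, table, mz_pairs


def _family_latent(table: pd.DataFrame, fam_var: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Standard-normal latent with a family random effect of variance fam_var."""
    fids = table["family_id"].to_numpy()
    uniq = pd.unique(fids)
    f = dict(zip(uniq, rng.standard_normal(uniq.size)))
    shared = np.array([f[x] for x in fids])
    ind = rng.standard_normal(len(fids))
    return np.sqrt(fam_var) * shared + np.sqrt(1 - fam_var) * ind


def generate_cohort(n_participants: int, n_roi: int = 100, n_frames: int = 1200,
                    tr_s: float = 0.72, n_runs: int = 1, *,
                    true_lag_frames: int = 16, true_canonical_r: float = 0.7,
                    coupled_maps: bool = True, resp_gain: float = 0.3,
                    hr_gain: float = 0.1, hr_lag_frames: int = 1,
                    mode_strength: float = 1.0, map_noise_sd: float = 0.2,
                    bold_noise_sd: float = 1.0, n_behaviors: int = 60,
                    family_variance: float = 0.3, mz_frac: float = 0.3,
                    dz_frac: float = 0.2, missing_rate: float = 0.0093,
                    store_physio: bool = False, physio_fs: float = 400.0,
                    carrier_hz: float = 0.3, mod_hz: float = 0.03,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate a cohort with a recoverable answer at every pipeline stage.

    BOLD model per run:
    ``bold(roi, t) = L_p(roi) g(t) - M_p(roi) rvt(t - lag) + H_p(roi) hr(t - 1)
    + noise`` where ``L_p`` are the participant's global loadings (base
    profile, tilted along the planted mode direction by the brain latent,
    plus idiosyncratic map noise), ``M_p = resp_gain * L_p`` when
    ``coupled_maps`` (an independent map otherwise) and ``H_p`` is a small
    cardiac map.  Behavior is ``loading * behavior-latent + noise`` with
    the two latents correlated at ``true_canonical_r``.
    """
    if n_participants < 4:
        raise InvalidArgumentError("need at least 4 participants")
    if n_roi < 2:
        raise InvalidArgumentError("need at least 2 ROIs")
    if n_frames <= 2 * (10 + true_lag_frames):
        raise InvalidArgumentError("n_frames too short for truncation plus lag")
    if not 0 <= missing_rate < 1:
        raise InvalidArgumentError("missing_rate must lie in [0, 1)")
    if true_lag_frames < 0:
        raise InvalidArgumentError("true_lag_frames must be non-negative")
    if not 0 <= true_canonical_r <= 1:
        raise InvalidArgumentError("true_canonical_r must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    frame_fs = 1.0 / tr_s

    pids, fam_table, mz_pairs = _make_families(n_participants, mz_frac, dz_frac, rng)

    # latents: brain latent z and behavior latent u, corr(z, u) = rho
    z = _family_latent(fam_table, family_variance, rng)
    u_noise = _family_latent(fam_table, family_variance, rng)
    rho = true_canonical_r
    u = rho * z + np.sqrt(1 - rho ** 2) * u_noise

    # spatial structure
    gl_base = rng.uniform(0.3, 1.0, size=n_roi)
    v = rng.standard_normal(n_roi)
    v /= np.linalg.norm(v)
    indep_base = rng.uniform(0.3, 1.0, size=n_roi)
    hr_map = hr_gain * rng.uniform(0.5, 1.0, size=n_roi)

    load = np.empty((n_participants, n_roi))
    resp_maps = np.empty((n_participants, n_roi))
    for p in range(n_participants):
        eta = rng.standard_normal(n_roi)
        load[p] = gl_base + mode_strength * z[p] * v + map_noise_sd * eta
        if coupled_maps:
            resp_maps[p] = resp_gain * load[p]
        else:
            eta2 = rng.standard_normal(n_roi)
            resp_maps[p] = resp_gain * (indep_base + map_noise_sd * eta2)

    # behavior battery
    lam = rng.uniform(0.3, 0.7, size=n_behaviors) * rng.choice([-1, 1], size=n_behaviors)
    conf = pd.DataFrame(rng.standard_normal((n_participants, 2)),
                        index=pids, columns=["conf1", "conf2"])
    behav = (np.outer(u, lam)
             + 0.2 * conf.to_numpy() @ rng.standard_normal((2, n_behaviors))
             + np.sqrt(np.maximum(1 - lam ** 2, 0.05)) * rng.standard_normal(
                 (n_participants, n_behaviors)))
    if missing_rate > 0:
        mask = rng.random(behav.shape) < missing_rate
        behav = np.where(mask, np.nan, behav)
    behavior = pd.DataFrame(behav, index=pids,
                            columns=[f"measure_{j:03d}" for j in range(n_behaviors)])

    atlas = pd.DataFrame({
        "roi": [f"roi{i:04d}" for i in range(n_roi)],
        "network": [NETWORKS[i * len(NETWORKS) // n_roi] for i in range(n_roi)],
    })

    duration_s = n_frames * tr_s
    runs: dict[str, list[RunSeries]] = {}
    rvt_frames: dict[str, list[np.ndarray]] = {}
    hr_frames: dict[str, list[np.ndarray]] = {}
    resp_traces: dict[str, list[PhysioTrace]] | None = {} if store_physio else None
    card_traces: dict[str, list[PhysioTrace]] | None = {} if store_physio else None

    for p, pid in enumerate(pids):
        runs[pid] = []
        rvt_frames[pid] = []
        hr_frames[pid] = []
        if store_physio:
            resp_traces[pid] = []
            card_traces[pid] = []
        for _ in range(n_runs):
            g = _global_component(n_frames, frame_fs, rng)
            # infra-slow modulator, pre-extended so lagged samples exist
            m_ext = _band_limited_noise(n_frames + true_lag_frames, frame_fs,
                                        (0.01, 0.05), rng)
            rvt_obs = m_ext[true_lag_frames:]
            rvt_used = m_ext[:n_frames]          # rvt(t - lag) on the frame grid
            h_ext = _band_limited_noise(n_frames + hr_lag_frames, frame_fs,
                                        (0.02, 0.1), rng)
            hr_obs = h_ext[hr_lag_frames:]
            hr_used = h_ext[:n_frames]
            bold = (np.outer(load[p], g)
                    - np.outer(resp_maps[p], rvt_used)
                    + np.outer(hr_map, hr_used)
                    + bold_noise_sd * rng.standard_normal((n_roi, n_frames)))
            runs[pid].append(RunSeries(bold, tr_s, roi_ids=list(atlas["roi"])))
            rvt_frames[pid].append(rvt_obs.copy())
            mean_hr, hr_sd = 70.0, 4.0
            hr_frames[pid].append(mean_hr + hr_sd * hr_obs)
            if store_physio:
                t_fs = np.arange(round(duration_s * physio_fs)) / physio_fs
                frame_centers = (np.arange(n_frames) + 0.5) * tr_s
                m_fs = np.interp(t_fs, frame_centers, rvt_obs)
                env = np.clip(1.0 + 0.4 * m_fs, 0.05, None)
                phase = rng.uniform(0, 2 * np.pi)
                trace = env * np.sin(2 * np.pi * carrier_hz * t_fs + phase)
                trace = trace + 0.05 * rng.standard_normal(t_fs.size)
                resp_traces[pid].append(PhysioTrace(trace, physio_fs, "respiratory"))
                hr_fs = np.interp(t_fs, frame_centers, hr_frames[pid][-1])
                beats, tcur = [], 30.0 / mean_hr
                while tcur < duration_s:
                    beats.append(tcur)
                    hr_here = np.interp(tcur, t_fs, hr_fs)
                    tcur += 60.0 / max(hr_here, 20.0)
                card = _pulse_waveform(np.asarray(beats), duration_s, physio_fs)
                card = card + 0.02 * rng.standard_normal(card.size)
                card_traces[pid].append(PhysioTrace(card, physio_fs, "cardiac",
                                                    meta={"beat_times_s": np.asarray(beats)}))

    truth = GroundTruth(global_loadings=gl_base,
                        resp_coupling_map=resp_gain * gl_base if coupled_maps
                        else resp_gain * indep_base,
                        true_lag_frames=true_lag_frames, true_flip=True,
                        true_canonical_r=true_canonical_r,
                        behavior_loadings=lam, mode_topography=v,
                        latent_brain=z, latent_behavior=u,
                        family_blocks=dict(zip(fam_table["participant"],
                                               fam_table["family_id"])),
                        mz_pairs=mz_pairs, hr_lag_frames=hr_lag_frames,
                        participant_loadings=load,
                        participant_resp_maps=resp_maps)
    return SyntheticCohort(participants=pids, runs=runs, rvt_frames=rvt_frames,
                           hr_frames=hr_frames, resp_traces=resp_traces,
                           cardiac_traces=card_traces, behavior=behavior,
                           confounds=conf, family=fam_table, atlas=atlas,
                           tr_s=tr_s, physio_fs=physio_fs, truth=truth)
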