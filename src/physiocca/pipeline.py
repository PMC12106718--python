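"""End-to-end analysis driver: cohort -> topographies -> ICC -> CCA -> CV.

These helpers chain the per-module operations in the order the analysis
prescribes: truncate 10 frames from each end of every frame series,
estimate the group lag of each physiological measure against the global
signal, build per-participant Fisher-z topographies (averaged across
runs), and hand matrices to the consistency and inference stages.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bh
from . import cca as cc
from . import cv as cvmod
from . import icc as iccmod
from .errors import InvalidArgumentError
from .families import FamilyStructure
from .physio import (FrameSeries, clean_cardiac_trace, clean_respiratory_trace,
                     compute_heart_rate, derive_respiration_measure,
                     resample_to_frames)
from .synthetic import SyntheticCohort, generate_cohort
from .topography import (LagEstimate, Topography, compute_coupling_map,
                         compute_global_signal, estimate_group_lag, truncate)


def global_signals(cohort: SyntheticCohort, n_edge: int = 10
                   ) -> dict[str, list[FrameSeries]]:
    """Truncated global signal per participant per run."""
    return {pid: [truncate(compute_global_signal(r), n_edge) for r in cohort.runs[pid]]
            for pid in cohort.participants}


def physio_frame_series(cohort: SyntheticCohort, measure: str,
                        from_traces: bool = False, n_edge: int = 10
                        ) -> dict[str, list[FrameSeries]]:
    """Truncated frame-level physiological series per participant per run.

    ``from_traces=True`` runs the full preprocessing path (clean, derive,
    block-average to frames); otherwise the cohort's stored frame-level
    series are used directly.
    """
    measure = measure.upper()
    out: dict[str, list[FrameSeries]] = {}
    n_frames = cohort.n_frames
    for pid in cohort.participants:
        series = []
        for i, run in enumerate(cohort.runs[pid]):
            if from_traces:
                if measure in ("RVT", "ENV", "RV"):
                    raw = cohort.resp_traces[pid][i]
                    cleaned = clean_respiratory_trace(raw)
                    s = derive_respiration_measure(cleaned, measure)
                else:  # HR
                    raw = cohort.cardiac_traces[pid][i]
                    s = compute_heart_rate(clean_cardiac_trace(raw))
                fr = resample_to_frames(s, cohort.physio_fs, n_frames,
                                        cohort.tr_s, measure=measure)
            else:
                stored = (cohort.rvt_frames if measure in ("RVT", "ENV", "RV")
                          else cohort.hr_frames)
                fr = FrameSeries(stored[pid][i], cohort.tr_s, measure=measure)
            series.append(truncate(fr, n_edge))
        out[pid] = series
    return out


def estimate_cohort_lag(cohort: SyntheticCohort, measure: str = "RVT",
                        from_traces: bool = False, max_lag_s: float = 72.0,
                        n_edge: int = 10) -> LagEstimate:
    """Group lag of a physiological measure against the global signal."""
    gs = global_signals(cohort, n_edge)
    ph = physio_frame_series(cohort, measure, from_traces, n_edge)
    return estimate_group_lag([gs[p] for p in cohort.participants],
                              [ph[p] for p in cohort.participants],
                              max_lag_s=max_lag_s)


def gscorr_matrix(cohort: SyntheticCohort, n_edge: int = 10) -> pd.DataFrame:
    """Participants x ROI GSCORR matrix (Fisher z, run-averaged)."""
    rows = {}
    for pid in cohort.participants:
        runs = [truncate(r, n_edge) for r in cohort.runs[pid]]
        gs = [compute_global_signal(r) for r in runs]
        topo = compute_coupling_map(runs, gs, lag=0, measure="GSCORR")
        rows[pid] = topo.values
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(cohort.atlas["roi"]))


def physio_corr_matrix(cohort: SyntheticCohort, measure: str,
                       lag: LagEstimate, from_traces: bool = False,
                       n_edge: int = 10) -> pd.DataFrame:
    """Participants x ROI coupling matrix for RVT/HR/ENV/RV at a given lag."""
    ph = physio_frame_series(cohort, measure, from_traces, n_edge)
    rows = {}
    for pid in cohort.participants:
        runs = [truncate(r, n_edge) for r in cohort.runs[pid]]
        topo = compute_coupling_map(runs, ph[pid], lag=lag,
                                    measure=f"{measure.upper()}CORR")
        rows[pid] = topo.values
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(cohort.atlas["roi"]))


def gscorr_matrix_residual(cohort: SyntheticCohort, lag: LagEstimate,
                           measure: str = "RVT", n_edge: int = 10) -> pd.DataFrame:
    """GSCORR recomputed after regressing the flipped, lagged physiological
    series out of the global signal (time-domain control analysis)."""
    ph = physio_frame_series(cohort, measure, False, n_edge)
    rows = {}
    for pid in cohort.participants:
        runs = [truncate(r, n_edge) for r in cohort.runs[pid]]
        gs_res, bolds = [], []
        for run, p in zip(runs, ph[pid]):
            gs = compute_global_signal(run)
            resid, sl = cc.regress_out_series(gs, [p], lags=[lag.lag_frames],
                                              flips=[lag.flip])
            gs_res.append(resid)
            bolds.append(type(run)(run.bold[:, sl], run.tr_s, run.roi_ids))
        topo = compute_coupling_map(bolds, gs_res, lag=0, measure="GSCORR")
        rows[pid] = topo.values
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(cohort.atlas["roi"]))


@dataclass
class PipelineConfig:
    """Seeds, sizes and analysis knobs for the end-to-end runner."""

    seed: int = 0
    n_participants: int = 120
    n_roi: int = 100
    n_frames: int = 800
    tr_s: float = 0.72
    n_runs: int = 1
    truncation: int = 10
    max_lag_s: float = 72.0
    k_components: int = 20
    n_perm_modes: int = 1000
    n_perm_backproject: int = 2000
    alpha_backproject: float = 0.001
    cv_folds: int = 10
    n_perm_cv: int = 200
    missing_rate: float = 0.0093
    true_canonical_r: float = 0.7
    icc_variant: str = "paper-literal"
    out_dir: str = "results"

    def to_yaml(self, path) -> None:
        import yaml
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _checksum(obj) -> str:
    if isinstance(obj, pd.DataFrame):
        payload = obj.to_csv().encode()
    elif isinstance(obj, np.ndarray):
        payload = obj.tobytes()
    else:
        payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute all stages on a synthetic cohort and write a results manifest.

    Stages: simulate, physio, topo, icc, prep, cca, cv.  Rerunning with the
    same config reproduces every stochastic output (checksums match).
    """
    from .io import write_matrix_tsv

    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": [], "config": asdict(config)}

    def stage(name, payload):
        manifest["stages"].append({"name": name, "checksum": _checksum(payload)})

    cohort = generate_cohort(config.n_participants, config.n_roi, config.n_frames,
                             config.tr_s, config.n_runs,
                             true_canonical_r=config.true_canonical_r,
                             missing_rate=config.missing_rate, seed=config.seed)
    stage("simulate", cohort.behavior)

    lag_rvt = estimate_cohort_lag(cohort, "RVT", max_lag_s=config.max_lag_s,
                                  n_edge=config.truncation)
    lag_hr = estimate_cohort_lag(cohort, "HR", max_lag_s=config.max_lag_s,
                                 n_edge=config.truncation)
    stage("physio", {"rvt_lag": lag_rvt.lag_frames, "rvt_flip": lag_rvt.flip,
                     "hr_lag": lag_hr.lag_frames, "hr_flip": lag_hr.flip})

    gscorr = gscorr_matrix(cohort, config.truncation)
    rvtcorr = physio_corr_matrix(cohort, "RVT", lag_rvt, n_edge=config.truncation)
    hrcorr = physio_corr_matrix(cohort, "HR", lag_hr, n_edge=config.truncation)
    write_matrix_tsv(out / "gscorr.tsv", gscorr)
    write_matrix_tsv(out / "rvtcorr.tsv", rvtcorr)
    write_matrix_tsv(out / "hrcorr.tsv", hrcorr)
    stage("topo", gscorr)

    icc_rvt = iccmod.icc_two_way(gscorr.to_numpy(), rvtcorr.to_numpy(),
                                 config.icc_variant)
    icc_hr = iccmod.icc_two_way(gscorr.to_numpy(), hrcorr.to_numpy(),
                                config.icc_variant)
    net = iccmod.network_icc_summary(icc_rvt, cohort.atlas)
    stage("icc", icc_rvt.icc)

    behav, report = bh.filter_behavior_variables(cohort.behavior)
    conf = cohort.confounds
    bc = bh.behavioral_components(behav, k=min(config.k_components, len(behav) - 1),
                                  confounds=conf)
    tc = bh.topography_components(gscorr, k=min(config.k_components,
                                                min(gscorr.shape) - 1),
                                  confounds=conf)
    stage("prep", bc.scores)

    family = FamilyStructure(cohort.family)
    modes = cc.fit_cca(tc, bc)
    pvals = cc.permutation_test_modes(tc, bc, family,
                                      n_perm=config.n_perm_modes,
                                      seed=config.seed + 1,
                                      roster=cohort.participants)
    bp_behav = cc.backproject_weights(modes[0], behav, side="behavior",
                                      n_perm=config.n_perm_backproject,
                                      alpha=config.alpha_backproject,
                                      family=family, seed=config.seed + 2,
                                      roster=cohort.participants)
    bp_brain = cc.backproject_weights(modes[0], gscorr, side="brain",
                                      n_perm=config.n_perm_backproject,
                                      alpha=config.alpha_backproject,
                                      family=family, seed=config.seed + 3,
                                      roster=cohort.participants)
    stage("cca", np.array([m.canonical_r for m in modes]))

    plan = cvmod.family_aware_folds(cohort.participants, family,
                                    k=config.cv_folds, seed=config.seed + 4)
    cv_report = cvmod.cross_validate_cca(gscorr, behav, plan,
                                         k_components=min(config.k_components,
                                                          min(gscorr.shape) - 1),
                                         confounds=conf)
    cv_report = cvmod.cv_permutation_significance(cv_report, family,
                                                  cohort.participants,
                                                  n_perm=config.n_perm_cv,
                                                  seed=config.seed + 5)
    stage("cv", cv_report.fold_r)

    results = {
        "rvt_lag_frames": lag_rvt.lag_frames,
        "rvt_lag_s": lag_rvt.lag_s,
        "rvt_flip": lag_rvt.flip,
        "hr_lag_frames": lag_hr.lag_frames,
        "icc_gscorr_rvtcorr_mean": float(np.nanmean(icc_rvt.icc)),
        "icc_gscorr_hrcorr_mean": float(np.nanmean(icc_hr.icc)),
        "icc_network_kruskal_p": net.p_value,
        "first_canonical_r": modes[0].canonical_r,
        "first_mode_p": float(pvals[0]),
        "n_significant_behavior_weights": int(bp_behav.significant.sum()),
        "n_significant_brain_weights": int(bp_brain.significant.sum()),
        "cv_mean_oos_r": cv_report.mean_r,
        "cv_max_oos_r": float(cv_report.fold_r.max()),
        "cv_mean_level_p": cv_report.mean_level_p,
        "weight_stability_brain": cv_report.weight_stability_brain,
        "weight_stability_behavior": cv_report.weight_stability_behavior,
    }
    manifest["results"] = results
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "results.json").write_text(json.dumps(results, indent=2, default=str))
    return manifest
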