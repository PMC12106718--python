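"""Canonical correlation analysis with family-aware permutation inference.

The decomposition follows the classical QR+SVD construction (the one
behind MATLAB's ``canoncorr``): center both blocks, take thin QR
decompositions, and SVD the cross-product of the orthonormal factors.
Canonical correlations are the singular values; weights are recovered by
back-substitution through the triangular factors.

Inference respects the cohort's family structure: permutations shuffle
whole families among families of equal size (see
:mod:`physiocca.families`).  Mode significance compares each observed
canonical correlation against the null distribution of *first* (maximal)
canonical correlations, with an add-one correction.  Back-projection onto
the original variables uses a max-statistic permutation null for
family-wise error control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidArgumentError
from .families import BlockPermuter, FamilyStructure
from .physio import FrameSeries


@dataclass
class CCAMode:
    canonical_r: float
    brain_weights: np.ndarray
    behavior_weights: np.ndarray
    brain_scores: np.ndarray
    behavior_scores: np.ndarray
    perm_p: float | None = None
    sign_state: str = "raw"


@dataclass
class BackProjection:
    """Full-length weights: correlation of mode scores with original variables."""

    full_weights: np.ndarray
    p_fwer: np.ndarray
    significant: np.ndarray
    alpha: float
    variable_names: list[str]
    excluded: list[str]


@dataclass
class ModeSimilarity:
    r_behavior_scores: float
    r_topography_scores: float
    r_behavior_weights: float
    r_topography_weights: float


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean(axis=0, keepdims=True)


def _qr_block(x: np.ndarray, label: str):
    xc = _center(np.asarray(x, dtype=float))
    q, r = np.linalg.qr(xc)
    diag = np.abs(np.diag(r))
    if diag.min() <= diag.max() * 1e-10 or diag.max() == 0:
        raise InvalidArgumentError(
            f"{label} block is rank deficient; reduce the number of components")
    return xc, q, r


def _scores_of(x) -> np.ndarray:
    from .behavior import ComponentScores
    if isinstance(x, ComponentScores):
        return x.scores
    return np.atleast_2d(np.asarray(x, dtype=float))


def fit_cca(x, y) -> list[CCAMode]:
    """Full canonical decomposition of two component blocks.

    Returns min(kx, ky) modes ordered by decreasing canonical correlation;
    each mode's score pair correlates exactly at its canonical r.
    """
    X = _scores_of(x)
    Y = _scores_of(y)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise InvalidArgumentError("blocks must share participants")
    n = X.shape[0]
    xc, qx, rx = _qr_block(X, "brain")
    yc, qy, ry = _qr_block(Y, "behavior")
    u, s, vt = np.linalg.svd(qx.T @ qy)
    d = min(X.shape[1], Y.shape[1])
    u, s, vt = u[:, :d], s[:d], vt[:d]
    a = np.linalg.solve(rx, u) * np.sqrt(n - 1)
    b = np.linalg.solve(ry, vt.T) * np.sqrt(n - 1)
    us = xc @ a
    vs = yc @ b
    modes = []
    for m in range(d):
        modes.append(CCAMode(canonical_r=float(min(s[m], 1.0)),
                             brain_weights=a[:, m], behavior_weights=b[:, m],
                             brain_scores=us[:, m], behavior_scores=vs[:, m]))
    return modes


def first_canonical_correlations(qx: np.ndarray, qy_perms: np.ndarray) -> np.ndarray:
    """Largest singular value of qx' P qy for a batch of permuted qy factors.

    ``qy_perms`` has shape (n_perm, n, k).  Row permutations commute with
    the QR factorization (P(QR) = (PQ)R), so permuting the orthonormal
    factor's rows is equivalent to permuting the raw block.
    """
    cross = np.einsum("ji,pjk->pik", qx, qy_perms)
    return np.linalg.svd(cross, compute_uv=False)[:, 0]


def permutation_test_modes(x, y, family: FamilyStructure | np.ndarray | None,
                           n_perm: int = 5000, seed: int | None = None,
                           roster=None) -> np.ndarray:
    """Add-one permutation p-value per mode against the null of first-mode maxima.

    One block's participant order is shuffled under family exchangeability
    blocks; each permutation contributes its first canonical correlation
    to the null.  ``family`` may be a :class:`FamilyStructure` (with
    ``roster`` giving participant order), a per-participant family-id
    array, or None for unrestricted permutation.
    """
    X = _scores_of(x)
    Y = _scores_of(y)
    n = X.shape[0]
    modes = fit_cca(X, Y)
    observed = np.array([m.canonical_r for m in modes])
    rng = np.random.default_rng(seed)
    if family is None:
        fam_ids = np.arange(n)
    elif isinstance(family, FamilyStructure):
        if roster is None:
            raise InvalidArgumentError("roster required with a FamilyStructure")
        fam_ids = family.family_ids_for(roster)
    else:
        fam_ids = np.asarray(family)
    permuter = BlockPermuter(fam_ids)
    _, qx, _ = _qr_block(X, "brain")
    _, qy, _ = _qr_block(Y, "behavior")
    perms = permuter.permutations(n_perm, rng)
    null_max = first_canonical_correlations(qx, qy[perms])
    counts = (null_max[None, :] >= observed[:, None]).sum(axis=1)
    return (1.0 + counts) / (1.0 + n_perm)


def _pearson_cols(score: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Correlation of one score vector with each column, pairwise-complete."""
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        col = X[:, j]
        ok = np.isfinite(col)
        if ok.sum() < 3 or col[ok].std() == 0:
            out[j] = np.nan
            continue
        out[j] = np.corrcoef(score[ok], col[ok])[0, 1]
    return out


def backproject_weights(mode: CCAMode, originals, side: str = "behavior",
                        n_perm: int = 10000, alpha: float = 0.001,
                        family=None, seed: int | None = None,
                        roster=None) -> BackProjection:
    """Correlate a mode's scores with the original variables, with a
    max-|r| permutation null for FWER control.

    ``side`` picks which score vector to use ("behavior" or "brain").
    Constant variables get NaN weights and are excluded from inference.
    For the null, sparsely missing cells are zero-imputed after
    standardization (the observed weights use pairwise-complete data).
    """
    df = pd.DataFrame(originals)
    X = df.to_numpy(dtype=float)
    score = mode.behavior_scores if side == "behavior" else mode.brain_scores
    if X.shape[0] != score.size:
        raise InvalidArgumentError("originals must align with participants")
    weights = _pearson_cols(score, X)
    excluded = [str(c) for c, w in zip(df.columns, weights) if not np.isfinite(w)]
    ok_cols = np.isfinite(weights)
    n = score.size
    rng = np.random.default_rng(seed)
    if family is None:
        fam_ids = np.arange(n)
    elif isinstance(family, FamilyStructure):
        fam_ids = family.family_ids_for(roster if roster is not None else df.index)
    else:
        fam_ids = np.asarray(family)
    permuter = BlockPermuter(fam_ids)
    # standardized, zero-imputed design for the fast permutation null
    mean = np.nanmean(X[:, ok_cols], axis=0)
    sd = np.nanstd(X[:, ok_cols], axis=0, ddof=1)
    Z = (X[:, ok_cols] - mean) / sd
    Z = np.where(np.isfinite(Z), Z, 0.0)
    zs = (score - score.mean()) / score.std(ddof=1)
    perms = permuter.permutations(n_perm, rng)
    P = zs[perms]                       # (n_perm, n)
    null_r = (P @ Z) / (n - 1)          # (n_perm, p_ok)
    null_max = np.abs(null_r).max(axis=1)
    thresh = np.quantile(null_max, 1.0 - alpha)
    p_fwer = np.full(weights.size, np.nan)
    counts = (null_max[None, :] >= np.abs(weights[ok_cols])[:, None]).sum(axis=1)
    p_fwer[ok_cols] = (1.0 + counts) / (1.0 + n_perm)
    significant = np.zeros(weights.size, dtype=bool)
    significant[ok_cols] = np.abs(weights[ok_cols]) > thresh
    return BackProjection(full_weights=weights, p_fwer=p_fwer,
                          significant=significant, alpha=alpha,
                          variable_names=[str(c) for c in df.columns],
                          excluded=excluded)


def align_signs(mode: CCAMode, backproj: BackProjection, anchor: str,
                desired_sign: int = -1) -> tuple[CCAMode, BackProjection]:
    """Fix the arbitrary sign of a mode using an anchor variable.

    If the anchor's back-projected weight does not carry ``desired_sign``,
    all weights and scores of the mode (and the back-projection) are
    negated jointly; the canonical correlation is unchanged.  An absent
    anchor is a no-op with a warning.
    """
    if anchor not in backproj.variable_names:
        warnings.warn(f"anchor {anchor!r} not found; signs left as-is", stacklevel=2)
        return mode, backproj
    idx = backproj.variable_names.index(anchor)
    w = backproj.full_weights[idx]
    if not np.isfinite(w) or np.sign(w) == np.sign(desired_sign) or w == 0:
        return (replace(mode, sign_state="aligned"),
                replace(backproj))
    flipped = replace(mode,
                      brain_weights=-mode.brain_weights,
                      behavior_weights=-mode.behavior_weights,
                      brain_scores=-mode.brain_scores,
                      behavior_scores=-mode.behavior_scores,
                      sign_state="aligned")
    flipped_bp = replace(backproj, full_weights=-backproj.full_weights)
    return flipped, flipped_bp


def _corr(a, b) -> float:
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    return float(np.corrcoef(a[ok], b[ok])[0, 1])


def compare_modes(mode_a: CCAMode, bp_behavior_a: BackProjection,
                  bp_brain_a: BackProjection,
                  mode_b: CCAMode, bp_behavior_b: BackProjection,
                  bp_brain_b: BackProjection) -> ModeSimilarity:
    """Four-correlation similarity between two (mode, back-projection) pairs:
    behavioral scores, topographic scores, behavioral weights, topographic
    weights."""
    if mode_a.behavior_scores.size != mode_b.behavior_scores.size:
        raise InvalidArgumentError("modes computed on different participants")
    if (len(bp_behavior_a.variable_names) != len(bp_behavior_b.variable_names)
            or len(bp_brain_a.variable_names) != len(bp_brain_b.variable_names)):
        raise InvalidArgumentError("back-projections live in different spaces")
    return ModeSimilarity(
        r_behavior_scores=_corr(mode_a.behavior_scores, mode_b.behavior_scores),
        r_topography_scores=_corr(mode_a.brain_scores, mode_b.brain_scores),
        r_behavior_weights=_corr(bp_behavior_a.full_weights, bp_behavior_b.full_weights),
        r_topography_weights=_corr(bp_brain_a.full_weights, bp_brain_b.full_weights),
    )


def regress_out_map(target: np.ndarray, regressor: np.ndarray) -> np.ndarray:
    """Per participant (row), OLS residual of the target ROI-vector on
    [1, regressor ROI-vector]."""
    T = np.atleast_2d(np.asarray(target, float))
    R = np.atleast_2d(np.asarray(regressor, float))
    if T.shape != R.shape:
        raise InvalidArgumentError("target and regressor maps must share shape")
    out = np.empty_like(T)
    for i in range(T.shape[0]):
        r = R[i]
        if r.std() == 0:
            raise DegenerateInputError(f"constant regressor map for row {i}")
        D = np.column_stack([np.ones(r.size), r])
        beta, *_ = np.linalg.lstsq(D, T[i], rcond=None)
        out[i] = T[i] - D @ beta
    return out


def regress_out_series(target, regressors, lags=None, flips=None
                       ) -> tuple[FrameSeries, slice]:
    """Time-domain OLS residual of a frame series on lagged/flipped regressors.

    Each regressor may carry a lag L (its sample at t - L is paired with
    the target at t) and a flip.  The residual is computed on the frames
    where all regressors are defined; the slice applied to the target is
    returned alongside so callers can align other series.
    """
    tv = target.values if isinstance(target, FrameSeries) else np.asarray(target, float)
    tr = target.tr_s if isinstance(target, FrameSeries) else 1.0
    regs = [r.values if isinstance(r, FrameSeries) else np.asarray(r, float)
            for r in regressors]
    if not regs:
        raise InvalidArgumentError("need at least one regressor")
    lags = list(lags) if lags is not None else [0] * len(regs)
    flips = list(flips) if flips is not None else [False] * len(regs)
    n = tv.size
    lo = max([0] + [l for l in lags if l > 0])
    hi = n + min([0] + [l for l in lags if l < 0])
    if hi - lo < 3:
        raise InvalidArgumentError("overlap shorter than 3 frames")
    cols = []
    for r, lag, flip in zip(regs, lags, flips):
        seg = r[lo - lag: hi - lag]
        cols.append(-seg if flip else seg)
    D = np.column_stack([np.ones(hi - lo)] + cols)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise InvalidArgumentError("collinear regressors")
    y = tv[lo:hi]
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    resid = y - D @ beta
    return FrameSeries(resid, tr_s=tr, measure="residual"), slice(lo, hi)
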