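"""Behavioral-variable screening, deconfounding, and rank-k component scores.

Behavioral batteries carry unusable columns (gross outliers, mostly
missing, near-constant) and nuisance covariates (body size, blood
pressure, scanner software ...).  This module applies the screening
rules, residualizes both data blocks against the confounds, completes
the participants x participants covariance of the (sparsely missing)
behavior block via a nearest symmetric-positive-semidefinite projection,
and produces the component scores fed to the CCA: eigenvector scores for
behavior, SVD scores for the complete topography block.

Because the behavioral columns are standardized to mean zero before the
participant-space covariance is formed, that covariance is computed about
zero from pairwise-complete observations; with no missing data it then
coincides exactly with the Gram matrix whose eigenvectors are the usual
PCA scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError


@dataclass
class ExclusionReport:
    outlier_rule: list[str] = field(default_factory=list)
    missing_rule: list[str] = field(default_factory=list)
    identical_rule: list[str] = field(default_factory=list)
    confounds: list[str] = field(default_factory=list)
    listed_drops: list[str] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)

    @property
    def dropped(self) -> list[str]:
        return (self.outlier_rule + self.missing_rule + self.identical_rule
                + self.confounds + self.listed_drops)


def filter_behavior_variables(table: pd.DataFrame,
                              sd_above_median: float = 100.0,
                              min_valid_fraction: float = 0.5,
                              max_identical_fraction: float = 0.95,
                              confounds: list[str] = (),
                              drop: list[str] = (),
                              symmetric_outlier_rule: bool = False
                              ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop quantitatively poor measures, confounds and listed variables.

    A measure is dropped when any value lies more than ``sd_above_median``
    standard deviations above its median (``symmetric_outlier_rule``
    extends this to both sides), when fewer than ``min_valid_fraction`` of
    its entries are valid, or when its modal value accounts for more than
    ``max_identical_fraction`` of the non-missing entries.  Each variable
    is reported once, under the first rule that fires.
    """
    report = ExclusionReport()
    keep = []
    confounds = list(confounds)
    drop = list(drop)
    for name in table.columns:
        col = table[name]
        if name in confounds:
            report.confounds.append(name)
            continue
        if name in drop:
            report.listed_drops.append(name)
            continue
        valid = col.dropna()
        if len(valid) / len(col) < min_valid_fraction:
            report.missing_rule.append(name)
            continue
        med = valid.median()
        # the extreme point is excluded from the SD estimate: with it
        # included the deviation is bounded by sqrt(n) and a 100-SD rule
        # could never fire at cohort scale
        vmax = valid.max()
        sd_rest = valid.drop(valid.idxmax()).std()
        hit = sd_rest > 0 and (vmax - med) / sd_rest > sd_above_median
        if symmetric_outlier_rule and not hit:
            vmin = valid.min()
            sd_rest = valid.drop(valid.idxmin()).std()
            hit = sd_rest > 0 and (med - vmin) / sd_rest > sd_above_median
        if hit:
            report.outlier_rule.append(name)
            continue
        if len(valid) and valid.value_counts().iloc[0] / len(valid) > max_identical_fraction:
            report.identical_rule.append(name)
            continue
        keep.append(name)
    if not keep:
        raise InvalidArgumentError("no behavioral measure survives screening")
    report.kept = keep
    return table[keep], report


def _design(confounds: np.ndarray) -> np.ndarray:
    n = confounds.shape[0]
    return np.column_stack([np.ones(n), confounds])


def _check_rank(design: np.ndarray, names) -> None:
    r = np.linalg.matrix_rank(design)
    if r < design.shape[1]:
        # name the offending columns via QR diagonal
        _, rr = np.linalg.qr(design)
        diag = np.abs(np.diag(rr))
        tol = diag.max() * 1e-10
        bad = [str(names[i - 1]) if i > 0 else "intercept"
               for i in np.where(diag < tol)[0]]
        raise InvalidArgumentError(f"confound matrix is rank deficient: {bad}")


def deconfound(matrix, confounds) -> pd.DataFrame:
    """z-score each variable then residualize against [1, confounds].

    Fitting uses the non-missing rows of each variable; missing cells stay
    missing.  Confounds must be complete.
    """
    X = pd.DataFrame(matrix).copy()
    C = np.atleast_2d(np.asarray(confounds, dtype=float))
    if C.shape[0] != len(X):
        C = C.T
    if C.shape[0] != len(X):
        raise InvalidArgumentError("confounds must have one row per participant")
    if np.isnan(C).any():
        raise InvalidArgumentError("confounds must be complete")
    names = list(pd.DataFrame(confounds).columns)
    D = _design(C)
    _check_rank(D, names)
    out = X.astype(float)
    for name in out.columns:
        col = out[name].to_numpy()
        ok = np.isfinite(col)
        v = col[ok]
        sd = v.std(ddof=1)
        if sd > 0:
            v = (v - v.mean()) / sd
        else:
            v = v - v.mean()
        beta, *_ = np.linalg.lstsq(D[ok], v, rcond=None)
        col = np.full_like(col, np.nan)
        col[ok] = v - D[ok] @ beta
        out[name] = col
    return out


def nearest_spd(a: np.ndarray, eps_scale: float = 1e-10) -> np.ndarray:
    """Project a square matrix onto the nearest symmetric PSD matrix.

    Symmetrize, eigendecompose, clip eigenvalues at
    ``eps_scale * max(eigenvalue, 0)``, reconstruct.  For symmetric input
    this is the fixed point of the alternating symmetric-polar projection.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InvalidArgumentError("nearest_spd expects a square matrix")
    sym = (a + a.T) / 2
    w, v = np.linalg.eigh(sym)
    floor = max(w.max(), 0.0) * eps_scale
    w = np.maximum(w, floor)
    out = (v * w) @ v.T
    return (out + out.T) / 2


def pairwise_complete_gram(X: np.ndarray) -> np.ndarray:
    """Participants x participants covariance about zero from
    pairwise-complete observations of (standardized) variables.

    Entry (i, j) averages ``x_i[m] * x_j[m]`` over the measures observed
    for both participants, with an n-1 style divisor.
    """
    X = np.asarray(X, dtype=float)
    W = np.isfinite(X).astype(float)
    X0 = np.where(np.isfinite(X), X, 0.0)
    counts = W @ W.T
    if (counts < 2).any():
        raise InvalidArgumentError("some participant pair shares <2 observed measures")
    return (X0 @ X0.T) / (counts - 1)


@dataclass
class ComponentScores:
    """Rank-k scores plus everything needed to project new participants."""

    scores: np.ndarray                 # (n, k)
    basis: np.ndarray                  # (p, k) variable-space projector
    explained_variance_fraction: float
    column_mean: np.ndarray
    column_sd: np.ndarray
    confound_beta: np.ndarray | None   # (c+1, p) fitted deconfounding model
    participants: list[str] | None = None

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def project(self, matrix, confounds=None) -> np.ndarray:
        """Project held-out participants through the trained standardization,
        deconfounding and component basis.  Missing cells are treated as the
        (zero) column mean after standardization."""
        X = np.asarray(pd.DataFrame(matrix), dtype=float)
        sd = np.where(self.column_sd > 0, self.column_sd, 1.0)
        X = (X - self.column_mean) / sd
        if self.confound_beta is not None:
            if confounds is None:
                raise InvalidArgumentError("model was fit with confounds")
            C = np.atleast_2d(np.asarray(confounds, dtype=float))
            if C.shape[0] != X.shape[0]:
                C = C.T
            X = X - _design(C) @ self.confound_beta
        X = np.where(np.isfinite(X), X, 0.0)
        return X @ self.basis


def _standardize_fit(X: np.ndarray):
    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd


def _deconfound_fit(X: np.ndarray, confounds):
    C = np.atleast_2d(np.asarray(confounds, dtype=float))
    if C.shape[0] != X.shape[0]:
        C = C.T
    D = _design(C)
    _check_rank(D, list(range(C.shape[1])))
    beta = np.empty((D.shape[1], X.shape[1]))
    out = np.full_like(X, np.nan)
    for j in range(X.shape[1]):
        ok = np.isfinite(X[:, j])
        b, *_ = np.linalg.lstsq(D[ok], X[ok, j], rcond=None)
        beta[:, j] = b
        out[ok, j] = X[ok, j] - D[ok] @ b
    return out, beta


def behavioral_components(table, k: int = 100, confounds=None) -> ComponentScores:
    """Eigenvector scores of the SPD-completed participant covariance.

    The (standardized, optionally deconfounded) behavior block may contain
    missing cells; the participant-space covariance is formed from
    pairwise-complete observations and projected to the nearest PSD
    matrix before the order-k eigendecomposition.  Scores are the top-k
    eigenvectors scaled by the square root of their eigenvalues.  The
    variable-space basis for out-of-sample projection is the least-squares
    regression of the (zero-imputed) training block onto the scores.
    """
    df = pd.DataFrame(table)
    # contiguity matters: BLAS kernels differ by layout, and training fits
    # must be bit-reproducible for identical training data
    X = np.ascontiguousarray(df.to_numpy(dtype=float))
    n, p = X.shape
    if k > n:
        raise InvalidArgumentError(f"k={k} exceeds n={n}")
    miss = np.mean(~np.isfinite(X))
    if miss >= 0.2:
        raise InvalidArgumentError(f"missing fraction {miss:.2f} too high")
    Xs, mean, sd = _standardize_fit(X)
    beta = None
    if confounds is not None:
        Xs, beta = _deconfound_fit(Xs, confounds)
    G = nearest_spd(pairwise_complete_gram(Xs))
    w, v = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, v = w[order][:k], v[:, order][:, :k]
    w = np.maximum(w, 0.0)
    scores = v * np.sqrt(w)
    total = np.maximum(np.linalg.eigh(G)[0], 0.0).sum()
    evf = float(w.sum() / total) if total > 0 else 0.0
    X0 = np.where(np.isfinite(Xs), Xs, 0.0)
    basis, *_ = np.linalg.lstsq(X0, scores, rcond=None)
    return ComponentScores(scores=scores, basis=basis,
                           explained_variance_fraction=evf,
                           column_mean=mean, column_sd=sd,
                           confound_beta=beta,
                           participants=[str(i) for i in df.index])


def topography_components(topos, k: int = 100, confounds=None) -> ComponentScores:
    """SVD scores of the (complete) topography block.

    Column-standardize, optionally deconfound, then SVD; scores are
    ``U S`` truncated to k, and the right singular vectors serve as the
    projection basis for held-out participants.
    """
    df = pd.DataFrame(topos)
    X = np.ascontiguousarray(df.to_numpy(dtype=float))
    n, p = X.shape
    if not np.isfinite(X).all():
        raise InvalidArgumentError("topography block must be complete")
    if k > min(n, p):
        raise InvalidArgumentError(f"k={k} exceeds min(n, p)={min(n, p)}")
    Xs, mean, sd = _standardize_fit(X)
    beta = None
    if confounds is not None:
        Xs, beta = _deconfound_fit(Xs, confounds)
    u, s, vt = np.linalg.svd(Xs, full_matrices=False)
    scores = (u * s)[:, :k]
    evf = float((s[:k] ** 2).sum() / (s ** 2).sum())
    return ComponentScores(scores=scores, basis=vt[:k].T,
                           explained_variance_fraction=evf,
                           column_mean=mean, column_sd=sd,
                           confound_beta=beta,
                           participants=[str(i) for i in df.index])
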