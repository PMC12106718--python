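"""Per-ROI intraclass correlation between two topography sets.

For every ROI, the two topographies form an n_participants x 2 table and
a two-way random-effects ANOVA decomposes its variance into row
(participant), column (measure) and error mean squares.  Three ICC
variants are exposed:

* ``paper-literal`` — sigma_r^2 / (sigma_r^2 + sigma_e^2) with
  sigma_r^2 = MSR - MSE and sigma_e^2 = MSE, i.e. (MSR - MSE) / MSR.
  This omits the divisor by the number of measures that the standard
  two-way forms carry; it is kept as the default because it is the
  printed definition this pipeline reproduces.
* ``icc_c1`` — Shrout-Fleiss ICC(C,1) = (MSR - MSE) / (MSR + (k-1) MSE).
* ``icc_a1`` — ICC(A,1), which additionally charges the column variance.

The reported row-variance component is floored at zero, but the ICC value
itself is left on its algebraic scale (it can be negative for discordant
columns), so that the null expectation is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError
from .topography import fisher_z

_VARIANTS = ("paper-literal", "icc_c1", "icc_a1")


@dataclass
class ICCMap:
    icc: np.ndarray            # per ROI
    variance_rows: np.ndarray  # sigma_r^2 per ROI (floored at 0)
    variance_error: np.ndarray
    formula_variant: str


@dataclass
class NetworkSummary:
    per_network: dict[str, np.ndarray]  # Fisher-z ICC values per network
    kruskal_h: float
    p_value: float
    excluded: list[str]


def _mean_squares(a: np.ndarray, b: np.ndarray):
    """Vectorized two-way ANOVA mean squares for n x 2 tables per column pair.

    ``a``/``b`` are (n_participants, n_roi); returns MSR, MSC, MSE arrays
    of length n_roi.
    """
    n = a.shape[0]
    k = 2
    grand = (a + b) / 2  # row means, shape (n, roi)
    gm = grand.mean(axis=0)
    ss_total = ((a - gm) ** 2 + (b - gm) ** 2).sum(axis=0)
    ss_rows = k * ((grand - gm) ** 2).sum(axis=0)
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    ss_cols = n * ((ca - gm) ** 2 + (cb - gm) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_two_way(a: np.ndarray, b: np.ndarray,
                variant: Literal["paper-literal", "icc_c1", "icc_a1"] = "paper-literal"
                ) -> ICCMap:
    """Two-way random-effects ICC per ROI across participants.

    ``a`` and ``b`` are (n_participants, n_roi) matrices of the two
    measures for the same participants.  ROIs with zero total variance
    yield NaN.
    """
    if variant not in _VARIANTS:
        raise InvalidArgumentError(f"variant must be one of {_VARIANTS}")
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise InvalidArgumentError("topography sets must have matching shape")
    n, _ = a.shape
    if n < 3:
        raise InvalidArgumentError("need at least 3 participants")
    msr, msc, mse = _mean_squares(a, b)
    k = 2
    with np.errstate(invalid="ignore", divide="ignore"):
        if variant == "paper-literal":
            icc = (msr - mse) / ((msr - mse) + mse)
        elif variant == "icc_c1":
            icc = (msr - mse) / (msr + (k - 1) * mse)
        else:  # icc_a1
            icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    total = msr + msc + mse
    icc = np.where(total > 0, icc, np.nan)
    return ICCMap(icc=icc,
                  variance_rows=np.maximum(msr - mse, 0.0),
                  variance_error=mse,
                  formula_variant=variant)


def icc_multi_session(pairs: list[tuple[np.ndarray, np.ndarray]],
                      variant: str = "paper-literal") -> ICCMap:
    """Average per-ROI ICC across sessions (one (a, b) pair per session)."""
    maps = [icc_two_way(a, b, variant) for a, b in pairs]
    icc = np.nanmean(np.stack([m.icc for m in maps]), axis=0)
    return ICCMap(icc=icc,
                  variance_rows=np.nanmean(np.stack([m.variance_rows for m in maps]), axis=0),
                  variance_error=np.nanmean(np.stack([m.variance_error for m in maps]), axis=0),
                  formula_variant=variant)


def network_icc_summary(icc_map: ICCMap, atlas: pd.DataFrame,
                        min_rois: int = 2) -> NetworkSummary:
    """Kruskal-Wallis comparison of Fisher-z ICC across networks.

    ``atlas`` maps ROI order to a ``network`` column (one row per ROI, in
    ROI order).  Networks with fewer than ``min_rois`` ROIs are excluded.
    """
    if "network" not in atlas.columns:
        raise InvalidArgumentError("atlas needs a 'network' column")
    networks = atlas["network"].to_numpy()
    if networks.size != icc_map.icc.size:
        raise InvalidArgumentError("atlas does not cover all ROIs")
    z = fisher_z(np.clip(icc_map.icc, -1.0, 1.0))
    groups: dict[str, np.ndarray] = {}
    excluded = []
    for name in pd.unique(networks):
        vals = z[networks == name]
        vals = vals[np.isfinite(vals)]
        if vals.size < min_rois:
            excluded.append(str(name))
        else:
            groups[str(name)] = vals
    if len(groups) < 2:
        raise InvalidArgumentError("need at least 2 networks with enough ROIs")
    h, p = stats.kruskal(*groups.values())
    return NetworkSummary(per_network=groups, kruskal_h=float(h),
                          p_value=float(p), excluded=excluded)
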