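"""Family-aware 10-fold cross-validation of the topography-behavior CCA.

Folds are built by assigning whole families to folds (greedy size
balancing), so twins — and in fact all family members — can never be
split between training and test data.  Per fold, component reduction and
the CCA are fitted on the training participants only; test participants
are pushed through the training standardization, deconfounding,
component bases and canonical weights, and the out-of-sample canonical
correlation is the Pearson correlation of the resulting test score pair
for mode 1.

Weight stability is measured on full-length weights (the correlation of
training canonical scores with the original variables), which live in a
common space across folds; component-space weights do not, because each
fold learns its own component basis.  Splits are sign-aligned to the
first split before the pairwise correlations are averaged.

Permutation significance re-pairs the two blocks within each fold's
training set (family-blocked), refits the canonical weights — the
per-block component reductions are unsupervised and row-order invariant,
so they need no refit — and rescores the test fold, yielding per-fold and
mean-level null distributions of out-of-sample correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import ComponentScores, behavioral_components, topography_components
from .cca import _pearson_cols, _qr_block, fit_cca
from .errors import InvalidArgumentError
from .families import BlockPermuter, FamilyStructure


@dataclass
class FoldPlan:
    fold_of: pd.Series  # participant -> fold id (0..k-1)
    k: int
    seed: int | None

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of.to_numpy() == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of.to_numpy() != fold)


@dataclass
class CVReport:
    fold_r: np.ndarray                # out-of-sample r per fold, mode 1
    mean_r: float
    weight_stability_brain: float
    weight_stability_behavior: float
    best_fold: int
    in_sample_r: np.ndarray
    fold_p: np.ndarray | None = None
    mean_level_p: float | None = None
    any_fold_significant: bool | None = None
    train_brain_weights: list = field(default_factory=list)    # full-length, per fold
    train_behavior_weights: list = field(default_factory=list)
    _artifacts: list = field(default_factory=list)             # per-fold fitted pieces


def family_aware_folds(roster, family: FamilyStructure, k: int = 10,
                       seed: int | None = None) -> FoldPlan:
    """Greedy size-balanced assignment of whole families to k folds."""
    roster = [str(r) for r in roster]
    n = len(roster)
    if n < 2 * k:
        raise InvalidArgumentError("need at least 2k participants")
    fam_ids = family.family_ids_for(roster)
    fams: dict = {}
    for pid, fid in zip(roster, fam_ids):
        fams.setdefault(fid, []).append(pid)
    sizes = {f: len(m) for f, m in fams.items()}
    if max(sizes.values()) > n / k:
        raise InvalidArgumentError("a family is larger than n/k; folds cannot balance")
    rng = np.random.default_rng(seed)
    order = list(fams.keys())
    rng.shuffle(order)
    order.sort(key=lambda f: -sizes[f])  # stable: ties keep shuffled order
    fold_sizes = np.zeros(k, dtype=int)
    assignment: dict[str, int] = {}
    for f in order:
        target = int(np.argmin(fold_sizes))
        for pid in fams[f]:
            assignment[pid] = target
        fold_sizes[target] += sizes[f]
    return FoldPlan(fold_of=pd.Series({p: assignment[p] for p in roster}), k=k, seed=seed)


def _standardize_scores(s: np.ndarray, mean: np.ndarray) -> np.ndarray:
    return s - mean


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def cross_validate_cca(topos, behavior, plan: FoldPlan, k_components: int = 100,
                       confounds=None) -> CVReport:
    """Out-of-sample mode-1 canonical correlations over the fold plan.

    ``topos`` (complete) and ``behavior`` (possibly sparsely missing) are
    participants x variables DataFrames aligned to the plan's roster.
    """
    T = pd.DataFrame(topos)
    B = pd.DataFrame(behavior)
    conf = None if confounds is None else np.asarray(pd.DataFrame(confounds), float)
    fold_r, in_r = [], []
    brain_w, behav_w = [], []
    artifacts = []
    for fold in range(plan.k):
        tr = plan.train_indices(fold)
        te = plan.test_indices(fold)
        if te.size < 3:
            raise InvalidArgumentError(f"test fold {fold} smaller than 3")
        conf_tr = None if conf is None else conf[tr]
        conf_te = None if conf is None else conf[te]
        tc = topography_components(T.iloc[tr], k=k_components, confounds=conf_tr)
        bc = behavioral_components(B.iloc[tr], k=k_components, confounds=conf_tr)
        modes = fit_cca(tc, bc)
        m0 = modes[0]
        in_r.append(m0.canonical_r)
        # project test participants through training bases and weights
        ts = tc.project(T.iloc[te], conf_te)
        bs = bc.project(B.iloc[te], conf_te)
        u = (ts - tc.scores.mean(axis=0)) @ m0.brain_weights
        v = (bs - bc.scores.mean(axis=0)) @ m0.behavior_weights
        fold_r.append(_corr(u, v))
        brain_w.append(_pearson_cols(m0.brain_scores, T.iloc[tr].to_numpy(float)))
        behav_w.append(_pearson_cols(m0.behavior_scores, B.iloc[tr].to_numpy(float)))
        artifacts.append({"fold": fold, "tc": tc, "bc": bc, "mode": m0,
                          "train": tr, "test": te,
                          "test_scores": (ts, bs)})
    fold_r = np.asarray(fold_r)
    stab_brain = _stability(brain_w)
    stab_behav = _stability(behav_w)
    return CVReport(fold_r=fold_r, mean_r=float(fold_r.mean()),
                    weight_stability_brain=stab_brain,
                    weight_stability_behavior=stab_behav,
                    best_fold=int(np.argmax(fold_r)),
                    in_sample_r=np.asarray(in_r),
                    train_brain_weights=brain_w,
                    train_behavior_weights=behav_w,
                    _artifacts=artifacts)


def _stability(weight_list: list[np.ndarray]) -> float:
    """Mean pairwise correlation of per-split weights, sign-aligned to split 1."""
    W = []
    ref = weight_list[0]
    for w in weight_list:
        ok = np.isfinite(w) & np.isfinite(ref)
        sign = np.sign(np.corrcoef(w[ok], ref[ok])[0, 1]) or 1.0
        W.append(w * sign)
    k = len(W)
    cors = []
    for i in range(k):
        for j in range(i + 1, k):
            ok = np.isfinite(W[i]) & np.isfinite(W[j])
            cors.append(np.corrcoef(W[i][ok], W[j][ok])[0, 1])
    return float(np.mean(cors))


def cv_permutation_significance(report: CVReport, family: FamilyStructure,
                                roster, n_perm: int = 5000,
                                seed: int | None = None) -> CVReport:
    """Per-fold and mean-level permutation p-values for the CV report.

    Within each fold's training set, the behavior block's rows are
    re-paired with the topography block under family-blocked permutations;
    canonical weights are refit (component bases are unaffected by row
    re-pairing) and the test fold rescored.
    """
    if n_perm < 100:
        import warnings
        warnings.warn("n_perm < 100 gives an unstable null tail", stacklevel=2)
    rng = np.random.default_rng(seed)
    fam_all = family.family_ids_for(roster)
    n_folds = len(report._artifacts)
    null = np.empty((n_perm, n_folds))
    for j, art in enumerate(report._artifacts):
        tc: ComponentScores = art["tc"]
        bc: ComponentScores = art["bc"]
        tr = art["train"]
        ts, bs = art["test_scores"]
        n_tr = tr.size
        xc, qx, rx = _qr_block(tc.scores, "brain")
        yc, qy, ry = _qr_block(bc.scores, "behavior")
        permuter = BlockPermuter(fam_all[tr])
        ts_c = ts - tc.scores.mean(axis=0)
        bs_c = bs - bc.scores.mean(axis=0)
        for p in range(n_perm):
            perm = permuter.permutation(rng)
            u_svd, s, vt = np.linalg.svd(qx.T @ qy[perm])
            a = np.linalg.solve(rx, u_svd[:, 0])
            # weights of the permuted-behavior block, mapped back to raw order
            b_perm = np.linalg.solve(ry, vt[0])
            u = ts_c @ a
            v = bs_c @ b_perm
            null[p, j] = _corr(u, v)
    counts = (null >= report.fold_r[None, :]).sum(axis=0)
    fold_p = (1.0 + counts) / (1.0 + n_perm)
    mean_counts = (null.mean(axis=1) >= report.mean_r).sum()
    mean_p = (1.0 + mean_counts) / (1.0 + n_perm)
    report.fold_p = fold_p
    report.mean_level_p = float(mean_p)
    report.any_fold_significant = bool((fold_p < 0.005).any())
    return report
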