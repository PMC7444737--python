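"""Statistical inference over accuracy maps.

Family-wise error (FWE) control across the parcel family uses the
max-statistic permutation scheme: labels are permuted (one shared
permutation per draw, applied identically to every parcel), the per-parcel
cross-validated accuracy is recomputed, and the maximum over parcels is
stored.  The FWE-corrected p-value of a parcel is the add-one empirical
tail probability of its observed accuracy under those maxima:
p = (1 + #{b : max_b >= acc}) / (1 + B), which is never exactly zero and
yields a valid level-alpha test under exchangeability.

Secondary analyses: rank correlation of accuracy maps, male-minus-female
connectivity-difference vectors and their correlation across samples,
gray-matter-volume (GMV) confound checks, the framewise-displacement group
test, and the consensus set of top-fraction parcels across analyses.
"""

from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from joblib import Parallel, delayed
from scipy import stats

from .atlas import Atlas
from . import classify as _clf
from .classify import HyperParams, cross_validated_accuracy, parcel_features
from .connectome import Connectome, parcel_feature_vector
from .results import AccuracyMap, DifferenceVector, MapComparison, PermutationNull

__all__ = [
    "permutation_fwe",
    "spearman_map_correlation",
    "sex_difference_vector",
    "difference_vector_correlation",
    "gmv_accuracy_correlation",
    "misclassification_gmv_test",
    "consensus_top_parcels",
    "fd_group_test",
]


def _resolve_hyperparams(observed: AccuracyMap, hyperparams, pid, n_features):
    if isinstance(hyperparams, HyperParams):
        return hyperparams
    if isinstance(hyperparams, Mapping):
        return hyperparams[pid]
    meta_hp = observed.metadata.get("hyperparams") if observed.metadata else None
    if meta_hp and pid in meta_hp:
        return meta_hp[pid]
    fixed = observed.metadata.get("fixed_hyperparams") if observed.metadata else None
    if fixed is not None:
        return fixed
    return _clf.default_hyperparams(n_features)


def permutation_fwe(
    z_stack: np.ndarray,
    atlas: Atlas,
    labels,
    confounds=None,
    observed: Optional[AccuracyMap] = None,
    n_perm: int = 5000,
    seed: int = 0,
    k: int = 10,
    hyperparams: Union[HyperParams, Mapping, None] = None,
    grid=None,
    retune: bool = False,
    n_jobs: int = 1,
):
    """Max-statistic permutation FWE correction over the parcel family.

    For each permutation one shared label shuffle is applied to ALL parcels;
    per-parcel CV accuracy is recomputed with the same CV settings as the
    observed map, and the maximum over parcels is stored.  By default the
    hyperparameters selected on the unpermuted data are reused inside the
    permutation loop; ``retune=True`` re-tunes per permutation with ``grid``.

    Returns ``(AccuracyMap with p_fwe, PermutationNull)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if observed is None:
        raise ValueError("an observed AccuracyMap is required")
    if observed.metadata.get("k", k) != k:
        raise ValueError("cv settings (k) mismatch with the observed map")
    pids = [int(p) for p in observed.parcel_ids]
    y = np.asarray(labels).astype(str)
    feats = {pid: parcel_features(z_stack, atlas, pid) for pid in pids}
    hp_by_pid = {
        pid: _resolve_hyperparams(observed, hyperparams, pid, feats[pid].shape[1])
        for pid in pids
    }

    rng = np.random.default_rng(seed)
    perms = [rng.permutation(len(y)) for _ in range(n_perm)]

    def one_perm(b):
        yb = y[perms[b]]
        fold_seed = int((seed * 2_000_003 + b + 1) % (2**31 - 1))
        best = 0.0
        for pid in pids:
            if retune and grid is not None:
                res = cross_validated_accuracy(
                    feats[pid], yb, confounds, k=k, grid=grid, seed=fold_seed, parcel_id=pid
                )
            else:
                res = cross_validated_accuracy(
                    feats[pid], yb, confounds, k=k, hyperparams=hp_by_pid[pid],
                    seed=fold_seed, parcel_id=pid,
                )
            best = max(best, res.accuracy)
        return best

    max_acc = np.array(Parallel(n_jobs=n_jobs)(delayed(one_perm)(b) for b in range(n_perm)))
    null = PermutationNull(max_accuracies=max_acc, n_permutations=n_perm, seed=seed)
    p_fwe = np.array([
        (1 + int(np.sum(max_acc >= a))) / (1 + n_perm) if np.isfinite(a) else np.nan
        for a in observed.accuracy
    ])
    corrected = AccuracyMap(
        parcel_ids=observed.parcel_ids.copy(),
        accuracy=observed.accuracy.copy(),
        p_fwe=p_fwe,
        metadata={**observed.metadata, "n_perm": n_perm, "perm_seed": seed},
    )
    return corrected, null


def spearman_map_correlation(a: AccuracyMap, b: AccuracyMap) -> MapComparison:
    """Spearman rank correlation (average-rank ties, t-approximation p) of two maps."""
    if len(a) != len(b) or np.any(a.parcel_ids != b.parcel_ids):
        raise ValueError("maps must cover the same parcel set, in the same order")
    if len(a) < 3:
        raise ValueError("need at least 3 parcels")
    rho, p = stats.spearmanr(a.accuracy, b.accuracy)
    return MapComparison(rho=float(rho), p_value=float(p), n_parcels=len(a))


def sex_difference_vector(
    connectomes: Sequence[Connectome], sexes, parcel_id: int
) -> DifferenceVector:
    """Male mean minus female mean of one parcel's feature vector (length P-1)."""
    sexes = np.asarray(sexes).astype(str)
    if not (np.any(sexes == "M") and np.any(sexes == "F")):
        raise ValueError("both sexes must be present")
    feats = np.vstack([parcel_feature_vector(c, parcel_id) for c in connectomes])
    diff = feats[sexes == "M"].mean(axis=0) - feats[sexes == "F"].mean(axis=0)
    return DifferenceVector(parcel_id=parcel_id, values=diff)


def difference_vector_correlation(a: DifferenceVector, b: DifferenceVector):
    """Pearson correlation of two samples' difference vectors. Returns (r, p)."""
    if len(a.values) != len(b.values):
        raise ValueError("difference vectors must have equal length")
    if a.parcel_id != b.parcel_id:
        raise ValueError("difference vectors refer to different parcels")
    if np.std(a.values) == 0 or np.std(b.values) == 0:
        raise ValueError("zero-variance difference vector")
    r, p = stats.pearsonr(a.values, b.values)
    return float(r), float(p)


def _subset_indices(acc_map: AccuracyMap, subset: str, alpha: float = 0.05) -> np.ndarray:
    if subset == "all":
        return np.arange(len(acc_map))
    if subset == "significant":
        if acc_map.p_fwe is None:
            raise ValueError("subset 'significant' requires p_fwe on the map")
        idx = np.flatnonzero(acc_map.p_fwe < alpha)
    elif subset == "top_decile":
        n_top = max(1, math.floor(0.1 * len(acc_map)))
        cutoff = np.sort(acc_map.accuracy)[::-1][n_top - 1]
        idx = np.flatnonzero(acc_map.accuracy >= cutoff)
    else:
        raise ValueError(f"unknown subset {subset!r}")
    if not idx.size:
        raise ValueError(f"subset {subset!r} is empty")
    return idx


def gmv_accuracy_correlation(
    gmv: np.ndarray, sexes, acc_map: AccuracyMap, subset: str = "all", alpha: float = 0.05
):
    """Rank correlation between per-parcel sex difference in GMV and accuracy.

    Returns ``(directed, absolute)`` MapComparisons: the directed
    male-minus-female mean GMV difference per parcel, and its absolute
    value, each Spearman-correlated with accuracy over the chosen subset.
    """
    gmv = np.asarray(gmv, dtype=float)
    sexes = np.asarray(sexes).astype(str)
    pid_mask = acc_map.parcel_ids != _clf.WHOLE_BRAIN_ID
    if gmv.shape[1] != int(pid_mask.sum()):
        raise ValueError("gmv must have one column per (brain) parcel of the map")
    directed = gmv[sexes == "M"].mean(axis=0) - gmv[sexes == "F"].mean(axis=0)
    idx = _subset_indices(acc_map, subset, alpha)
    idx = idx[pid_mask[idx]]
    acc = acc_map.accuracy[idx]
    pos = np.cumsum(pid_mask) - 1  # map-row -> gmv column
    d = directed[pos[idx]]
    out = []
    for vec in (d, np.abs(d)):
        rho, p = stats.spearmanr(vec, acc)
        out.append(MapComparison(rho=float(rho), p_value=float(p), n_parcels=len(idx)))
    return tuple(out)


def misclassification_gmv_test(
    gmv: np.ndarray, per_subject_correct, alpha_fdr: float = 0.05
) -> dict:
    """Welch t-test per parcel: GMV of correctly vs incorrectly classified subjects.

    P-values are Benjamini-Hochberg adjusted across parcels.  A parcel with
    constant GMV in either group yields NaN, recorded but excluded from FDR.
    """
    gmv = np.asarray(gmv, dtype=float)
    correct = np.asarray(per_subject_correct, dtype=bool)
    if correct.all() or (~correct).all():
        return {
            "t": np.full(gmv.shape[1], np.nan), "p": np.full(gmv.shape[1], np.nan),
            "p_fdr": np.full(gmv.shape[1], np.nan), "n_significant": 0,
            "message": "one correctness group is empty; t-tests undefined",
        }
    g1, g0 = gmv[correct], gmv[~correct]
    t = np.full(gmv.shape[1], np.nan)
    p = np.full(gmv.shape[1], np.nan)
    for j in range(gmv.shape[1]):
        if g1[:, j].std() == 0 and g0[:, j].std() == 0:
            continue
        tj, pj = stats.ttest_ind(g1[:, j], g0[:, j], equal_var=False)
        t[j], p[j] = tj, pj
    p_fdr = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        p_fdr[ok] = stats.false_discovery_control(p[ok], method="bh")
    return {
        "t": t, "p": p, "p_fdr": p_fdr,
        "n_significant": int(np.nansum(p_fdr < alpha_fdr)),
    }


def consensus_top_parcels(maps: Sequence[AccuracyMap], fraction: float = 0.03) -> set:
    """Intersection of each map's top floor(fraction * P) parcels.

    Ties at the accuracy cutoff are broken by including all tied parcels.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if not maps:
        raise ValueError("need at least one map")
    pid0 = set(int(p) for p in maps[0].parcel_ids)
    consensus = None
    for m in maps:
        if set(int(p) for p in m.parcel_ids) != pid0:
            raise ValueError("maps must share the same parcel set")
        n_top = max(1, math.floor(fraction * len(m)))
        cutoff = np.sort(m.accuracy)[::-1][n_top - 1]
        top = {int(p) for p, a in zip(m.parcel_ids, m.accuracy) if a >= cutoff}
        consensus = top if consensus is None else consensus & top
    return consensus


def fd_group_test(phenotypes_or_cohort):
    """Two-sample t-test of mean framewise displacement by sex. Returns (t, p)."""
    obj = phenotypes_or_cohort
    if hasattr(obj, "mean_fd") and hasattr(obj, "sexes"):
        fd, sexes = np.asarray(obj.mean_fd, dtype=float), np.asarray(obj.sexes).astype(str)
    else:
        fd = np.array([p.mean_fd for p in obj])
        sexes = np.array([p.sex for p in obj])
    m, f = fd[sexes == "M"], fd[sexes == "F"]
    if len(m) < 2 or len(f) < 2:
        raise ValueError("need at least two subjects per sex")
    t, p = stats.ttest_ind(m, f, equal_var=False)
    return float(t), float(p)
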