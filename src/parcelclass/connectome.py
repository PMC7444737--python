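"""From cleaned time series to Fisher-Z connectomes and feature vectors.

Per subject: regress white-matter/CSF nuisance signals out of each channel
(OLS with intercept), reduce each parcel's voxel time courses to its first
eigenvariate when voxel-level data are given, correlate every parcel with
every other parcel (Pearson), and variance-stabilize with the Fisher Z
transform z = atanh(r).  A parcel's feature vector is its row of the Z
matrix excluding the diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .atlas import Atlas, make_atlas

__all__ = [
    "TimeSeriesMatrix",
    "Connectome",
    "regress_nuisance",
    "first_eigenvariate",
    "compute_connectome",
    "parcel_feature_vector",
    "whole_brain_feature_vector",
    "connectome_from_upper",
    "cohort_connectomes",
    "stack_connectomes",
]

_CLIP_EPS = 1e-7  # correlation clipping before atanh keeps Z finite


@dataclass
class TimeSeriesMatrix:
    """volumes x channels matrix with channel identifiers and TR (seconds)."""

    values: np.ndarray
    channel_ids: Sequence[int]
    tr: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (volumes x channels)")
        if self.values.shape[0] < 3:
            raise ValueError("need at least 3 volumes")
        if self.values.shape[1] != len(self.channel_ids):
            raise ValueError("channel_ids length must match number of columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contain non-finite values")


@dataclass
class Connectome:
    """Symmetric Fisher-Z connectivity matrix; the diagonal is masked (NaN)."""

    z: np.ndarray
    atlas: Atlas

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        p = self.atlas.n_parcels
        if self.z.shape != (p, p):
            raise ValueError("z must be n_parcels x n_parcels")
        off = ~np.eye(p, dtype=bool)
        if not np.all(np.isfinite(self.z[off])):
            raise ValueError("off-diagonal Fisher-Z values must be finite")
        if not np.allclose(self.z[off], self.z.T[off], atol=1e-12):
            raise ValueError("z must be symmetric")


def regress_nuisance(ts: TimeSeriesMatrix, nuisance: TimeSeriesMatrix) -> TimeSeriesMatrix:
    """OLS residuals of each channel on [intercept, nuisance columns].

    Residual columns are mean-zero and orthogonal to every nuisance column.
    Collinear nuisance columns are dropped with a warning.
    """
    x = ts.values
    nvals = np.asarray(nuisance.values, dtype=float)
    if nvals.ndim != 2 or nvals.shape[1] < 1:
        raise ValueError("nuisance must have at least one column")
    if nvals.shape[0] != x.shape[0]:
        raise ValueError("time series and nuisance must have equal volume counts")
    design = np.column_stack([np.ones(x.shape[0]), nvals])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # drop collinear columns greedily, keeping the intercept
        keep = [0]
        for j in range(1, design.shape[1]):
            cand = design[:, keep + [j]]
            if np.linalg.matrix_rank(cand) > len(keep):
                keep.append(j)
        warnings.warn(
            f"nuisance design rank-deficient; dropped {design.shape[1] - len(keep)} column(s)",
            stacklevel=2,
        )
        design = design[:, keep]
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    resid = x - design @ beta
    return TimeSeriesMatrix(values=resid, channel_ids=list(ts.channel_ids), tr=ts.tr)


def first_eigenvariate(voxel_ts: TimeSeriesMatrix) -> np.ndarray:
    """Dominant temporal mode of a parcel's voxel time courses.

    Returns the first left singular vector of the column-demeaned voxel
    matrix scaled by its singular value / sqrt(n_voxels).  Sign convention:
    non-negative correlation with the mean voxel signal; if that is a tie
    (zero mean signal), non-negative correlation with the first voxel.
    """
    x = np.asarray(voxel_ts.values, dtype=float)
    if x.shape[1] < 1:
        raise ValueError("need at least one voxel column")
    xc = x - x.mean(axis=0, keepdims=True)
    if not np.any(np.abs(xc) > 0):
        raise ValueError("all voxel time courses are constant (zero variance)")
    n_vox = x.shape[1]
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    ev = u[:, 0] * s[0] / np.sqrt(n_vox)
    mean_sig = xc.mean(axis=1)
    ref = mean_sig if np.dot(mean_sig, mean_sig) > 1e-12 * n_vox else xc[:, 0]
    if np.dot(ev, ref) < 0:
        ev = -ev
    return ev


def compute_connectome(parcel_ts: TimeSeriesMatrix, atlas: Optional[Atlas] = None) -> Connectome:
    """Pairwise Pearson correlations between parcel time series, Fisher-Z transformed.

    Correlations are clipped to [-1+eps, 1-eps] (eps = 1e-7) before atanh so
    degenerate inputs stay finite.  The diagonal is masked as NaN and never
    consumed downstream.
    """
    x = parcel_ts.values
    if atlas is None:
        atlas = make_atlas(x.shape[1])
    if list(parcel_ts.channel_ids) != list(atlas.parcel_ids):
        raise ValueError("channels must be the atlas parcels, in atlas order")
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        bad = [atlas.parcel_ids[i] for i in dead]
        raise ValueError(f"zero-variance time series for parcel(s) {bad}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(r, -1 + _CLIP_EPS, 1 - _CLIP_EPS)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, np.nan)
    return Connectome(z=z, atlas=atlas)


def parcel_feature_vector(c: Connectome, parcel_id: int) -> np.ndarray:
    """Row of Z for one parcel, excluding the diagonal entry (length n_parcels - 1)."""
    i = c.atlas.index_of(parcel_id)
    row = c.z[i]
    return np.delete(row, i)


def whole_brain_feature_vector(c: Connectome) -> np.ndarray:
    """Strict upper triangle of Z in row-major atlas order (length P(P-1)/2)."""
    p = c.atlas.n_parcels
    iu = np.triu_indices(p, k=1)
    return c.z[iu]


def connectome_from_upper(vec: np.ndarray, atlas: Atlas) -> Connectome:
    """Inverse of :func:`whole_brain_feature_vector`."""
    p = atlas.n_parcels
    iu = np.triu_indices(p, k=1)
    if len(vec) != len(iu[0]):
        raise ValueError("vector length does not match atlas size")
    z = np.zeros((p, p))
    z[iu] = vec
    z = z + z.T
    np.fill_diagonal(z, np.nan)
    return Connectome(z=z, atlas=atlas)


def cohort_connectomes(cohort, clean: bool = True, clean_stage: str = "voxel") -> list:
    """Connectome per subject of a synthetic cohort.

    When voxel-level series are present, each parcel is reduced to its
    first eigenvariate; ``clean_stage`` controls whether WM/CSF cleaning is
    applied to the voxel series before reduction (``'voxel'``, default) or
    to the parcel series afterwards (``'parcel'``).
    """
    if clean_stage not in ("voxel", "parcel"):
        raise ValueError("clean_stage must be 'voxel' or 'parcel'")
    out = []
    ids = list(cohort.atlas.parcel_ids)
    for i in range(cohort.n_subjects):
        nuis = TimeSeriesMatrix(cohort.nuisance[i], ["wm", "csf"], tr=cohort.config.tr)
        if cohort.voxel_timeseries is not None:
            cols = []
            for j, vox in enumerate(cohort.voxel_timeseries[i]):
                vts = TimeSeriesMatrix(vox, list(range(vox.shape[1])), tr=cohort.config.tr)
                if clean and clean_stage == "voxel":
                    vts = regress_nuisance(vts, nuis)
                cols.append(first_eigenvariate(vts))
            ts = TimeSeriesMatrix(np.column_stack(cols), ids, tr=cohort.config.tr)
            if clean and clean_stage == "parcel":
                ts = regress_nuisance(ts, nuis)
        else:
            ts = TimeSeriesMatrix(cohort.timeseries[i], ids, tr=cohort.config.tr)
            if clean:
                ts = regress_nuisance(ts, nuis)
        out.append(compute_connectome(ts, cohort.atlas))
    return out


def stack_connectomes(connectomes: Sequence[Connectome]) -> np.ndarray:
    """(n_subjects, P, P) array of Fisher-Z matrices (diagonal NaN)."""
    if not connectomes:
        raise ValueError("no connectomes given")
    a0 = connectomes[0].atlas
    for c in connectomes:
        if c.atlas.parcel_ids != a0.parcel_ids:
            raise ValueError("connectomes use different atlases")
    return np.stack([c.z for c in connectomes])
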