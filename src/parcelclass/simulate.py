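"""Synthetic resting-state cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes: two balanced sex groups whose mean parcelwise connectivity differs
by a controlled amount (in Fisher-Z units) on chosen parcels, age-coupled
connectivity, per-parcel gray-matter volume (GMV) with a sex offset, mean
framewise displacement (FD), white-matter/CSF nuisance components, and two
acquisition profiles (a long high-temporal-resolution run versus a short
slow one).

The generative model is a low-rank factor model on parcel signals plus
diagonal noise.  Sex and age effects are applied additively on the Fisher-Z
scale to the group-mean correlation matrix and back-transformed; each
subject's correlation matrix is a Wishart perturbation of that group matrix
(degrees of freedom set by ``subject_noise_sd``), repaired to a valid
correlation matrix when needed (:func:`nearest_correlation`), and the
subject's time series is drawn as a zero-mean Gaussian with that
correlation structure.  Two AR(1) nuisance series (white-matter / CSF proxies) are
injected with subject-specific per-parcel loadings so the cleaning stage
has real work to do.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .atlas import Atlas, default_atlas, make_atlas

__all__ = [
    "CohortConfig",
    "SubjectPhenotype",
    "Cohort",
    "generate_cohort",
    "generate_sample_pair",
    "nearest_correlation",
    "match_subjects_by_covariate",
    "profile_long_run",
    "profile_short_run",
]

_Z_BOUND = 7.0  # |tanh(7)| rounds to 1.0 in float64 at ~1e-6 precision


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of one synthetic cohort ("sample").

    Defaults mirror the long-acquisition study profile: 434 subjects,
    436 parcels, 1200 volumes at TR = 0.72 s, ages 22-37.  Effect sizes
    ``effect_parcels`` map parcel id -> delta (Fisher-Z units), applied to
    that parcel's connectivity with the designated target set so that the
    male-minus-female expected Fisher-Z on those edges equals delta.
    """

    n_subjects: int = 434
    n_parcels: int = 436
    n_volumes: int = 1200
    tr: float = 0.72
    n_latent_factors: int = 12
    effect_parcels: Mapping[int, float] = field(default_factory=dict)
    target_parcels: Optional[Sequence[int]] = None
    age_effect: float = 0.0
    age_parcels: Optional[Sequence[int]] = None
    age_range: tuple = (22.0, 37.0)
    age_sex_gap: float = 0.0  # years added to male ages (breaks age matching when nonzero)
    gmv_sex_offset: float = 30.0
    subject_noise_sd: float = 0.1
    fd_median: float = 0.16
    fd_sigma: float = 0.25
    nuisance_ar: float = 0.6
    nuisance_loading: tuple = (0.5, 0.15)  # mean, sd of per-parcel loadings
    voxels_per_parcel: int = 20
    voxel_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2 or self.n_subjects % 2:
            raise ValueError("n_subjects must be even and >= 2")
        if self.n_parcels < 3:
            raise ValueError("n_parcels must be >= 3")
        if self.n_volumes < 3:
            raise ValueError("n_volumes must be >= 3")
        if self.n_latent_factors < 1:
            raise ValueError("n_latent_factors must be >= 1")
        for pid, delta in self.effect_parcels.items():
            if not np.isfinite(delta):
                raise ValueError(f"effect size for parcel {pid} is not finite")
        if self.subject_noise_sd < 0:
            raise ValueError("subject_noise_sd must be >= 0")


def profile_long_run(**overrides) -> CohortConfig:
    """Acquisition profile A: 1200 volumes, TR 0.72 s, young adults (22-37 y)."""
    return replace(CohortConfig(), **overrides)


def profile_short_run(**overrides) -> CohortConfig:
    """Acquisition profile B: 300 volumes, TR 2.2 s, wide age range (18-88 y)."""
    base = CohortConfig(n_subjects=941, n_volumes=300, tr=2.2, age_range=(18.0, 88.0))
    return replace(base, **overrides)


@dataclass(frozen=True)
class SubjectPhenotype:
    subject_id: str
    sex: str  # 'F' or 'M'
    age: float
    mean_fd: float
    gmv: np.ndarray  # per-parcel, arbitrary units, all > 0

    def __post_init__(self):
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if self.age <= 0 or self.mean_fd < 0:
            raise ValueError("invalid age or mean_fd")
        if np.any(np.asarray(self.gmv) <= 0):
            raise ValueError("gmv entries must be > 0")


@dataclass
class Cohort:
    """Per-subject parcel time series plus phenotypes for one sample."""

    atlas: Atlas
    phenotypes: list  # list[SubjectPhenotype]
    timeseries: list  # list of (n_volumes, n_parcels) arrays
    nuisance: list  # list of (n_volumes, 2) arrays: WM, CSF proxies
    config: CohortConfig
    voxel_timeseries: Optional[list] = None  # per subject: list of (n_volumes, n_voxels) per parcel

    @property
    def n_subjects(self) -> int:
        return len(self.phenotypes)

    @property
    def sexes(self) -> np.ndarray:
        return np.array([p.sex for p in self.phenotypes])

    @property
    def ages(self) -> np.ndarray:
        return np.array([p.age for p in self.phenotypes])

    @property
    def mean_fd(self) -> np.ndarray:
        return np.array([p.mean_fd for p in self.phenotypes])

    @property
    def gmv(self) -> np.ndarray:
        """(n_subjects, n_parcels) gray-matter volumes."""
        return np.vstack([p.gmv for p in self.phenotypes])

    def subset(self, indices: Sequence[int]) -> "Cohort":
        idx = list(indices)
        return Cohort(
            atlas=self.atlas,
            phenotypes=[self.phenotypes[i] for i in idx],
            timeseries=[self.timeseries[i] for i in idx],
            nuisance=[self.nuisance[i] for i in idx],
            config=self.config,
            voxel_timeseries=None
            if self.voxel_timeseries is None
            else [self.voxel_timeseries[i] for i in idx],
        )


def nearest_correlation(m: np.ndarray, tol: float = 1e-8, max_iter: int = 100) -> np.ndarray:
    """Project a symmetric matrix to the nearest valid correlation matrix.

    Eigenvalue-clipping scheme: off-diagonals are clipped to [-1, 1], the
    diagonal set to 1, negative eigenvalues clipped to a small positive
    floor, and the diagonal renormalized; iterated until the smallest
    eigenvalue is >= -tol.  A valid correlation matrix is a fixed point.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be a square matrix")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("input must be symmetric")
    a = (m + m.T) / 2.0
    np.fill_diagonal(a, 1.0)
    a = np.clip(a, -1.0, 1.0)
    for _ in range(max_iter):
        w, v = np.linalg.eigh(a)
        if w[0] >= -tol:
            return a
        w = np.clip(w, tol, None)
        a = (v * w) @ v.T
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
        a = (a + a.T) / 2.0
        np.fill_diagonal(a, 1.0)
        a = np.clip(a, -1.0, 1.0)
    return a


def _psd_factor(r: np.ndarray) -> np.ndarray:
    """Factor F with F F' = R for sampling; falls back to an eigen-factor
    (and a PSD repair) when R is singular or slightly indefinite."""
    try:
        return np.linalg.cholesky(r + 1e-12 * np.eye(len(r)))
    except np.linalg.LinAlgError:
        rr = nearest_correlation(r)
        w, v = np.linalg.eigh(rr)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Unit-marginal-variance AR(1) series."""
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov_sd = np.sqrt(1.0 - phi**2)
    eps = rng.standard_normal(n - 1) * innov_sd
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def _resolve_atlas(n_parcels: int) -> Atlas:
    return default_atlas() if n_parcels == 436 else make_atlas(n_parcels)


def _resolve_targets(config: CohortConfig, atlas: Atlas) -> list:
    """Target set for sex/age effects: explicit, or the last 10 non-effect parcels."""
    if config.target_parcels is not None:
        return [int(p) for p in config.target_parcels]
    non_effect = [p for p in atlas.parcel_ids if p not in config.effect_parcels]
    return non_effect[-min(10, len(non_effect)):]


def _resolve_age_parcels(config: CohortConfig, atlas: Atlas, targets: list) -> list:
    if config.age_parcels is not None:
        return [int(p) for p in config.age_parcels]
    if config.age_effect == 0.0:
        return []
    pool = [p for p in atlas.parcel_ids if p not in config.effect_parcels and p not in targets]
    return pool[:1]


def _edge_mask(atlas: Atlas, sources: Sequence[int], targets: Sequence[int]) -> np.ndarray:
    """Symmetric boolean mask over (source, target) edges, self-edges excluded."""
    p = atlas.n_parcels
    mask = np.zeros((p, p), dtype=bool)
    for s in sources:
        si = atlas.index_of(s)
        for t in targets:
            if t == s:
                continue
            ti = atlas.index_of(t)
            mask[si, ti] = mask[ti, si] = True
    return mask


def generate_cohort(
    config: CohortConfig,
    voxel_level: bool = False,
    structure_seed: Optional[int] = None,
) -> Cohort:
    """Generate one synthetic cohort.

    ``structure_seed`` pins the latent covariance structure (factor
    loadings, base GMV) independently of the subject-level draws; two
    cohorts generated with the same structure seed live on the same
    underlying "brain" and differ only in subjects and acquisition.
    """
    config.validate()
    atlas = _resolve_atlas(config.n_parcels)
    p = atlas.n_parcels
    sseed = config.seed if structure_seed is None else structure_seed
    rng_struct = np.random.default_rng(np.random.SeedSequence(entropy=(0xA11A5, sseed)))
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(0x5AB1EC7, config.seed)))

    # base correlation structure: low-rank factors + diagonal uniqueness
    loadings = rng_struct.normal(size=(p, config.n_latent_factors))
    uniq = rng_struct.uniform(0.5, 1.5, size=p) * config.n_latent_factors / 4.0
    sigma = loadings @ loadings.T + np.diag(uniq)
    d = np.sqrt(np.diag(sigma))
    r0 = sigma / np.outer(d, d)
    # shrink toward identity: guarantees spectral headroom (min eigenvalue
    # > 0.5) so planted Fisher-Z effects never push the group matrix off the
    # correlation cone, which would force a repair that shrinks the effect
    r0 = 0.5 * r0 + 0.5 * np.eye(p)
    z0 = np.arctanh(np.clip(r0, -1 + 1e-7, 1 - 1e-7))
    np.fill_diagonal(z0, 0.0)
    gmv_base = rng_struct.lognormal(mean=np.log(500.0), sigma=0.2, size=p)

    targets = _resolve_targets(config, atlas)
    age_parcels = _resolve_age_parcels(config, atlas, targets)
    delta = np.zeros((p, p))
    for pid, d_z in config.effect_parcels.items():
        delta[_edge_mask(atlas, [pid], targets)] = d_z
    z_male = z0 + delta / 2.0
    z_female = z0 - delta / 2.0
    for z in (z_male, z_female):
        off = z[~np.eye(p, dtype=bool)]
        if np.any(np.abs(off) > _Z_BOUND):
            raise ValueError(
                "effect sizes push mean Fisher-Z past the invertible range "
                "(|z| > 7, back-transformed correlation indistinguishable from 1)"
            )
    age_mask = _edge_mask(atlas, age_parcels, targets) if age_parcels else None

    n = config.n_subjects
    half = n // 2
    lo, hi = config.age_range
    pair_ages = rng.uniform(lo, hi, size=half)
    age_mid = (lo + hi) / 2.0

    # Subject "trait" noise: a Wishart draw around the (sex- and age-specific)
    # correlation matrix with nu = 1/sd^2 degrees of freedom.  This perturbs
    # every edge with Fisher-Z standard deviation ~ subject_noise_sd while
    # keeping the matrix positive semidefinite and, crucially, leaving the
    # expected male-minus-female Fisher-Z difference at the designed delta
    # (an unstructured entrywise perturbation would need a PSD projection
    # that systematically shrinks planted effects).
    nu = None
    if config.subject_noise_sd > 0:
        nu = max(3, int(round(1.0 / config.subject_noise_sd**2)))

    phenotypes, ts_list, nuis_list = [], [], []
    vox_list = [] if voxel_level else None
    for i in range(n):
        sex = "F" if i % 2 == 0 else "M"
        age = pair_ages[i // 2] + (config.age_sex_gap if sex == "M" else 0.0)
        zi = (z_male if sex == "M" else z_female).copy()
        if age_mask is not None:
            zi[age_mask] += config.age_effect * (age - age_mid)
        ri = np.tanh(zi)
        np.fill_diagonal(ri, 1.0)
        fac = _psd_factor(ri)
        if nu is not None:
            g = rng.standard_normal((nu, p)) @ fac.T
            s = g.T @ g / nu
            d = np.sqrt(np.diag(s))
            ri = s / np.outer(d, d)
            ri = nearest_correlation(ri) if np.linalg.eigvalsh(ri)[0] < -1e-8 else ri
            fac = _psd_factor(ri)
        x = rng.standard_normal((config.n_volumes, fac.shape[1])) @ fac.T

        wm = _ar1(rng, config.n_volumes, config.nuisance_ar)
        csf = _ar1(rng, config.n_volumes, config.nuisance_ar)
        mu_l, sd_l = config.nuisance_loading
        load_wm = rng.normal(mu_l, sd_l, size=p)
        load_csf = rng.normal(mu_l, sd_l, size=p)
        x = x + np.outer(wm, load_wm) + np.outer(csf, load_csf)

        fd = float(rng.lognormal(mean=np.log(config.fd_median), sigma=config.fd_sigma))
        gmv = gmv_base * (1.0 + 0.1 * rng.standard_normal(p))
        if sex == "M":
            gmv = gmv + config.gmv_sex_offset
        gmv = np.maximum(gmv, 1e-3)
        phenotypes.append(
            SubjectPhenotype(subject_id=f"sub-{i + 1:04d}", sex=sex, age=float(age), mean_fd=fd, gmv=gmv)
        )
        ts_list.append(x)
        nuis_list.append(np.column_stack([wm, csf]))
        if voxel_level:
            per_parcel = []
            v = config.voxels_per_parcel
            for j in range(p):
                w = np.abs(rng.normal(1.0, 0.3, size=v))
                vox = x[:, j][:, None] * w[None, :] + rng.normal(
                    0.0, config.voxel_noise_sd, size=(config.n_volumes, v)
                )
                per_parcel.append(vox)
            vox_list.append(per_parcel)

    return Cohort(
        atlas=atlas,
        phenotypes=phenotypes,
        timeseries=ts_list,
        nuisance=nuis_list,
        config=config,
        voxel_timeseries=vox_list,
    )


def generate_sample_pair(
    config_a: CohortConfig,
    config_b: CohortConfig,
    shared_effect: Mapping[int, float],
):
    """Generate two cohorts sharing the same sex-effect map and latent structure.

    The cohorts differ in acquisition (volumes, TR), subjects, noise and age
    distribution but share the base covariance structure and effect parcels
    — the cross-sample generalization test bed.
    """
    if config_a.n_parcels != config_b.n_parcels:
        raise ValueError("sample pair must share the same atlas (n_parcels differ)")
    if config_a.target_parcels != config_b.target_parcels:
        raise ValueError("sample pair must share the same target parcels")
    ca = replace(config_a, effect_parcels=dict(shared_effect))
    cb = replace(config_b, effect_parcels=dict(shared_effect))
    structure_seed = config_a.seed
    cohort_a = generate_cohort(ca, structure_seed=structure_seed)
    cohort_b = generate_cohort(cb, structure_seed=structure_seed)
    return cohort_a, cohort_b


def match_subjects_by_covariate(
    cohort: Cohort,
    covariate: str = "gmv_total",
    caliper: Optional[float] = None,
) -> Cohort:
    """Greedy nearest-neighbor sex matching on a subject-level covariate.

    Each male (in input order) is paired without replacement with the
    nearest unmatched female; pairs farther apart than ``caliper`` are
    discarded.  Returns the subset cohort (original subject order) with
    equal sex counts; deterministic given input order.
    """
    if covariate == "gmv_total":
        values = cohort.gmv.sum(axis=1)
    elif covariate in ("age", "mean_fd"):
        values = getattr(cohort, "ages" if covariate == "age" else "mean_fd")
    else:
        raise ValueError(f"unknown covariate {covariate!r}")
    sexes = cohort.sexes
    male_idx = [i for i in range(cohort.n_subjects) if sexes[i] == "M"]
    female_idx = [i for i in range(cohort.n_subjects) if sexes[i] == "F"]
    available = list(female_idx)
    keep = []
    for mi in male_idx:
        if not available:
            break
        dists = [abs(values[mi] - values[fi]) for fi in available]
        j = int(np.argmin(dists))  # ties -> lowest index among available
        if caliper is not None and dists[j] > caliper:
            continue
        keep.append(mi)
        keep.append(available.pop(j))
    if not keep:
        raise ValueError("no subject pairs could be formed under the caliper")
    return cohort.subset(sorted(keep))


def expected_sex_difference(config: CohortConfig) -> np.ndarray:
    """Designed male-minus-female mean Fisher-Z matrix (zero off effect edges)."""
    atlas = _resolve_atlas(config.n_parcels)
    targets = _resolve_targets(config, atlas)
    delta = np.zeros((atlas.n_parcels, atlas.n_parcels))
    for pid, d_z in config.effect_parcels.items():
        delta[_edge_mask(atlas, [pid], targets)] = d_z
    return delta
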