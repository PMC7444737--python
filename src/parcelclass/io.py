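"""On-disk formats: cohort directories, accuracy maps, NIfTI extraction.

The interchange format is TSV (tab-separated, UTF-8, "." decimal, NA for
missing).  A cohort directory holds one atlas TSV, one phenotype TSV (with
per-parcel GMV columns), per-subject time-series and nuisance TSVs, and a
JSON provenance file recording the generating configuration and seed.
Floats are written with 17 significant digits so write -> read -> write
round-trips are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .atlas import Atlas
from .connectome import Connectome, TimeSeriesMatrix
from .results import AccuracyMap, PermutationNull
from .simulate import Cohort, CohortConfig, SubjectPhenotype

__all__ = [
    "write_cohort",
    "read_cohort",
    "write_atlas",
    "read_atlas",
    "write_accuracy_map",
    "read_accuracy_map",
    "write_connectome",
    "read_connectome",
    "write_permutation_null",
    "read_nifti_parcels",
    "summarize_accuracy_map",
]

_FMT = "%.17g"


def _write_matrix(path: Path, values: np.ndarray, header: list) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(str(h) for h in header) + "\n")
        np.savetxt(fh, values, fmt=_FMT, delimiter="\t")


def _read_matrix(path: Path):
    df = pd.read_csv(path, sep="\t", header=0, na_values=["NA"], keep_default_na=False,
                     float_precision="round_trip")
    return df.columns.tolist(), df.to_numpy(dtype=float)


def write_atlas(atlas: Atlas, path) -> None:
    df = pd.DataFrame({
        "parcel_id": atlas.parcel_ids,
        "name": atlas.names,
        "is_subcortical": [int(b) for b in atlas.is_subcortical],
    })
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_atlas(path) -> Atlas:
    df = pd.read_csv(path, sep="\t")
    for col in ("parcel_id", "name", "is_subcortical"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing atlas column {col!r}")
    return Atlas(
        tuple(int(i) for i in df["parcel_id"]),
        tuple(str(n) for n in df["name"]),
        tuple(bool(b) for b in df["is_subcortical"]),
    )


def write_cohort(cohort: Cohort, out_dir) -> None:
    """Write a cohort to a directory (atlas, phenotypes, time series, provenance)."""
    out = Path(out_dir)
    (out / "timeseries").mkdir(parents=True, exist_ok=True)
    (out / "nuisance").mkdir(parents=True, exist_ok=True)
    write_atlas(cohort.atlas, out / "atlas.tsv")

    gmv_cols = {f"gmv_{pid}": cohort.gmv[:, j] for j, pid in enumerate(cohort.atlas.parcel_ids)}
    pheno = pd.DataFrame({
        "subject_id": [p.subject_id for p in cohort.phenotypes],
        "sex": [p.sex for p in cohort.phenotypes],
        "age": [p.age for p in cohort.phenotypes],
        "mean_fd": [p.mean_fd for p in cohort.phenotypes],
        **gmv_cols,
    })
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False,
                 float_format=_FMT, lineterminator="\n")

    ids = list(cohort.atlas.parcel_ids)
    for p, ts, nuis in zip(cohort.phenotypes, cohort.timeseries, cohort.nuisance):
        _write_matrix(out / "timeseries" / f"{p.subject_id}.tsv", ts, ids)
        _write_matrix(out / "nuisance" / f"{p.subject_id}.tsv", nuis, ["wm", "csf"])

    prov = {"config": dataclasses.asdict(cohort.config), "format": "parcelclass-cohort-v1"}
    prov["config"]["effect_parcels"] = {str(k): v for k, v in cohort.config.effect_parcels.items()}
    with open(out / "provenance.json", "w") as fh:
        json.dump(prov, fh, indent=1, sort_keys=True)


def read_cohort(in_dir) -> Cohort:
    """Read a cohort directory written by :func:`write_cohort` (lossless round-trip)."""
    src = Path(in_dir)
    atlas = read_atlas(src / "atlas.tsv")
    pheno = pd.read_csv(src / "phenotypes.tsv", sep="\t", na_values=["NA"],
                        keep_default_na=False, float_precision="round_trip")
    for col in ("subject_id", "sex", "age", "mean_fd"):
        if col not in pheno.columns:
            raise ValueError(f"phenotypes.tsv: missing column {col!r}")
    gmv_cols = [f"gmv_{pid}" for pid in atlas.parcel_ids]
    missing = [c for c in gmv_cols if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotypes.tsv: missing GMV column(s) {missing[:3]}...")

    with open(src / "provenance.json") as fh:
        prov = json.load(fh)
    cfg = dict(prov["config"])
    cfg["effect_parcels"] = {int(k): float(v) for k, v in cfg.get("effect_parcels", {}).items()}
    for key in ("age_range", "nuisance_loading"):
        if key in cfg and cfg[key] is not None:
            cfg[key] = tuple(cfg[key])
    for key in ("target_parcels", "age_parcels"):
        if cfg.get(key) is not None:
            cfg[key] = tuple(cfg[key])
    config = CohortConfig(**cfg)

    phenotypes, ts_list, nuis_list = [], [], []
    for _, row in pheno.iterrows():
        sid = str(row["subject_id"])
        gmv = row[gmv_cols].to_numpy(dtype=float)
        phenotypes.append(SubjectPhenotype(
            subject_id=sid, sex=str(row["sex"]), age=float(row["age"]),
            mean_fd=float(row["mean_fd"]), gmv=gmv,
        ))
        header, ts = _read_matrix(src / "timeseries" / f"{sid}.tsv")
        if not np.all(np.isfinite(ts)):
            raise ValueError(f"timeseries/{sid}.tsv contains NA or non-finite cells")
        if [int(h) for h in header] != list(atlas.parcel_ids):
            raise ValueError(f"timeseries/{sid}.tsv: header does not match atlas order")
        _, nuis = _read_matrix(src / "nuisance" / f"{sid}.tsv")
        if not np.all(np.isfinite(nuis)):
            raise ValueError(f"nuisance/{sid}.tsv contains NA or non-finite cells")
        ts_list.append(ts)
        nuis_list.append(nuis)
    return Cohort(atlas=atlas, phenotypes=phenotypes, timeseries=ts_list,
                  nuisance=nuis_list, config=config)


def write_connectome(c: Connectome, path, sidecar: Optional[dict] = None) -> None:
    """Connectome TSV (P x P, diagonal written as NA) with a JSON sidecar."""
    path = Path(path)
    z = c.z.copy()
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(str(i) for i in c.atlas.parcel_ids) + "\n")
        for row in z:
            fh.write("\t".join("NA" if np.isnan(v) else _FMT % v for v in row) + "\n")
    meta = {"atlas_hash": c.atlas.hash()}
    if sidecar:
        meta.update(sidecar)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_connectome(path, atlas: Atlas) -> Connectome:
    header, z = _read_matrix(Path(path))
    if [int(h) for h in header] != list(atlas.parcel_ids):
        raise ValueError(f"{path}: header does not match atlas")
    return Connectome(z=z, atlas=atlas)


def write_accuracy_map(amap: AccuracyMap, path, atlas: Optional[Atlas] = None,
                       config_hash: str = "") -> None:
    path = Path(path)
    df = amap.to_frame(atlas)
    df.to_csv(path, sep="\t", index=False, float_format=_FMT, lineterminator="\n")
    meta = {"config_hash": config_hash,
            "metadata": {k: v for k, v in amap.metadata.items()
                         if isinstance(v, (int, float, str, bool, type(None)))}}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def read_accuracy_map(path):
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False,
                     float_precision="round_trip")
    amap = AccuracyMap(
        parcel_ids=df["parcel_id"].to_numpy(int),
        accuracy=df["accuracy"].to_numpy(float),
        p_fwe=df["p_fwe"].to_numpy(float) if "p_fwe" in df.columns else None,
    )
    sidecar = path.with_suffix(".json")
    config_hash = ""
    if sidecar.exists():
        with open(sidecar) as fh:
            config_hash = json.load(fh).get("config_hash", "")
    return amap, config_hash


def write_permutation_null(null: PermutationNull, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("max_accuracy\n")
        np.savetxt(fh, null.max_accuracies, fmt=_FMT)


def read_nifti_parcels(image_4d, labels_3d, atlas: Atlas) -> dict:
    """Group voxel time series of a 4-D NIfTI image by an integer label image.

    Returns ``{parcel_id: TimeSeriesMatrix (volumes x voxels)}``.  Label
    value 0 is background; label values absent from the atlas raise; atlas
    parcels absent from the label image are excluded with a warning.
    """
    import nibabel as nib

    img = nib.load(str(image_4d)) if not hasattr(image_4d, "get_fdata") else image_4d
    lab = nib.load(str(labels_3d)) if not hasattr(labels_3d, "get_fdata") else labels_3d
    data = np.asarray(img.get_fdata())
    labels = np.asarray(lab.get_fdata())
    if data.ndim != 4:
        raise ValueError("image must be 4-D")
    if labels.shape != data.shape[:3] or not np.allclose(img.affine, lab.affine, atol=1e-4):
        raise ValueError("image and label grids do not match")
    if not np.allclose(labels, np.round(labels)):
        raise ValueError("label image must contain integer labels")
    labels = np.round(labels).astype(int)
    present = set(int(v) for v in np.unique(labels)) - {0}
    unknown = present - set(atlas.parcel_ids)
    if unknown:
        raise ValueError(f"label value(s) {sorted(unknown)} not in atlas")
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    out = {}
    for pid in atlas.parcel_ids:
        mask = labels == pid
        if not mask.any():
            warnings.warn(f"parcel {pid} has no voxels in the label image; excluded", stacklevel=2)
            continue
        vox = data[mask, :].T  # volumes x voxels
        out[pid] = TimeSeriesMatrix(values=vox, channel_ids=list(range(vox.shape[1])), tr=tr)
    return out


def summarize_accuracy_map(amap: AccuracyMap, alpha: float = 0.05) -> dict:
    """Headline numbers: max/min/mean and sample SD of accuracies, significance counts."""
    acc = amap.accuracy[np.isfinite(amap.accuracy)]
    if acc.size == 0:
        raise ValueError("accuracy map is empty")
    out = {
        "n_parcels": int(len(amap)),
        "max_accuracy": float(acc.max()),
        "min_accuracy": float(acc.min()),
        "mean_accuracy": float(acc.mean()),
        "sd_accuracy": float(acc.std(ddof=1)) if acc.size > 1 else None,
    }
    if amap.p_fwe is not None:
        sig = amap.p_fwe < alpha
        out["n_significant"] = int(np.nansum(sig))
        out["n_not_significant"] = int(len(amap) - np.nansum(sig))
        out["alpha"] = alpha
    return out
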