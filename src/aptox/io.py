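"""Cohort and report file I/O.

A cohort on disk is one directory per patient of NIfTI volumes (dose +
each organ mask), a cohort-level CSV of covariates and outcomes, and a
JSON manifest echoing the generating configuration and listing every
written file. Volumes are stored with the array axes (z, y, x) and a
diagonal affine carrying the voxel spacing.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import CohortConfig, DoseGrid, PatientRecord, StructureSet

__all__ = [
    "write_cohort",
    "load_cohort",
    "write_report",
    "write_volume",
    "write_significance_map",
]

_COVARIATE_COLUMNS = (
    "age", "gender", "PS", "chemo", "AJCC_stage", "MEVS", "smoking", "COPD",
)


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([*spacing, 1.0])
    aff[:3, 3] = origin
    return aff


def _save_volume(path: Path, values: np.ndarray, spacing, origin) -> None:
    img = nib.Nifti1Image(np.asarray(values), _affine(spacing, origin))
    nib.save(img, str(path))


def write_cohort(cohort: list[PatientRecord], path, config: CohortConfig | None = None) -> Path:
    """Write a cohort directory; returns the manifest path."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    files: list[str] = []
    rows = []
    for r in cohort:
        pdir = root / r.id
        pdir.mkdir(exist_ok=True)
        _save_volume(pdir / "dose.nii", r.dose.values.astype(np.float32),
                     r.dose.spacing, r.dose.origin)
        files.append(f"{r.id}/dose.nii")
        for name, mask in r.structures.masks.items():
            _save_volume(pdir / f"{name}.nii", mask,
                         r.structures.spacing, r.structures.origin)
            files.append(f"{r.id}/{name}.nii")
        rows.append({"id": r.id, **{c: r.covariates[c] for c in _COVARIATE_COLUMNS},
                     "apt2": int(r.apt2), "apt3": int(r.apt3)})
    table = pd.DataFrame(rows)
    table.to_csv(root / "cohort.csv", index=False)
    files.append("cohort.csv")
    manifest = {
        "n_patients": len(cohort),
        "files": files,
        "config": None if config is None else dataclasses.asdict(config),
    }
    mpath = root / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, default=list))
    files.append("manifest.json")
    return mpath


def _load_volume(path: Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    aff = img.affine
    spacing = tuple(float(aff[i, i]) for i in range(3))
    origin = tuple(float(aff[i, 3]) for i in range(3))
    return np.asarray(img.dataobj), spacing, origin


def load_cohort(path) -> list[PatientRecord]:
    """Load a cohort directory written by :func:`write_cohort`.

    Validates that every volume shares one frame and that no covariate is
    missing; errors name the offending patient and column/mask.
    """
    root = Path(path)
    table = pd.read_csv(root / "cohort.csv")
    for col in (*_COVARIATE_COLUMNS, "apt2", "apt3"):
        if col not in table.columns:
            raise ValueError(f"cohort.csv is missing column {col!r}")
        bad = table[table[col].isna()]
        if len(bad):
            raise ValueError(
                f"missing covariate {col!r} for patient {bad['id'].iloc[0]!r}"
            )
    records = []
    frame = None
    for row in table.to_dict("records"):
        pid = str(row["id"])
        pdir = root / pid
        dose_values, spacing, origin = _load_volume(pdir / "dose.nii")
        masks = {}
        for name in StructureSet.REQUIRED:
            fpath = pdir / f"{name}.nii"
            if not fpath.exists():
                raise FileNotFoundError(f"patient {pid}: missing mask {name!r}")
            m, msp, _ = _load_volume(fpath)
            if m.shape != dose_values.shape:
                raise ValueError(f"patient {pid}: mask {name!r} shape mismatch")
            masks[name] = m.astype(np.uint8)
        this_frame = (dose_values.shape, spacing)
        if frame is None:
            frame = this_frame
        elif this_frame != frame:
            raise ValueError(f"patient {pid}: grid frame differs from cohort frame")
        covariates = {c: row[c] for c in _COVARIATE_COLUMNS}
        covariates["chemo"] = bool(covariates["chemo"])
        covariates["COPD"] = bool(covariates["COPD"])
        records.append(
            PatientRecord(
                id=pid,
                dose=DoseGrid(values=np.asarray(dose_values, float),
                              spacing=spacing, origin=origin),
                structures=StructureSet(masks, spacing=spacing, origin=origin),
                covariates=covariates,
                apt2=bool(row["apt2"]),
                apt3=bool(row["apt3"]),
            )
        )
    return records


def write_volume(values: np.ndarray, path, spacing=(1.0, 1.0, 1.0),
                 origin=(0.0, 0.0, 0.0)) -> Path:
    """Write any scalar volume (e.g. a radiomics map) as NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _save_volume(path, np.asarray(values, dtype=np.float32), spacing, origin)
    return path


def write_significance_map(sig, path, spacing=(1.0, 1.0, 1.0)) -> Path:
    """Write a voxel-analysis result: t, p_fwe and region volumes as NIfTI
    plus a one-row CSV summary (voxel count and centroid of the region)."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    origin = (0.0, 0.0, 0.0)
    _save_volume(root / "t.nii", sig.t.astype(np.float32), spacing, origin)
    _save_volume(root / "p_fwe.nii", sig.p_fwe.astype(np.float32), spacing, origin)
    _save_volume(root / "region.nii", sig.region.astype(np.uint8), spacing, origin)
    n = int(sig.region.sum())
    centroid = (
        [float(c) for c in np.argwhere(sig.region).mean(axis=0)]
        if n else [float("nan")] * 3
    )
    pd.DataFrame([{
        "n_voxels": n,
        "centroid_z": centroid[0],
        "centroid_y": centroid[1],
        "centroid_x": centroid[2],
        "alpha": sig.alpha,
        "n_perm": sig.n_perm_used,
        "exhaustive": sig.exhaustive,
    }]).to_csv(root / "region_summary.csv", index=False)
    return root


def write_report(bundle: dict, path) -> Path:
    """Write a run-report bundle (per-model metrics, curves) to disk.

    Scalars land in ``metrics.csv``, curves in per-model CSV files, and a
    manifest lists every file written. Returns the manifest path.
    """
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    files = []
    scalar_rows = []
    for model_name, res in bundle["models"].items():
        scalar_rows.append({"model": model_name, **res["metrics"]})
        for curve_name in ("decision_curve", "precision_recall", "calibration"):
            if curve_name not in res:
                continue
            fname = f"{model_name}_{curve_name}.csv"
            pd.DataFrame(res[curve_name]).to_csv(root / fname, index=False)
            files.append(fname)
    pd.DataFrame(scalar_rows).to_csv(root / "metrics.csv", index=False)
    files.append("metrics.csv")
    config = bundle.get("config")
    meta = {
        "config": config,
        "files": sorted(files),
    }
    mpath = root / "manifest.json"
    mpath.write_text(json.dumps(meta, indent=2, default=str))
    return mpath
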