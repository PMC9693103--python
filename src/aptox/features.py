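"""Per-patient scalar features from planning-dose grids.

Dose-volume features (Vx, Dmean), six co-occurrence/histogram texture
features computed on the dose map discretized at 1 Gy per grey level
(IBSI-style definitions, merged symmetric GLCM over the 13 unique 3D
offsets at distance 1), and voxel-wise texture maps over a cubic kernel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import DoseGrid, PatientRecord, encode_covariate

__all__ = [
    "DiscretizedVolume",
    "CooccurrenceMatrix",
    "compute_vx",
    "compute_dmean",
    "discretize_dose",
    "build_glcm",
    "glcm_features",
    "histogram_energy",
    "radiomics_map",
    "extract_feature_table",
    "RADIOMIC_FEATURES",
    "DEFAULT_DVH_SPEC",
    "CLINICAL_FEATURES",
    "OFFSETS_3D",
]

#: the six dose-map texture features and the structures they are read from
RADIOMIC_FEATURES = (
    ("LungH_Variance", "lung_homo", "variance"),
    ("LungH_DVAR", "lung_homo", "difference_variance"),
    ("LungH_Contrast", "lung_homo", "contrast"),
    ("LungH_Entropy", "lung_homo", "entropy"),
    ("LungH_IC1", "lung_homo", "ic1"),
    ("Lungs_Energy", "lungs", "energy"),
)

#: default dose-volume features: (column, structure, kind, threshold Gy)
DEFAULT_DVH_SPEC = (
    ("V5_LungH", "lung_homo", "vx", 5.0),
    ("V10_LungH", "lung_homo", "vx", 10.0),
    ("V13_LungH", "lung_homo", "vx", 13.0),
    ("V30_2Lungs", "lungs", "vx", 30.0),
    ("V40_Heart", "heart", "vx", 40.0),
    ("DMean_LungH", "lung_homo", "dmean", None),
    ("DMean_2Lungs", "lungs", "dmean", None),
    ("DMean_Pmap", "pmap_region", "dmean", None),
)

CLINICAL_FEATURES = (
    "age", "gender", "PS", "chemo", "AJCC_stage", "MEVS", "smoking", "COPD",
)

#: the 13 unique displacement vectors at Chebyshev distance 1 in 3D
OFFSETS_3D = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)


def _as_bool_mask(mask: np.ndarray, like: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.shape != like.shape:
        raise ValueError("mask shape does not match dose shape")
    if not mask.any():
        raise ValueError("mask is empty")
    return mask


def _dose_values(dose: DoseGrid | np.ndarray) -> np.ndarray:
    return dose.values if isinstance(dose, DoseGrid) else np.asarray(dose, float)


@dataclass
class DiscretizedVolume:
    """Integer grey-level volume (1-based) with its validity mask."""

    levels: np.ndarray
    n_levels: int
    mask: np.ndarray

    def masked_levels(self) -> np.ndarray:
        return self.levels[self.mask]


@dataclass
class CooccurrenceMatrix:
    """Normalized symmetric grey-level co-occurrence matrix."""

    p: np.ndarray
    distance: int = 1

    @property
    def p_x(self) -> np.ndarray:
        return self.p.sum(axis=1)

    @property
    def p_y(self) -> np.ndarray:
        return self.p.sum(axis=0)


def compute_vx(dose: DoseGrid | np.ndarray, mask: np.ndarray, x: float) -> float:
    """Percent of the masked volume receiving at least ``x`` Gy."""
    d = _dose_values(dose)
    m = _as_bool_mask(mask, d)
    return float(100.0 * np.count_nonzero(d[m] >= x) / np.count_nonzero(m))


def compute_dmean(dose: DoseGrid | np.ndarray, mask: np.ndarray) -> float:
    """Mean dose (Gy) over the masked voxels."""
    d = _dose_values(dose)
    m = _as_bool_mask(mask, d)
    return float(d[m].mean())


def discretize_dose(
    dose: DoseGrid | np.ndarray, mask: np.ndarray, bin_width: float = 1.0
) -> DiscretizedVolume:
    """Fixed-bin-width grey-level discretization anchored at 0 Gy.

    level = floor(dose / bin_width) + 1, with doses on or above the top
    edge clamped into the last level; n_levels = ceil(max masked dose /
    bin_width), at least 1.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    d = _dose_values(dose)
    m = _as_bool_mask(mask, d)
    dmax = float(d[m].max())
    n_levels = max(1, math.ceil(dmax / bin_width))
    levels = np.zeros(d.shape, dtype=np.int32)
    levels[m] = np.minimum(
        np.floor(d[m] / bin_width).astype(np.int64) + 1, n_levels
    )
    return DiscretizedVolume(levels=levels, n_levels=n_levels, mask=m)


def build_glcm(vol: DiscretizedVolume, distance: int = 1) -> CooccurrenceMatrix:
    """Merged symmetric co-occurrence matrix over all 13 unique 3D offsets.

    Only pairs with both voxels inside the mask contribute; counts are
    accumulated in both orientations and normalized to sum 1.
    """
    lv, mask, n = vol.levels, vol.mask, vol.n_levels
    counts = np.zeros((n, n), dtype=np.float64)

    def shift_slices(off):
        src, dst = [], []
        for o in off:
            o *= distance
            if o >= 0:
                src.append(slice(o, None))
                dst.append(slice(None, lv.shape[len(src) - 1] - o))
            else:
                src.append(slice(None, o))
                dst.append(slice(-o, None))
        return tuple(src), tuple(dst)

    for off in OFFSETS_3D:
        src, dst = shift_slices(off)
        valid = mask[src] & mask[dst]
        if not valid.any():
            continue
        a = lv[src][valid] - 1
        b = lv[dst][valid] - 1
        np.add.at(counts, (a, b), 1.0)
        np.add.at(counts, (b, a), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid in-mask voxel pairs for the GLCM")
    return CooccurrenceMatrix(p=counts / total, distance=distance)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def glcm_features(m: CooccurrenceMatrix) -> dict[str, float]:
    """The five co-occurrence features (log base 2, 0*log 0 = 0).

    variance: joint variance sum p(i,j) (i - mu)^2 with mu the marginal
    mean; difference_variance: variance of the |i - j| distribution;
    contrast: sum p(i,j) (i - j)^2; entropy: -sum p log2 p;
    ic1 = (HXY - HXY1) / HX, 0 when HX = 0 (flagged degenerate).
    """
    p = m.p
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    p_x = m.p_x
    mu = float((i * p_x).sum())
    variance = float((p * (ii - mu) ** 2).sum())
    contrast = float((p * (ii - jj) ** 2).sum())

    k = np.abs(ii - jj).astype(np.int64)
    p_diff = np.bincount(k.ravel(), weights=p.ravel(), minlength=n)
    kk = np.arange(p_diff.size, dtype=float)
    mu_d = float((kk * p_diff).sum())
    difference_variance = float((p_diff * (kk - mu_d) ** 2).sum())

    entropy = _entropy_bits(p.ravel())
    hx = _entropy_bits(p_x)
    outer = np.outer(p_x, m.p_y)
    pos = (p > 0) & (outer > 0)
    hxy1 = float(-(p[pos] * np.log2(outer[pos])).sum())
    ic1 = 0.0 if hx == 0 else (entropy - hxy1) / hx

    return {
        "variance": variance,
        "difference_variance": difference_variance,
        "contrast": contrast,
        "entropy": entropy,
        "ic1": ic1,
    }


def histogram_energy(vol: DiscretizedVolume) -> float:
    """Histogram energy sum_i p_i^2 over the masked grey levels."""
    lv = vol.masked_levels()
    counts = np.bincount(lv, minlength=vol.n_levels + 1)[1:]
    p = counts / counts.sum()
    return float((p**2).sum())


_MAP_FEATURES = ("variance", "difference_variance", "contrast", "entropy", "ic1", "energy")


def radiomics_map(
    dose: DoseGrid | np.ndarray,
    mask: np.ndarray,
    feature: str,
    kernel: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-wise texture map over a ``kernel``^3 neighbourhood.

    The dose is discretized once over the whole mask (1 Gy grey levels);
    for every masked voxel the named feature is recomputed on the in-mask
    voxels of its neighbourhood, clipped at volume borders. Returns
    (map, valid) where ``valid`` flags voxels whose neighbourhood held at
    least 2 in-mask voxels (and, for co-occurrence features, at least one
    adjacent pair).

    Neighbourhood grey levels keep the global discretization so map values
    are comparable across voxels.
    """
    if feature not in _MAP_FEATURES:
        raise ValueError(f"unknown feature {feature!r}; one of {_MAP_FEATURES}")
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError("kernel must be odd and >= 3")
    d = _dose_values(dose)
    vol = discretize_dose(d, mask)
    lv, m = vol.levels, vol.mask
    r = kernel // 2
    out = np.zeros(d.shape, dtype=np.float64)
    valid = np.zeros(d.shape, dtype=bool)
    for z, y, x in zip(*np.nonzero(m)):
        sl = (
            slice(max(z - r, 0), z + r + 1),
            slice(max(y - r, 0), y + r + 1),
            slice(max(x - r, 0), x + r + 1),
        )
        pm = m[sl]
        if np.count_nonzero(pm) < 2:
            continue
        patch = DiscretizedVolume(levels=lv[sl], n_levels=vol.n_levels, mask=pm)
        if feature == "energy":
            out[z, y, x] = histogram_energy(patch)
            valid[z, y, x] = True
            continue
        try:
            g = build_glcm(patch)
        except ValueError:  # isolated voxels: no adjacent in-mask pair
            continue
        out[z, y, x] = glcm_features(g)[feature]
        valid[z, y, x] = True
    return out, valid


def patient_features(
    record: PatientRecord,
    dvh_spec=DEFAULT_DVH_SPEC,
) -> dict[str, float]:
    """All scalar features for one patient (dosimetric + radiomic + clinical)."""
    dose = record.dose
    masks = record.structures.masks
    row: dict[str, float] = {}
    for col, struct, kind, x in dvh_spec:
        mask = masks[struct]
        row[col] = (
            compute_vx(dose, mask, x) if kind == "vx" else compute_dmean(dose, mask)
        )
    glcm_cache: dict[str, dict[str, float]] = {}
    for col, struct, feat in RADIOMIC_FEATURES:
        vol = discretize_dose(dose, masks[struct])
        if feat == "energy":
            row[col] = histogram_energy(vol)
        else:
            if struct not in glcm_cache:
                glcm_cache[struct] = glcm_features(build_glcm(vol))
            row[col] = glcm_cache[struct][feat]
    for name in CLINICAL_FEATURES:
        row[name] = encode_covariate(name, record.covariates[name])
    return row


def extract_feature_table(
    cohort: list[PatientRecord],
    dvh_spec=DEFAULT_DVH_SPEC,
) -> pd.DataFrame:
    """Patients x features table with apt2/apt3 outcome columns.

    Column order is deterministic; any per-patient failure aborts with the
    offending patient id.
    """
    shapes = {r.structures.shape for r in cohort}
    if len(shapes) > 1:
        raise ValueError("cohort records do not share one grid frame")
    rows = []
    for record in cohort:
        try:
            row = patient_features(record, dvh_spec)
        except Exception as exc:  # noqa: BLE001 - re-raise with patient id
            raise RuntimeError(
                f"feature extraction failed for patient {record.id}: {exc}"
            ) from exc
        row["apt2"] = int(record.apt2)
        row["apt3"] = int(record.apt3)
        rows.append((record.id, row))
    df = pd.DataFrame.from_dict(dict(rows), orient="index")
    df.index.name = "id"
    if df.isna().any().any():
        raise ValueError("feature table contains missing values")
    return df
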