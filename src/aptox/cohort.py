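"""Synthetic lung-VMAT cohort generator.

Builds cohorts of 3D planning-dose grids, organ masks, clinical covariates
and planted binary pulmonary-toxicity outcomes (APT2 = CTCAE grade >= 2
within 6 months, APT3 = grade >= 3) with the statistical structure the
downstream analysis assumes:

* an ellipsoidal tumour target inside the homolateral (right) lung with a
  smooth exponential dose falloff, a broad low-dose bath and multiplicative
  correlated noise, normalized so the in-target peak equals the prescription
  dose — a crude but controllable stand-in for a VMAT plan;
* a posterior sub-region of the homolateral lung ("Pmap") whose mean dose
  drives toxicity risk through a logistic outcome model, together with the
  two-lung mean dose and optional clinical covariates;
* per-patient geometry jitter so dose-volume features vary across patients.

Everything is a pure function of :class:`CohortConfig` (including its seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.ndimage import distance_transform_edt, gaussian_filter
from scipy.optimize import bisect
from scipy.special import expit

__all__ = [
    "CohortConfig",
    "DoseGrid",
    "StructureSet",
    "PatientRecord",
    "generate_structures",
    "generate_dose_grid",
    "generate_covariates",
    "plant_outcome",
    "calibrate_intercept",
    "generate_cohort",
    "generate_planted_voxel_data",
    "OUTCOME_FEATURES",
]

#: features plant_outcome always requires in its input mapping
OUTCOME_FEATURES = ("DMean_Pmap", "DMean_2Lungs")

#: numeric encodings used for categorical covariates in the outcome model
#: and in downstream feature tables
CATEGORY_CODES = {
    "gender": {"M": 0, "F": 1},
    "AJCC_stage": {"IIIA": 0, "IIIB": 1, "IIIC": 2},
    "smoking": {"never": 0, "former": 1, "current": 2},
}


class InvalidStructureError(ValueError):
    """Raised when a structure set violates its geometric invariants."""


@dataclass(frozen=True)
class CohortConfig:
    """Generating configuration for a synthetic cohort.

    Parameters
    ----------
    n_patients
        Cohort size (>= 2). The emulated study uses 165 (training) and
        42 (testing).
    grid_shape
        Voxels per axis, indexed (z, y, x); each >= 4.
    voxel_spacing
        Millimetres per voxel along (z, y, x).
    prescription_dose
        Planned target dose in Gy (60–66 typical for locally advanced
        lung cancer).
    target_event_rate
        Desired marginal APT2 probability, in (0, 1); the intercept is
        calibrated to it when not given explicitly.
    beta_pmap, beta_lung
        Log-odds of APT2 per Gy of mean Pmap dose and per Gy of two-lung
        mean dose.
    beta_clinical
        Log-odds per unit of each (encoded) clinical covariate.
    intercept
        Logistic intercept; ``None`` means "calibrate to
        ``target_event_rate`` by bisection".
    p_apt3_given_apt2
        Conditional probability that an APT2 event is also grade >= 3.
    falloff_mm
        e-folding length of the dose falloff outside the target.
    bath_dose, bath_scale_mm
        Amplitude (Gy) and length scale of the broad low-dose bath.
    noise_sd, noise_corr_voxels
        Relative amplitude and correlation length (smoothing sigma, in
        voxels) of the multiplicative dose noise.
    """

    n_patients: int = 165
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    prescription_dose: float = 66.0
    target_event_rate: float = 0.224
    beta_pmap: float = 0.35
    beta_lung: float = 0.30
    beta_clinical: Mapping[str, float] = field(
        default_factory=lambda: {"COPD": 0.8}
    )
    intercept: float | None = None
    p_apt3_given_apt2: float = 0.25
    falloff_mm: float = 25.0
    bath_dose: float = 4.0
    bath_scale_mm: float = 120.0
    noise_sd: float = 0.05
    noise_corr_voxels: float = 1.0
    calibration_n: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 axes, each >= 4")
        if not 0.0 < self.target_event_rate < 1.0:
            raise ValueError("target_event_rate must lie in (0, 1)")
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be positive")


@dataclass
class DoseGrid:
    """A 3D absorbed-dose array (Gy) with grid metadata, indexed (z, y, x)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("dose values must be a 3D array")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("dose values must be finite and non-negative")


@dataclass
class StructureSet:
    """Named binary organ masks sharing one grid frame.

    Masks are uint8 0/1 volumes: ``lung_homo`` (homolateral lung),
    ``lung_contra``, ``lungs`` (their union), ``heart`` and ``pmap_region``
    (the toxicity-sensitive posterior sub-region of the homolateral lung).
    """

    masks: dict[str, np.ndarray]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    REQUIRED = ("lung_homo", "lung_contra", "lungs", "heart", "pmap_region")

    def __post_init__(self) -> None:
        self.masks = {
            k: np.asarray(v, dtype=np.uint8) for k, v in self.masks.items()
        }
        self.validate()

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.masks.values())).shape

    def validate(self) -> None:
        missing = [n for n in self.REQUIRED if n not in self.masks]
        if missing:
            raise InvalidStructureError(f"missing masks: {missing}")
        shape = self.shape
        for name, m in self.masks.items():
            if m.shape != shape:
                raise InvalidStructureError(f"mask {name!r} shape mismatch")
            if m.sum() == 0:
                raise InvalidStructureError(f"mask {name!r} is empty")
        homo, contra = self.masks["lung_homo"], self.masks["lung_contra"]
        if np.any(homo & contra):
            raise InvalidStructureError("lung_homo and lung_contra overlap")
        if not np.array_equal(self.masks["lungs"], homo | contra):
            raise InvalidStructureError("lungs != lung_homo | lung_contra")
        if np.any(self.masks["pmap_region"] & ~self.masks["lungs"]):
            raise InvalidStructureError("pmap_region not inside lungs")


@dataclass
class PatientRecord:
    """One synthetic patient: dose, structures, covariates, outcomes."""

    id: str
    dose: DoseGrid
    structures: StructureSet
    covariates: dict[str, object]
    apt2: bool
    apt3: bool

    def __post_init__(self) -> None:
        if self.apt3 and not self.apt2:
            raise ValueError("apt3 implies apt2")
        missing = [k for k, v in self.covariates.items() if v is None]
        if missing:
            raise ValueError(f"missing covariates: {missing}")


# ---------------------------------------------------------------------------
# geometry

def _ellipsoid(shape, center, semi_axes):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    d2 = (
        ((zz - center[0]) / semi_axes[0]) ** 2
        + ((yy - center[1]) / semi_axes[1]) ** 2
        + ((xx - center[2]) / semi_axes[2]) ** 2
    )
    return (d2 <= 1.0).astype(np.uint8)


def generate_structures(config: CohortConfig, rng: np.random.Generator) -> StructureSet:
    """Jittered ellipsoidal organ masks on the config grid.

    The homolateral lung sits on the patient's right (high x); the Pmap
    region is the posterior (high y) third of the homolateral lung, so it is
    a subset by construction.
    """
    nz, ny, nx = config.grid_shape
    shape = config.grid_shape

    def jitter(frac_center, frac_semi):
        c = [
            f * n + rng.uniform(-0.03, 0.03) * n
            for f, n in zip(frac_center, shape)
        ]
        s = [
            max(1.0, f * n * rng.uniform(0.9, 1.1))
            for f, n in zip(frac_semi, shape)
        ]
        return c, s

    c, s = jitter((0.50, 0.50, 0.71), (0.36, 0.28, 0.13))
    lung_homo = _ellipsoid(shape, c, s)
    homo_center, homo_semi = c, s
    c, s = jitter((0.50, 0.50, 0.29), (0.36, 0.28, 0.13))
    lung_contra = _ellipsoid(shape, c, s)
    c, s = jitter((0.45, 0.36, 0.50), (0.17, 0.15, 0.15))
    heart = _ellipsoid(shape, c, s)
    heart = (heart & ~(lung_homo | lung_contra)).astype(np.uint8)
    if heart.sum() == 0:  # degenerate tiny grid: keep the closest voxel
        heart = np.zeros(shape, np.uint8)
        heart[int(c[0]) % nz, int(c[1]) % ny, int(c[2]) % nx] = 1

    lungs = (lung_homo | lung_contra).astype(np.uint8)
    # posterior third of the homolateral lung, by y-coordinate quantile
    zi, yi, xi = np.nonzero(lung_homo)
    y_cut = np.quantile(yi, 2.0 / 3.0)
    pmap = np.zeros(shape, np.uint8)
    sel = yi >= y_cut
    if not sel.any():
        sel = yi == yi.max()
    pmap[zi[sel], yi[sel], xi[sel]] = 1

    masks = {
        "lung_homo": lung_homo,
        "lung_contra": lung_contra,
        "lungs": lungs,
        "heart": heart,
        "pmap_region": pmap,
    }
    st = StructureSet(masks, spacing=tuple(config.voxel_spacing))
    # stash target geometry for the dose model
    st._target_center = (  # type: ignore[attr-defined]
        homo_center[0] + rng.uniform(-0.15, 0.15) * nz,
        homo_center[1] + rng.uniform(-0.6, 0.6) * homo_semi[1],
        homo_center[2] + rng.uniform(-0.2, 0.2) * homo_semi[2],
    )
    st._target_semi = (  # type: ignore[attr-defined]
        max(1.0, 0.10 * nz),
        max(1.0, 0.09 * ny),
        max(1.0, 0.07 * nx),
    )
    return st


# ---------------------------------------------------------------------------
# dose

def generate_dose_grid(
    config: CohortConfig,
    structures: StructureSet,
    rng: np.random.Generator,
    *,
    falloff_mm: float | None = None,
) -> DoseGrid:
    """Emulate a VMAT plan on the structure set's grid.

    High-dose ellipsoidal target with exponential falloff of e-folding
    length ``falloff_mm`` plus a broad low-dose bath, multiplied by a
    spatially correlated noise field, then normalized so the in-target
    peak equals the prescription dose.
    """
    shape = structures.shape
    spacing = np.asarray(structures.spacing, dtype=float)
    center = getattr(structures, "_target_center", None)
    if center is None:
        zi, yi, xi = np.nonzero(structures.masks["lung_homo"])
        center = (zi.mean(), yi.mean(), xi.mean())
        semi = (
            max(1.0, 0.10 * shape[0]),
            max(1.0, 0.09 * shape[1]),
            max(1.0, 0.07 * shape[2]),
        )
    else:
        semi = structures._target_semi  # type: ignore[attr-defined]

    target = _ellipsoid(shape, center, semi)
    if target.sum() == 0:
        raise InvalidStructureError("target region is empty on this grid")

    # distance (mm) to the target, anisotropy handled by voxel spacing
    dist = distance_transform_edt(~target.astype(bool), sampling=spacing)

    lam = config.falloff_mm if falloff_mm is None else falloff_mm
    # per-patient plan-quality jitter of the falloff
    lam = lam * rng.uniform(0.85, 1.15)
    rx = config.prescription_dose
    with np.errstate(over="ignore"):
        core = rx * np.exp(-dist / max(lam, 1e-9))
    bath = config.bath_dose * np.exp(-dist / config.bath_scale_mm)
    dose = core + bath

    if config.noise_sd > 0:
        white = rng.standard_normal(shape)
        noise = gaussian_filter(white, sigma=config.noise_corr_voxels)
        sd = noise.std()
        if sd > 0:
            noise /= sd
        dose = dose * np.clip(1.0 + config.noise_sd * noise, 0.0, None)
    else:
        rng.standard_normal(shape)  # keep the stream position identical

    peak = dose[target.astype(bool)].max()
    if peak > 0:
        dose = dose * (rx / peak)
    return DoseGrid(values=dose, spacing=tuple(structures.spacing))


# ---------------------------------------------------------------------------
# covariates and outcome

def generate_covariates(rng: np.random.Generator) -> dict[str, object]:
    """Clinically plausible covariate draw for one patient."""
    age = float(np.clip(rng.normal(66.0, 8.0), 40.0, 90.0))
    return {
        "age": round(age, 1),
        "gender": "F" if rng.random() < 0.3 else "M",
        "PS": int(rng.choice([0, 1, 2], p=[0.35, 0.50, 0.15])),
        "chemo": bool(rng.random() < 0.8),
        "AJCC_stage": str(rng.choice(["IIIA", "IIIB", "IIIC"])),
        "MEVS": round(float(np.clip(rng.normal(2.0, 0.6), 0.6, 4.0)), 2),
        "smoking": str(rng.choice(["never", "former", "current"], p=[0.1, 0.45, 0.45])),
        "COPD": bool(rng.random() < 0.3),
    }


def encode_covariate(name: str, value: object) -> float:
    """Numeric encoding of a covariate for the outcome model / feature table."""
    if name in CATEGORY_CODES:
        return float(CATEGORY_CODES[name][value])  # type: ignore[index]
    if isinstance(value, bool):
        return float(value)
    return float(value)  # type: ignore[arg-type]


def _linear_predictor(features: Mapping[str, float], config: CohortConfig,
                      intercept: float) -> float:
    for name in OUTCOME_FEATURES:
        if name not in features:
            raise KeyError(f"plant_outcome requires feature {name!r}")
    lp = (
        intercept
        + config.beta_pmap * float(features["DMean_Pmap"])
        + config.beta_lung * float(features["DMean_2Lungs"])
    )
    for name, beta in config.beta_clinical.items():
        if name not in features:
            raise KeyError(f"plant_outcome requires feature {name!r}")
        lp += beta * float(features[name])
    return lp


def plant_outcome(
    features: Mapping[str, float],
    config: CohortConfig,
    rng: np.random.Generator,
    *,
    intercept: float | None = None,
) -> tuple[bool, bool]:
    """Draw (apt2, apt3) from the logistic outcome model.

    P(apt2) = expit(intercept + beta_pmap * DMean_Pmap
    + beta_lung * DMean_2Lungs + sum(beta_clinical * covariate)); apt3 is a
    Bernoulli(``p_apt3_given_apt2``) subset of apt2 cases.
    """
    if intercept is None:
        intercept = config.intercept if config.intercept is not None else 0.0
    p = expit(_linear_predictor(features, config, intercept))
    apt2 = bool(rng.random() < p)
    apt3 = bool(apt2 and rng.random() < config.p_apt3_given_apt2)
    return apt2, apt3


def _sample_outcome_features(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[dict[str, float], dict[str, object], StructureSet, DoseGrid]:
    """One patient's geometry + dose + the features the outcome model uses."""
    structures = generate_structures(config, rng)
    dose = generate_dose_grid(config, structures, rng)
    cov = generate_covariates(rng)
    d = dose.values
    feats = {
        "DMean_Pmap": float(d[structures.masks["pmap_region"].astype(bool)].mean()),
        "DMean_2Lungs": float(d[structures.masks["lungs"].astype(bool)].mean()),
    }
    for name in config.beta_clinical:
        feats[name] = encode_covariate(name, cov[name])
    return feats, cov, structures, dose


def calibrate_intercept(
    config: CohortConfig,
    n: int | None = None,
    seed: int | None = None,
    tol: float = 0.005,
) -> float:
    """Bisection on the mean event probability over ``n`` sampled patients.

    Returns the intercept for which the Monte-Carlo mean of
    expit(intercept + lp_i) equals ``config.target_event_rate`` to within
    ``tol``, where lp_i are linear-predictor contributions (betas applied
    to sampled dose and covariate features, no intercept).
    """
    n = config.calibration_n if n is None else n
    rng = np.random.default_rng(config.seed + 977 if seed is None else seed)
    lps = np.empty(n)
    for i in range(n):
        feats = _sample_outcome_features(config, rng)[0]
        lps[i] = _linear_predictor(feats, config, intercept=0.0)

    def rate_gap(c: float) -> float:
        return float(expit(c + lps).mean()) - config.target_event_rate

    lo, hi = -60.0, 60.0
    return float(bisect(rate_gap, lo, hi, xtol=tol / 4.0))


def generate_planted_voxel_data(
    config: CohortConfig,
    n_patients: int,
    region_size: tuple[int, int, int] = (5, 5, 5),
    effect: float = 1.0,
    region_dose_sd: float = 0.10,
    voxel_noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Registered dose maps with a planted toxicity-sensitive sub-region.

    Emulates a voxel-based analysis input: all patients share one frame
    (one reference geometry, as after phantom registration). A cuboid
    region of ``region_size`` voxels is centred on the posterior lung
    sub-region; each patient's dose inside it is scaled by a patient
    factor of relative spread ``region_dose_sd``, on top of independent
    voxel-level noise of relative spread ``voxel_noise_sd``. The outcome
    is drawn by :func:`plant_outcome` from the mean planted-region dose
    alone, with log-odds slope ``effect`` per Gy (``effect=0`` gives a
    global null: labels independent of the maps).

    Returns ``(data, valid_mask, labels, planted_mask)`` where ``data``
    is (n_patients, z, y, x), ``valid_mask`` is the shared lung mask and
    ``planted_mask`` is the sensitive region clipped to the lungs.
    """
    rng = np.random.default_rng(seed)
    base_cfg = dataclasses.replace(config, noise_sd=0.0)
    structures = generate_structures(base_cfg, rng)
    base = generate_dose_grid(base_cfg, structures, rng).values
    lungs = structures.masks["lungs"].astype(bool)

    zi, yi, xi = np.nonzero(structures.masks["pmap_region"])
    center = (int(round(zi.mean())), int(round(yi.mean())), int(round(xi.mean())))
    planted = np.zeros(base.shape, dtype=bool)
    sl = tuple(
        slice(max(c - s // 2, 0), min(c + s // 2 + 1, n))
        for c, s, n in zip(center, region_size, base.shape)
    )
    planted[sl] = True
    planted &= lungs
    if not planted.any():
        raise InvalidStructureError("planted region fell outside the lungs")

    base_region_mean = float(base[planted].mean())
    outcome_cfg = dataclasses.replace(
        config,
        beta_pmap=effect,
        beta_lung=0.0,
        beta_clinical={},
        intercept=-effect * base_region_mean,
    )
    data = np.empty((n_patients, *base.shape))
    labels = np.empty(n_patients, dtype=bool)
    for i in range(n_patients):
        s_i = rng.standard_normal()
        eps = rng.standard_normal(base.shape)
        factor = 1.0 + region_dose_sd * s_i * planted + voxel_noise_sd * eps
        dose = np.clip(base * factor, 0.0, None)
        data[i] = dose
        feats = {"DMean_Pmap": float(dose[planted].mean()), "DMean_2Lungs": 0.0}
        apt2, _ = plant_outcome(feats, outcome_cfg, rng,
                                intercept=outcome_cfg.intercept)
        labels[i] = apt2
    return data, lungs, labels, planted


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate ``config.n_patients`` records, deterministically from the seed.

    Per-patient substreams are spawned from ``SeedSequence(config.seed)`` so
    any patient's data is independent of cohort ordering.
    """
    intercept = config.intercept
    if intercept is None:
        intercept = calibrate_intercept(config)
    seqs = np.random.SeedSequence(config.seed).spawn(config.n_patients)
    records = []
    for i, sq in enumerate(seqs):
        rng = np.random.default_rng(sq)
        feats, cov, structures, dose = _sample_outcome_features(config, rng)
        apt2, apt3 = plant_outcome(feats, config, rng, intercept=intercept)
        records.append(
            PatientRecord(
                id=f"P{i:04d}",
                dose=dose,
                structures=structures,
                covariates=cov,
                apt2=apt2,
                apt3=apt3,
            )
        )
    return records
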