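"""Synthetic whole-body FDG-PET phantoms, an imperfect focus detector, and
survival cohorts with a known hazard model.

The phantom emulates a body-weight-SUV volume at clinical PET voxel size
(3.18 x 3.18 x 5.0 mm by default) containing a soft-tissue background,
a mediastinal blood-pool compartment, a liver compartment, and hot
lesions of known voxel-exact volume and SUVmax placed in organ-specific
zones.  Lesions are voxelised spheres: the ``ceil(volume / voxel
volume)`` voxels nearest the lesion centre (anisotropic metric), so the
constructed volume is an exact multiple of the voxel volume and the
half-max segmentation downstream can be checked against it without
slack.

The simulated detector stands in for a neural-network read: it flags
each truly suspicious focus as suspicious with a logistic probability
that rises with lesion volume and SUVmax (so small, faint lesions are
preferentially missed), mislabels physiological foci at a fixed
false-positive rate, and corrupts anatomical labels with per-level
confusion rates.

The cohort generator draws per-patient organ-wise metabolic tumor
volumes from a zero-inflated log-normal law and event times from a
proportional-hazards model on log2(MTV + 1 ml), so that downstream Cox
fits have a recoverable ground truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.special import expit, logit

from .anatomy import ORGAN_TO_LABELS
from .io import SUVVolume
from .survival import log2p1


class PlacementError(RuntimeError):
    """A lesion could not be placed without collision."""


class ConfigError(ValueError):
    """A phantom/detector/cohort configuration violates an invariant."""


# --------------------------------------------------------------------------
# configuration types
# --------------------------------------------------------------------------

#: fractional (x0, x1, y0, y1, z0, z1) boxes of the grid where lesions of
#: each organ may be centred; z runs caudal -> cranial
ORGAN_ZONES: dict[str, tuple[float, float, float, float, float, float]] = {
    "bone": (0.40, 0.60, 0.38, 0.62, 0.06, 0.94),
    "lymph node": (0.15, 0.85, 0.15, 0.85, 0.46, 0.82),
    "liver": (0.18, 0.52, 0.25, 0.75, 0.32, 0.43),
    "lung": (0.08, 0.92, 0.12, 0.88, 0.55, 0.78),
    "soft tissue": (0.12, 0.88, 0.12, 0.88, 0.08, 0.40),
    "breast/pectoral": (0.05, 0.30, 0.15, 0.85, 0.58, 0.76),
}


@dataclass
class LesionSpec:
    """One lesion to render: organ habitat, target volume (ml), SUVmax."""

    lesion_id: str
    organ: str
    volume_ml: float
    suvmax: float
    classification: str = "suspicious"
    center: tuple[int, int, int] | None = None  # voxel; None -> random in zone

    def __post_init__(self) -> None:
        if self.organ not in ORGAN_ZONES:
            raise ConfigError(f"unknown organ {self.organ!r} for lesion {self.lesion_id}")
        if self.volume_ml <= 0:
            raise ConfigError(f"lesion {self.lesion_id}: volume must be > 0 ml")
        if self.suvmax <= 0:
            raise ConfigError(f"lesion {self.lesion_id}: SUVmax must be > 0")
        if self.classification not in ("suspicious", "unsuspicious"):
            raise ConfigError(f"lesion {self.lesion_id}: bad classification")


@dataclass
class LesionSamplingLaw:
    """Random lesion law used when no explicit lesion list is given.

    Counts are Poisson; volumes and SUVmax log-normal (ml / SUV), both
    truncated to keep lesions renderable and supra-threshold.  Defaults
    echo a metastasised-breast-cancer read: about 21 foci per patient,
    roughly half physiological, with a wide small-skewed volume law.
    """

    n_suspicious_mean: float = 11.0
    n_physiological_mean: float = 10.0
    volume_log_mean: float = math.log(1.5)   # ml, log-normal median 1.5 ml
    volume_log_sd: float = 1.0
    volume_range_ml: tuple[float, float] = (0.1, 50.0)
    suvmax_log_mean: float = math.log(7.0)
    suvmax_log_sd: float = 0.35
    suvmax_min: float = 4.5
    organ_probs: dict[str, float] = field(default_factory=lambda: {
        "bone": 0.30, "lymph node": 0.30, "liver": 0.12,
        "lung": 0.10, "soft tissue": 0.10, "breast/pectoral": 0.08,
    })


@dataclass
class Compartment:
    """Reference-region compartment (box or ellipsoid) with its SUV law."""

    shape: str                      # "box" | "ellipsoid"
    center_frac: tuple[float, float, float]
    half_size_mm: tuple[float, float, float]
    suv_mean: float
    suv_sd: float

    def mask(self, grid_shape: tuple[int, int, int],
             spacing: tuple[float, float, float]) -> np.ndarray:
        centre = np.array(self.center_frac) * (np.array(grid_shape) - 1)
        coords = np.indices(grid_shape, dtype=float)
        d = [(coords[a] - centre[a]) * spacing[a] / self.half_size_mm[a]
             for a in range(3)]
        if self.shape == "box":
            return (np.abs(d[0]) <= 1) & (np.abs(d[1]) <= 1) & (np.abs(d[2]) <= 1)
        if self.shape == "ellipsoid":
            return d[0] ** 2 + d[1] ** 2 + d[2] ** 2 <= 1.0
        raise ConfigError(f"unknown compartment shape {self.shape!r}")


@dataclass
class PhantomConfig:
    """Geometry, compartments and lesion content of one synthetic scan."""

    grid_shape: tuple[int, int, int] = (48, 48, 72)
    spacing: tuple[float, float, float] = (3.18, 3.18, 5.0)
    background_suv: float = 0.5
    background_noise_sd: float = 0.05
    blood_pool: Compartment = field(default_factory=lambda: Compartment(
        "ellipsoid", (0.5, 0.5, 0.62), (12.0, 12.0, 45.0), 1.8, 0.2))
    liver: Compartment = field(default_factory=lambda: Compartment(
        "box", (0.33, 0.5, 0.375), (45.0, 55.0, 32.0), 2.2, 0.3))
    lesions: list[LesionSpec] | None = None
    sampling: LesionSamplingLaw = field(default_factory=LesionSamplingLaw)
    blur_fwhm_mm: float | None = None
    seed: int = 0
    max_placement_tries: int = 200

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ConfigError("voxel spacing must be positive on all axes")
        if any(n < 4 for n in self.grid_shape):
            raise ConfigError("grid too small")
        if self.background_noise_sd < 0:
            raise ConfigError("noise SD must be >= 0")

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def detection_threshold(self) -> float:
        """Nominal blood-pool threshold 2*mean + 2*SD of the configured law."""
        return 2.0 * self.blood_pool.suv_mean + 2.0 * self.blood_pool.suv_sd

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PhantomConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("blood_pool", "liver"):
            if key in raw and isinstance(raw[key], dict):
                c = raw[key]
                c["center_frac"] = tuple(c["center_frac"])
                c["half_size_mm"] = tuple(c["half_size_mm"])
                raw[key] = Compartment(**c)
        if raw.get("lesions"):
            raw["lesions"] = [LesionSpec(**(dict(l, center=tuple(l["center"]) if l.get("center") else None)))
                              for l in raw["lesions"]]
        if "sampling" in raw and isinstance(raw["sampling"], dict):
            s = raw["sampling"]
            if "volume_range_ml" in s:
                s["volume_range_ml"] = tuple(s["volume_range_ml"])
            raw["sampling"] = LesionSamplingLaw(**s)
        for key in ("grid_shape", "spacing"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class GroundTruthLesion:
    """One rendered lesion with its exact voxel-wise ground truth."""

    lesion_id: str
    organ: str
    body_part: str
    region: str
    subregion: str | None
    volume_ml: float              # realised: n_voxels * voxel volume
    requested_volume_ml: float
    suvmax: float
    classification: str
    center: tuple[int, int, int]
    voxels: np.ndarray            # (k, 3) int voxel indices


@dataclass
class PhantomResult:
    volume: SUVVolume
    masks: dict[str, np.ndarray]          # "blood_pool", "liver" boolean masks
    lesions: list[GroundTruthLesion]


# --------------------------------------------------------------------------
# phantom generation
# --------------------------------------------------------------------------

def _sphere_voxels(center: tuple[int, int, int], n_voxels: int,
                   grid_shape: tuple[int, int, int],
                   spacing: tuple[float, float, float]) -> np.ndarray | None:
    """The ``n_voxels`` in-grid voxels nearest ``center`` (mm metric).

    Deterministic tie-break by (distance, x, y, z).  Returns None when
    the ball would have to leave the grid (caller retries elsewhere).
    """
    # generous bounding half-widths from the equivalent-sphere radius
    vol_mm3 = n_voxels * float(np.prod(spacing))
    r_mm = (3.0 * vol_mm3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    half = [int(math.ceil((r_mm + 2 * spacing[a]) / spacing[a])) for a in range(3)]
    lo = [center[a] - half[a] for a in range(3)]
    hi = [center[a] + half[a] + 1 for a in range(3)]
    if any(lo[a] < 0 or hi[a] > grid_shape[a] for a in range(3)):
        return None
    ax = [np.arange(lo[a], hi[a]) for a in range(3)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    d2 = (((gx - center[0]) * spacing[0]) ** 2
          + ((gy - center[1]) * spacing[1]) ** 2
          + ((gz - center[2]) * spacing[2]) ** 2)
    flat = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    order = np.lexsort((flat[:, 2], flat[:, 1], flat[:, 0], d2.ravel()))
    if n_voxels > flat.shape[0]:
        return None
    return flat[order[:n_voxels]]


def _zone_bounds(organ: str, grid_shape: tuple[int, int, int]) -> list[tuple[int, int]]:
    f = ORGAN_ZONES[organ]
    return [(int(f[2 * a] * (grid_shape[a] - 1)),
             int(f[2 * a + 1] * (grid_shape[a] - 1))) for a in range(3)]


def _sample_lesions(cfg: PhantomConfig, rng: np.random.Generator,
                    liver_mean: float) -> list[LesionSpec]:
    law = cfg.sampling
    organs = list(law.organ_probs)
    probs = np.array([law.organ_probs[o] for o in organs], dtype=float)
    probs /= probs.sum()
    specs: list[LesionSpec] = []
    for cls, mean in (("suspicious", law.n_suspicious_mean),
                      ("unsuspicious", law.n_physiological_mean)):
        n = int(rng.poisson(mean))
        for i in range(n):
            organ = organs[rng.choice(len(organs), p=probs)]
            vol = float(np.clip(rng.lognormal(law.volume_log_mean, law.volume_log_sd),
                                *law.volume_range_ml))
            suv = float(max(rng.lognormal(law.suvmax_log_mean, law.suvmax_log_sd),
                            law.suvmax_min))
            if organ == "liver":
                # half-max contour must stay clear of liver parenchyma
                suv = max(suv, 3.0 * liver_mean)
            specs.append(LesionSpec(f"{cls[:4]}-{len(specs):03d}", organ, vol, suv, cls))
    return specs


def generate_phantom(config: PhantomConfig) -> PhantomResult:
    """Render one synthetic SUV volume with ground-truth lesions.

    Deterministic for a fixed ``config.seed``.  Lesion voxels carry the
    lesion's SUVmax exactly (noise-free) so that, before any optional
    blur, the regional maximum equals the requested SUVmax and the
    constructed volume is recoverable without quantisation slack.

    Raises
    ------
    PlacementError
        When a lesion cannot be placed collision-free within the
        configured number of tries.
    """
    rng = np.random.default_rng(config.seed)
    shape, spacing = tuple(config.grid_shape), tuple(config.spacing)
    vox_ml = config.voxel_volume_ml

    bp_mask = config.blood_pool.mask(shape, spacing)
    liver_mask = config.liver.mask(shape, spacing)
    if (bp_mask & liver_mask).any():
        raise ConfigError("blood-pool and liver compartments overlap")

    vol = np.full(shape, config.background_suv, dtype=np.float64)
    if config.background_noise_sd > 0:
        vol += rng.normal(0.0, config.background_noise_sd, shape)
    vol[bp_mask] = config.blood_pool.suv_mean
    if config.blood_pool.suv_sd > 0:
        vol[bp_mask] += rng.normal(0.0, config.blood_pool.suv_sd, int(bp_mask.sum()))
    vol[liver_mask] = config.liver.suv_mean
    if config.liver.suv_sd > 0:
        vol[liver_mask] += rng.normal(0.0, config.liver.suv_sd, int(liver_mask.sum()))
    np.clip(vol, 0.0, None, out=vol)

    specs = config.lesions
    if specs is None:
        specs = _sample_lesions(config, rng, config.liver.suv_mean)

    thr = config.detection_threshold
    for spec in specs:
        if spec.suvmax <= thr:
            raise ConfigError(
                f"lesion {spec.lesion_id}: SUVmax {spec.suvmax} is not above the "
                f"blood-pool detection threshold {thr:.2f}"
            )

    occupied = np.zeros(shape, dtype=bool)      # lesions placed so far
    forbidden_bp = bp_mask                      # no lesion may enter blood pool
    lesions: list[GroundTruthLesion] = []
    struct = np.ones((3, 3, 3), dtype=bool)

    for spec in specs:
        n_vox = max(1, int(math.ceil(spec.volume_ml / vox_ml)))
        bounds = _zone_bounds(spec.organ, shape)
        placed = None
        tries = config.max_placement_tries if spec.center is None else 1
        for _ in range(tries):
            if spec.center is not None:
                centre = spec.center
            else:
                centre = tuple(int(rng.integers(lo, hi + 1)) for lo, hi in bounds)
            vox = _sphere_voxels(centre, n_vox, shape, spacing)
            if vox is None:
                continue
            idx = tuple(vox.T)
            cand = np.zeros(shape, dtype=bool)
            cand[idx] = True
            # candidate plus a 1-voxel halo must stay clear of other lesions,
            # the blood pool, and (for extra-hepatic lesions) the liver
            halo = ndimage.binary_dilation(cand, structure=struct)
            clash = (halo & occupied).any() or (halo & forbidden_bp).any()
            if not clash and spec.organ != "liver":
                clash = (halo & liver_mask).any()
            if not clash:
                placed = (centre, vox, idx)
                break
        if placed is None:
            raise PlacementError(
                f"could not place lesion {spec.lesion_id} "
                f"({spec.volume_ml} ml in {spec.organ}) after {tries} tries"
            )
        centre, vox, idx = placed
        occupied[idx] = True
        vol[idx] = spec.suvmax
        body_part, region, subregion = ORGAN_TO_LABELS[spec.organ]
        lesions.append(GroundTruthLesion(
            lesion_id=spec.lesion_id, organ=spec.organ,
            body_part=body_part, region=region, subregion=subregion,
            volume_ml=n_vox * vox_ml, requested_volume_ml=spec.volume_ml,
            suvmax=spec.suvmax, classification=spec.classification,
            center=tuple(int(c) for c in centre), voxels=vox,
        ))

    if config.blur_fwhm_mm is not None:
        sigma_vox = [config.blur_fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0))) / s
                     for s in spacing]
        vol = ndimage.gaussian_filter(vol, sigma=sigma_vox)

    suv = SUVVolume(data=vol, spacing=spacing, patient_id=f"phantom-{config.seed}")
    return PhantomResult(volume=suv,
                         masks={"blood_pool": bp_mask, "liver": liver_mask},
                         lesions=lesions)


def lesions_to_table(lesions: list[GroundTruthLesion], patient_id: str) -> pd.DataFrame:
    """Ground-truth lesions as a lesion-table DataFrame (one reference read)."""
    rows = []
    for les in lesions:
        rows.append({
            "patient_id": patient_id,
            "focus_id": les.lesion_id,
            "classification": les.classification,
            "mtv_ml": les.volume_ml,
            "suvmax": les.suvmax,
            "body_part": les.body_part,
            "region": les.region,
            "subregion": les.subregion if les.subregion is not None else pd.NA,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# simulated detector
# --------------------------------------------------------------------------

@dataclass
class DetectorProfile:
    """Imperfect focus classifier emulating an automated PET read.

    The probability of flagging a truly suspicious focus is
    ``expit(intercept + slope_log_volume * ln(volume_ml) +
    slope_suvmax * SUVmax)``, non-decreasing in both size and uptake, so
    the simulated read preferentially misses small, faint lesions.
    Physiological foci are flagged suspicious at ``fp_rate``.
    Anatomical labels are replaced by a different random label of the
    same level with the configured confusion rate.
    """

    intercept: float = -3.0
    slope_log_volume: float = 1.2
    slope_suvmax: float = 0.35
    fp_rate: float = 0.02
    label_confusion: dict[str, float] = field(default_factory=lambda: {
        "body_part": 0.02, "region": 0.12, "subregion": 0.20})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.slope_log_volume < 0 or self.slope_suvmax < 0:
            raise ConfigError("sensitivity must be non-decreasing in volume and SUVmax")
        if not 0 <= self.fp_rate <= 1:
            raise ConfigError("fp_rate must lie in [0, 1]")
        for level, rate in self.label_confusion.items():
            if not 0 <= rate <= 1:
                raise ConfigError(f"label confusion rate for {level} outside [0, 1]")

    @classmethod
    def constant(cls, sensitivity: float, fp_rate: float = 0.0,
                 seed: int = 0, label_confusion: dict[str, float] | None = None
                 ) -> "DetectorProfile":
        """Volume/SUV-independent sensitivity (slopes zero)."""
        if not 0 <= sensitivity <= 1:
            raise ConfigError("sensitivity must lie in [0, 1]")
        eps = 1e-12
        icpt = float(logit(min(max(sensitivity, eps), 1 - eps)))
        return cls(intercept=icpt, slope_log_volume=0.0, slope_suvmax=0.0,
                   fp_rate=fp_rate, seed=seed,
                   label_confusion=label_confusion or
                   {"body_part": 0.0, "region": 0.0, "subregion": 0.0})

    def sensitivity(self, volume_ml, suvmax) -> np.ndarray:
        """Per-focus detection probability for suspicious foci."""
        v = np.maximum(np.asarray(volume_ml, dtype=float), 1e-9)
        return expit(self.intercept + self.slope_log_volume * np.log(v)
                     + self.slope_suvmax * np.asarray(suvmax, dtype=float))


def simulate_detector(reference: pd.DataFrame, profile: DetectorProfile) -> pd.DataFrame:
    """Produce a candidate read of a reference lesion table.

    Returns a copy of ``reference`` whose ``classification`` column holds
    the simulated read and whose anatomical labels carry the configured
    confusion.  Deterministic for a fixed ``profile.seed``.
    """
    from .anatomy import BODY_PARTS, REGIONS, SUBREGIONS

    rng = np.random.default_rng(profile.seed)
    out = reference.copy(deep=True)
    vol_col = "mtv_ml" if "mtv_ml" in out.columns else "volume_ml"
    susp = (out["classification"] == "suspicious").to_numpy()
    p = np.where(susp,
                 profile.sensitivity(out[vol_col].to_numpy(float),
                                     out["suvmax"].to_numpy(float)),
                 profile.fp_rate)
    flagged = rng.random(len(out)) < p
    out["classification"] = np.where(flagged, "suspicious", "unsuspicious")

    vocab = {"body_part": BODY_PARTS, "region": REGIONS, "subregion": SUBREGIONS}
    for level, rate in profile.label_confusion.items():
        if level not in out.columns or rate <= 0:
            continue
        labels = out[level].to_numpy(object)
        corrupt = rng.random(len(out)) < rate
        for i in np.flatnonzero(corrupt):
            if pd.isna(labels[i]):
                continue  # absent labels stay absent
            alternatives = [w for w in vocab[level] if w != labels[i]]
            labels[i] = alternatives[rng.integers(len(alternatives))]
        out[level] = labels
    return out


# --------------------------------------------------------------------------
# survival cohorts
# --------------------------------------------------------------------------

@dataclass
class OrganMTVLaw:
    """Zero-inflated log-normal law for one organ's per-patient MTV (ml)."""

    p_zero: float
    log_mean: float
    log_sd: float

    def __post_init__(self) -> None:
        if not 0 <= self.p_zero <= 1:
            raise ConfigError("zero-inflation probability outside [0, 1]")
        if self.log_sd < 0:
            raise ConfigError("log-normal SD must be >= 0")


def _default_mtv_laws() -> dict[str, OrganMTVLaw]:
    return {
        "bone": OrganMTVLaw(0.40, math.log(8.0), 1.3),
        "lymph node": OrganMTVLaw(0.30, math.log(8.0), 1.3),
        "liver": OrganMTVLaw(0.60, math.log(9.0), 1.3),
        "lung": OrganMTVLaw(0.60, math.log(6.0), 1.3),
        "soft tissue": OrganMTVLaw(0.50, math.log(4.5), 1.3),
    }


@dataclass
class CohortConfig:
    """Survival-cohort generator: organ MTV laws and a true Cox model.

    ``beta`` holds the true log hazard ratios per unit of
    log2(MTV + 1 ml); event times are exponential with rate
    ``baseline_hazard * exp(sum_k beta_k * log2(MTV_k + 1))`` and are
    administratively censored at ``censoring_horizon_months``.
    """

    n_patients: int = 50
    mtv_laws: dict[str, OrganMTVLaw] = field(default_factory=_default_mtv_laws)
    beta: dict[str, float] = field(default_factory=lambda: {
        "liver": 0.16, "lymph node": 0.24})
    baseline_hazard: float = 0.008           # events per month at MTV = 0
    censoring_horizon_months: float = 84.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline hazard must be > 0")
        if self.censoring_horizon_months <= 0:
            raise ConfigError("censoring horizon must be > 0")
        unknown = set(self.beta) - set(self.mtv_laws) - {"whole_body"}
        if unknown:
            raise ConfigError(f"beta names without an MTV law: {sorted(unknown)}")


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic survival cohort from a known Cox model.

    Returns ``(mtv_table, survival_table)``.  The survival table carries
    raw (``mtv_<organ>``) and transformed (``log2_mtv_<organ>``)
    covariates plus ``mtv_whole_body`` / ``log2_mtv_whole_body``; its
    ``attrs['event_fraction']`` records the realised event fraction.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    organs = list(config.mtv_laws)

    mtv = {}
    for organ in organs:
        law = config.mtv_laws[organ]
        positive = rng.random(n) >= law.p_zero
        values = np.where(positive, rng.lognormal(law.log_mean, law.log_sd, n), 0.0)
        mtv[organ] = values
    mtv_df = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n)], **mtv})

    lp = np.zeros(n)
    for name, b in config.beta.items():
        covariate = (np.sum([mtv[o] for o in organs], axis=0)
                     if name == "whole_body" else mtv[name])
        lp += b * log2p1(covariate)
    rate = config.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    horizon = config.censoring_horizon_months
    event = (t_event <= horizon).astype(int)
    time = np.minimum(t_event, horizon)
    time = np.maximum(time, 1e-6)
    if event.sum() == 0:
        warnings.warn("all-censored cohort: no events before the horizon",
                      RuntimeWarning, stacklevel=2)

    surv = pd.DataFrame({
        "patient_id": mtv_df["patient_id"],
        "time_months": time,
        "event": event,
    })
    whole_body = np.sum([mtv[o] for o in organs], axis=0)
    surv["mtv_whole_body"] = whole_body
    surv["log2_mtv_whole_body"] = log2p1(whole_body)
    for organ in organs:
        key = organ.replace(" ", "_").replace("/", "_")
        surv[f"mtv_{key}"] = mtv[organ]
        surv[f"log2_mtv_{key}"] = log2p1(mtv[organ])
    surv.attrs["event_fraction"] = float(event.mean())
    return mtv_df, surv
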