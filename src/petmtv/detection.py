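"""Reference-standard FDG-focus quantification.

The pipeline mirrors a PERCIST-style semi-automated read:

1. a patient-specific detection threshold, 2*mean + 2*SD of the
   mediastinal blood-pool SUV;
2. connected-component extraction of supra-threshold voxels
   (26-connectivity by default), discarding foci smaller than 0.5 ml;
3. SUVpeak as the mean over a 1.0-ml sphere positioned (within the
   focus) to maximise that mean;
4. PERCIST measurability: SUVpeak strictly greater than
   2*mean + 2*SD of the liver SUV;
5. metabolic tumor volume by relative thresholding at 50% of the
   focus's local SUVmax, grown by connectivity from the maximum voxel;
6. whole-body and organ-wise MTV aggregation over suspicious foci.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .anatomy import organ_system, ORGAN_SYSTEMS
from .io import SUVVolume


@dataclass
class RegionStats:
    """Mean/SD summary of a reference region (blood pool or liver)."""

    mean: float
    sd: float
    n_voxels: int
    region: str = ""

    def __post_init__(self) -> None:
        if self.n_voxels < 1:
            raise ValueError("region must contain at least one voxel")
        if self.sd < 0:
            raise ValueError("SD must be >= 0")


@dataclass
class Focus:
    """One connected supra-threshold component and its quantification."""

    focus_id: str
    voxels: np.ndarray                    # (k, 3) detection-mask voxel indices
    suvmax: float
    suvpeak: float | None = None
    mtv_voxels: np.ndarray | None = None  # (m, 3) half-max mask
    mtv_ml: float | None = None
    measurable: bool | None = None
    classification: str | None = None
    body_part: str | None = None
    region: str | None = None
    subregion: str | None = None

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("connectivity must be 6 or 26")


def region_stats(volume: SUVVolume, mask: np.ndarray, region: str = "") -> RegionStats:
    """Mean and population SD (divisor N) of SUV over a reference mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask grid does not match the volume")
    values = volume.data[mask]
    if values.size == 0:
        raise ValueError("empty reference-region mask")
    return RegionStats(mean=float(values.mean()), sd=float(values.std(ddof=0)),
                       n_voxels=int(values.size), region=region)


def detection_threshold(stats: RegionStats) -> float:
    """Blood-pool detection threshold: 2*mean + 2*SD."""
    return 2.0 * stats.mean + 2.0 * stats.sd


def percist_threshold(liver_stats: RegionStats) -> float:
    """Liver measurability threshold: 2*mean + 2*SD."""
    return 2.0 * liver_stats.mean + 2.0 * liver_stats.sd


def percist_measurable(suvpeak: float, liver_stats: RegionStats) -> bool:
    """True iff SUVpeak strictly exceeds the liver threshold."""
    return suvpeak > percist_threshold(liver_stats)


def detect_foci(volume: SUVVolume, threshold: float,
                min_volume_ml: float = 0.5, connectivity: int = 26) -> list[Focus]:
    """Connected components of SUV > threshold, small foci dropped.

    The minimum-volume filter applies to the detection mask (voxel
    count times voxel volume); retained foci carry their SUVmax.
    """
    if threshold <= 0:
        raise ValueError("detection threshold must be > 0")
    supra = volume.data > threshold
    labels, n = ndimage.label(supra, structure=_structure(connectivity))
    foci: list[Focus] = []
    if n == 0:
        return foci
    vox_ml = volume.voxel_volume_ml
    min_count = min_volume_ml / vox_ml
    objects = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        where = np.argwhere(labels[sl] == lab)
        if where.shape[0] < min_count:
            continue
        where += np.array([s.start for s in sl])
        vals = volume.data[tuple(where.T)]
        foci.append(Focus(focus_id=f"f{len(foci):03d}", voxels=where,
                          suvmax=float(vals.max())))
    return foci


def _sphere_offsets(spacing: tuple[float, float, float],
                    sphere_volume_ml: float = 1.0) -> np.ndarray:
    """Voxel-centre offsets inside a sphere of the given volume."""
    r_mm = (3.0 * sphere_volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    half = [int(math.floor(r_mm / s)) for s in spacing]
    ax = [np.arange(-h, h + 1) for h in half]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    d2 = ((gx * spacing[0]) ** 2 + (gy * spacing[1]) ** 2 + (gz * spacing[2]) ** 2)
    keep = d2 <= r_mm ** 2
    return np.stack([gx[keep], gy[keep], gz[keep]], axis=1)


def suv_peak(volume: SUVVolume, focus: Focus,
             sphere_volume_ml: float = 1.0) -> float:
    """SUVpeak: maximal mean SUV over a 1.0-ml sphere centred in the focus.

    Sphere membership is decided by voxel-centre distance; candidate
    centres are the focus's own voxels.  For foci smaller than the
    sphere, the sphere extends into the surroundings (voxels outside
    the grid are excluded from the mean).
    """
    if focus.n_voxels == 0:
        raise ValueError("empty focus")
    offsets = _sphere_offsets(volume.spacing, sphere_volume_ml)
    shape = np.array(volume.shape)
    best = -np.inf
    for centre in focus.voxels:
        pts = centre[None, :] + offsets
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        vals = volume.data[tuple(pts[ok].T)]
        mean = float(vals.mean())
        if mean > best:
            best = mean
    return best


def segment_mtv(volume: SUVVolume, focus: Focus,
                connectivity: int = 26) -> tuple[np.ndarray, float]:
    """Half-max MTV mask: voxels >= 50% of the focus's local SUVmax,
    connected to the focus's maximum voxel.

    Returns ``(voxel indices, MTV in ml)``.  Seeding at the maximum
    voxel keeps adjacent structures that happen to exceed half-max but
    are not connected to this focus out of the mask.
    """
    if focus.suvmax <= 0:
        raise ValueError("focus SUVmax must be > 0")
    half = 0.5 * focus.suvmax
    above = volume.data >= half
    labels, _ = ndimage.label(above, structure=_structure(connectivity))
    vals = volume.data[tuple(focus.voxels.T)]
    seed = focus.voxels[int(np.argmax(vals))]
    lab = labels[tuple(seed)]
    vox = np.argwhere(labels == lab)
    return vox, vox.shape[0] * volume.voxel_volume_ml


def quantify_foci(volume: SUVVolume, blood_pool_mask: np.ndarray,
                  liver_mask: np.ndarray, min_volume_ml: float = 0.5,
                  connectivity: int = 26) -> tuple[list[Focus], dict]:
    """Full reference quantification of one volume.

    Runs threshold detection, SUVpeak, measurability and half-max MTV
    for every retained focus.  Returns the foci and a report dict with
    the thresholds used.
    """
    bp = region_stats(volume, blood_pool_mask, "blood pool")
    liver = region_stats(volume, liver_mask, "liver")
    thr = detection_threshold(bp)
    foci = detect_foci(volume, thr, min_volume_ml, connectivity)
    for focus in foci:
        focus.suvpeak = suv_peak(volume, focus)
        focus.measurable = percist_measurable(focus.suvpeak, liver)
        focus.mtv_voxels, focus.mtv_ml = segment_mtv(volume, focus, connectivity)
    report = {
        "blood_pool": {"mean": bp.mean, "sd": bp.sd, "n_voxels": bp.n_voxels},
        "liver": {"mean": liver.mean, "sd": liver.sd, "n_voxels": liver.n_voxels},
        "detection_threshold": thr,
        "percist_threshold": percist_threshold(liver),
        "n_foci": len(foci),
    }
    return foci, report


def foci_to_table(foci: list[Focus], patient_id: str) -> pd.DataFrame:
    """Quantified foci as a lesion-table DataFrame."""
    rows = []
    for f in foci:
        rows.append({
            "patient_id": patient_id,
            "focus_id": f.focus_id,
            "classification": f.classification if f.classification else "suspicious",
            "measurable": bool(f.measurable) if f.measurable is not None else True,
            "mtv_ml": f.mtv_ml,
            "suvmax": f.suvmax,
            "suvpeak": f.suvpeak,
            "body_part": f.body_part,
            "region": f.region,
            "subregion": f.subregion if f.subregion is not None else pd.NA,
        })
    return pd.DataFrame(rows)


def aggregate_mtv(lesions: pd.DataFrame, scope: str = "whole-body",
                  measurable_only: bool = False,
                  patients: list | None = None) -> pd.DataFrame:
    """Sum MTV over suspicious foci per patient.

    ``scope='whole-body'`` yields one ``mtv_total`` column;
    ``scope='per-organ'`` maps region labels onto the organ systems
    {bone, lymph node, liver, lung, soft tissue} and yields one column
    per system.  Patients without foci in scope (including any listed
    in ``patients``) get 0.
    """
    df = lesions
    if measurable_only:
        if "measurable" not in df.columns:
            raise ValueError("measurable_only requested but no 'measurable' column")
        df = df[df["measurable"].astype(bool)]
    df = df[df["classification"] == "suspicious"]

    index = pd.Index(sorted(set(lesions["patient_id"]) | set(patients or [])),
                     name="patient_id")
    if scope == "whole-body":
        totals = df.groupby("patient_id")["mtv_ml"].sum()
        out = totals.reindex(index, fill_value=0.0).to_frame("mtv_total")
    elif scope == "per-organ":
        df = df.assign(organ=[organ_system(r) for r in df["region"]])
        pivot = df.pivot_table(index="patient_id", columns="organ",
                               values="mtv_ml", aggfunc="sum", fill_value=0.0)
        out = pivot.reindex(index=index, columns=list(ORGAN_SYSTEMS),
                            fill_value=0.0)
        out.columns = [f"mtv_{c.replace(' ', '_')}" for c in out.columns]
    else:
        raise ValueError("scope must be 'whole-body' or 'per-organ'")
    return out.reset_index()
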