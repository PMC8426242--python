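"""Closed anatomical vocabulary and organ-system mapping.

Foci are localised at up to three granularities: *body part* (always
present), *region* (always present, usually an organ) and *subregion*
(optional; e.g. a specific bone or lymph-node level).  The "most
detailed" classification of a focus is its subregion when one exists
and its region otherwise.

Organ-wise tumor-volume aggregation maps regions onto five organ
systems (bone, lymph node, liver, lung, soft tissue); the breast /
pectoral region is additionally singled out for primary-tumor
sub-analyses.
"""

from __future__ import annotations

BODY_PARTS: tuple[str, ...] = (
    "cranium",
    "neck",
    "thorax",
    "abdomen",
    "upper limb",
    "lower limb",
)

REGIONS: tuple[str, ...] = (
    "brain",
    "esophagus",
    "lung",
    "pleura",
    "heart",
    "thymus",
    "mediastinum",
    "bones",
    "skin",
    "muscles",
    "breast",
    "liver",
    "spleen",
    "bowel",
    "lymph nodes",
)

SUBREGIONS: tuple[str, ...] = (
    "scapula",
    "sternum",
    "spine",
    "rib",
    "pelvis",
    "femur",
    "humerus",
    "pectoral muscle",
    "cervical lymph nodes",
    "axillary lymph nodes",
    "mediastinal lymph nodes",
    "mesenteric lymph nodes",
    "inguinal lymph nodes",
)

#: organ systems used for organ-wise MTV aggregation
ORGAN_SYSTEMS: tuple[str, ...] = (
    "bone",
    "lymph node",
    "liver",
    "lung",
    "soft tissue",
)

#: region label -> organ system
REGION_TO_SYSTEM: dict[str, str] = {
    "bones": "bone",
    "lymph nodes": "lymph node",
    "mediastinum": "lymph node",
    "liver": "liver",
    "lung": "lung",
    "pleura": "lung",
    "brain": "soft tissue",
    "esophagus": "soft tissue",
    "heart": "soft tissue",
    "thymus": "soft tissue",
    "skin": "soft tissue",
    "muscles": "soft tissue",
    "breast": "soft tissue",
    "spleen": "soft tissue",
    "bowel": "soft tissue",
}

#: simulated lesion habitats: organ -> (body part, region, subregion or None)
ORGAN_TO_LABELS: dict[str, tuple[str, str, str | None]] = {
    "bone": ("thorax", "bones", "spine"),
    "lymph node": ("thorax", "lymph nodes", "axillary lymph nodes"),
    "liver": ("abdomen", "liver", None),
    "lung": ("thorax", "lung", None),
    "soft tissue": ("abdomen", "muscles", None),
    "breast/pectoral": ("thorax", "breast", "pectoral muscle"),
}


class VocabularyError(ValueError):
    """An anatomical label outside the closed vocabulary."""


def validate_labels(body_part: str, region: str, subregion: str | None) -> None:
    """Check one focus's label triple against the closed vocabulary."""
    if body_part not in BODY_PARTS:
        raise VocabularyError(f"unknown body part: {body_part!r}")
    if region not in REGIONS:
        raise VocabularyError(f"unknown region: {region!r}")
    if subregion is not None and subregion not in SUBREGIONS:
        raise VocabularyError(f"unknown subregion: {subregion!r}")


def organ_system(region: str) -> str:
    """Map a region label to its organ system for MTV aggregation."""
    try:
        return REGION_TO_SYSTEM[region]
    except KeyError:
        raise VocabularyError(
            f"region {region!r} has no organ-system mapping"
        ) from None
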