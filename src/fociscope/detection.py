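"""RNA focus calling: size-gated bright speckles inside nuclei.

Foci are bright speckles whose equivalent diameter lies within a
region-specific pixel gate (1-11 px in frontal cortex, 1-10 px in
cerebellum) and whose centroid falls inside a segmented nucleus.
Supra-threshold objects larger than the gate are too big to be foci and
are masked from analysis; in-gate speckles outside every nucleus are
discarded.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology

from .segmentation import NucleusRecord

__all__ = [
    "DetectionParams",
    "FocusRecord",
    "enhance_speckles",
    "detect_foci",
    "count_per_nucleus",
    "GATE_BY_REGION",
]

# region -> (min, max) equivalent-diameter gate in pixels
GATE_BY_REGION = {
    "frontal_cortex": (1, 11),
    "cerebellum": (1, 10),
}


@dataclasses.dataclass(frozen=True)
class DetectionParams:
    region: str = "frontal_cortex"
    diameter_gate_px: tuple | None = None  # defaults to the region gate
    speckle_k: float = 5.0  # threshold = mean + k*SD inside the nucleus region
    min_threshold: float = 0.05  # absolute response floor
    mask_margin_px: int = 2

    def __post_init__(self) -> None:
        if self.region not in GATE_BY_REGION:
            raise ValueError(f"unknown region {self.region!r}")
        lo, hi = self.gate
        if lo < 1 or hi < lo:
            raise ValueError("diameter gate must satisfy 1 <= min <= max")
        if self.mask_margin_px < 0:
            raise ValueError("mask_margin_px must be nonnegative")

    @property
    def gate(self) -> tuple:
        return self.diameter_gate_px or GATE_BY_REGION[self.region]


@dataclasses.dataclass
class FocusRecord:
    """One called RNA focus, owned by a nucleus."""

    focus_id: int
    nucleus_id: int
    centroid: tuple  # (row, col)
    equivalent_diameter_px: float
    peak_intensity: float
    probe: str

    def __post_init__(self) -> None:
        if self.equivalent_diameter_px < 1.0:
            raise ValueError("focus diameter below 1 px")
        if not (0 <= self.peak_intensity <= 1):
            raise ValueError("peak_intensity must lie in [0, 1]")


def enhance_speckles(probe_image: np.ndarray, max_diameter_px: float) -> np.ndarray:
    """White top-hat with a disk element slightly larger than the gate max.

    Flat or smoothly varying backgrounds map to approximately zero while
    speckles up to ``max_diameter_px`` survive.
    """
    img = np.asarray(probe_image, dtype=np.float64)
    radius = int(np.ceil(max_diameter_px / 2.0)) + 1
    return morphology.white_tophat(img, footprint=morphology.disk(radius))


def _oversized_bright_objects(raw: np.ndarray, max_diameter: float) -> tuple:
    """Mask of supra-threshold raw-image objects larger than the gate.

    The speckle enhancement flattens large bright structures, so objects
    too big to be foci must be found on the raw probe image; Otsu
    separates bright structure from background.
    """
    from skimage import filters

    if raw.max() <= raw.min():
        return np.zeros(raw.shape, dtype=bool), 0
    thr = filters.threshold_otsu(raw)
    labels = measure.label(raw > thr, connectivity=2)
    mask = np.zeros(raw.shape, dtype=bool)
    count = 0
    for comp in measure.regionprops(labels):
        if comp.equivalent_diameter_area > max_diameter:
            mask[labels == comp.label] = True
            count += 1
    return mask, count


def detect_foci(
    response: np.ndarray,
    nucleus_label_map: np.ndarray,
    params: DetectionParams = DetectionParams(),
    probe: str = "sense",
    raw_image: np.ndarray | None = None,
) -> tuple:
    """Call foci on a speckle-enhanced response image.

    Thresholds the response at ``max(mean + k*SD, min_threshold)``
    computed over the dilated nucleus region, labels connected
    components, and keeps components whose equivalent diameter lies
    inside the gate and whose centroid falls in a nucleus.  Components
    above the gate maximum are counted as masked objects, as are
    oversized bright objects found on ``raw_image`` (when supplied);
    pixels of masked objects are excluded from focus calling.  In-gate
    components outside every nucleus are dropped.

    Returns ``(focus_records, masked_object_count)``.
    """
    response = np.asarray(response, dtype=np.float64)
    if response.shape != nucleus_label_map.shape:
        raise ValueError("response and label map shapes differ")
    lo, hi = params.gate

    region_mask = nucleus_label_map > 0
    if params.mask_margin_px > 0:
        region_mask = ndimage.binary_dilation(
            region_mask, morphology.disk(params.mask_margin_px)
        )
    if not region_mask.any():
        return [], 0
    vals = response[region_mask]
    threshold = max(
        float(vals.mean() + params.speckle_k * vals.std()), params.min_threshold
    )

    if raw_image is not None:
        excluded, masked = _oversized_bright_objects(
            np.asarray(raw_image, dtype=np.float64), hi
        )
    else:
        excluded = np.zeros(response.shape, dtype=bool)
        masked = 0

    binary = response > threshold
    labels = measure.label(binary, connectivity=2)

    foci: list[FocusRecord] = []
    focus_id = 1
    for comp in measure.regionprops(labels, intensity_image=response):
        d = comp.equivalent_diameter_area
        r, c = comp.centroid
        on_excluded = excluded[int(round(r)), int(round(c))]
        if d > hi:
            if not on_excluded:  # not already counted via the raw image
                masked += 1
            continue
        if d < lo or on_excluded:
            continue
        owner = int(nucleus_label_map[int(round(r)), int(round(c))])
        if owner == 0:
            continue
        foci.append(
            FocusRecord(
                focus_id=focus_id,
                nucleus_id=owner,
                centroid=(float(r), float(c)),
                equivalent_diameter_px=float(max(d, 1.0)),
                peak_intensity=float(np.clip(comp.intensity_max, 0.0, 1.0)),
                probe=probe,
            )
        )
        focus_id += 1
    return foci, masked


def count_per_nucleus(
    foci: Iterable[FocusRecord],
    nuclei: Sequence[NucleusRecord],
) -> pd.DataFrame:
    """Per-nucleus focus counts, including zero-count nuclei.

    The sum of counts equals the number of focus records; a focus owned
    by an unknown nucleus is a consistency error.  A nucleus carrying a
    manual count override uses that count instead of the automated one.
    """
    ids = [rec.nucleus_id for rec in nuclei]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate nucleus ids")
    counts = {nid: 0 for nid in ids}
    for focus in foci:
        if focus.nucleus_id not in counts:
            raise ValueError(
                f"focus {focus.focus_id} owned by unknown nucleus {focus.nucleus_id}"
            )
        counts[focus.nucleus_id] += 1
    rows = []
    for rec in nuclei:
        n = counts[rec.nucleus_id]
        if rec.manual_foci_count is not None:
            n = rec.manual_foci_count
        rows.append(dict(nucleus_id=rec.nucleus_id, foci_count=n))
    return pd.DataFrame(rows, columns=["nucleus_id", "foci_count"])
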