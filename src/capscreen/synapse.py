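"""Pre-/postsynaptic puncta quantification in a fixed ROI at the HM.

Per hemisegment, a square 400 um^2 region of interest centred on the
horizontal myoseptum is background-subtracted (morphological top-hat),
thresholded at 30 % of its maximum, and 8-connected components at least
``min_size_px`` pixels large are counted as puncta.  The pre/post overlap
(the synaptic area proper) is the conjunction of both binary masks.  Values
from four to five hemisegments are averaged per embryo.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from skimage.measure import label as cc_label

from .geometry import EmbryoGeometry

__all__ = ["PunctaStats", "SynapseMeasurement", "MeasureParams",
           "extract_roi", "subtract_background", "binarize",
           "quantify_puncta", "overlap_stats", "measure_embryo"]

ROI_SIDE_UM = 20.0   # square root of the 400 um^2 region of interest


@dataclass(frozen=True)
class PunctaStats:
    """Puncta summary of one channel in one ROI (or averaged per embryo)."""

    puncta_count: float
    total_area_um2: float
    mean_intensity: float    # NaN when no puncta

    @classmethod
    def empty(cls) -> "PunctaStats":
        return cls(0.0, 0.0, float("nan"))


@dataclass
class SynapseMeasurement:
    """Per-embryo averaged puncta statistics."""

    pre: PunctaStats
    post: PunctaStats
    overlap: PunctaStats
    n_hemisegments: int
    usable: bool = True


@dataclass(frozen=True)
class MeasureParams:
    """Tunable parameters of the puncta pipeline."""

    threshold_fraction: float = 0.30
    background_radius_um: float = 10.0
    min_size_px: int = 2
    hemisegments: tuple[int, ...] = (2, 3, 4, 5, 6)
    intensity_on: str = "subtracted"     # or "raw"

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.intensity_on not in ("subtracted", "raw"):
            raise ValueError("intensity_on must be 'subtracted' or 'raw'")


def extract_roi(channel: np.ndarray, geometry: EmbryoGeometry,
                hemisegment: int) -> np.ndarray:
    """Square ROI of side 20 um centred on (hm_row, hemisegment centre)."""
    side = int(round(ROI_SIDE_UM / geometry.pixel_size))
    ccol = geometry.exit_cols[hemisegment]
    half = side // 2
    r0, c0 = geometry.hm_row - half, ccol - half
    r1, c1 = r0 + side, c0 + side
    if r0 < 0 or c0 < 0 or r1 > channel.shape[0] or c1 > channel.shape[1]:
        raise ValueError(
            f"ROI rows {r0}:{r1} cols {c0}:{c1} exceed image {channel.shape}")
    return channel[r0:r1, c0:c1]


def subtract_background(roi: np.ndarray, radius_um: float = 10.0,
                        pixel_size: float = 1.0) -> np.ndarray:
    """Morphological top-hat: ROI minus its grayscale opening with a disk.

    Removes smooth background (a rolling-ball analogue) while preserving
    puncta much smaller than the disk; output is clipped at zero.
    """
    if radius_um <= 0:
        raise ValueError("background radius must be positive")
    radius_px = max(1, int(round(radius_um / pixel_size)))
    opened = ndimage.grey_opening(roi, footprint=disk(radius_px))
    return np.clip(roi - opened, 0.0, None)


def binarize(roi: np.ndarray, fraction: float = 0.30) -> np.ndarray:
    """Foreground where value >= fraction x max(roi); all-zero ROI -> empty."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("threshold fraction must be in (0, 1)")
    peak = float(roi.max())
    if peak <= 0:
        return np.zeros(roi.shape, dtype=bool)
    return roi >= fraction * peak


def quantify_puncta(mask: np.ndarray, roi: np.ndarray, pixel_size: float,
                    min_size_px: int = 2) -> PunctaStats:
    """Count 8-connected components of at least ``min_size_px`` pixels.

    ``total_area_um2`` is the retained foreground pixel count times the
    pixel area; ``mean_intensity`` is the mean of ``roi`` over punctum
    pixels (NaN when there are none).
    """
    if mask.shape != roi.shape:
        raise ValueError(f"mask {mask.shape} and roi {roi.shape} differ")
    labels = cc_label(mask, connectivity=2)
    if labels.max() == 0:
        return PunctaStats.empty()
    sizes = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(sizes >= min_size_px) + 1
    if keep.size == 0:
        return PunctaStats.empty()
    punctum = np.isin(labels, keep)
    area = float(punctum.sum()) * pixel_size ** 2
    return PunctaStats(puncta_count=float(keep.size), total_area_um2=area,
                       mean_intensity=float(roi[punctum].mean()))


def overlap_stats(pre_mask: np.ndarray, post_mask: np.ndarray,
                  pre_roi: np.ndarray, pixel_size: float,
                  min_size_px: int = 2) -> PunctaStats:
    """Puncta statistics of the pre AND post conjunction mask."""
    if pre_mask.shape != post_mask.shape:
        raise ValueError("pre and post masks must be congruent")
    return quantify_puncta(pre_mask & post_mask, pre_roi, pixel_size,
                           min_size_px)


def _average(stats: list[PunctaStats]) -> PunctaStats:
    counts = [s.puncta_count for s in stats]
    areas = [s.total_area_um2 for s in stats]
    intens = [s.mean_intensity for s in stats
              if not math.isnan(s.mean_intensity)]
    return PunctaStats(
        puncta_count=float(np.mean(counts)),
        total_area_um2=float(np.mean(areas)),
        mean_intensity=float(np.mean(intens)) if intens else float("nan"),
    )


def measure_embryo(image: np.ndarray, geometry: EmbryoGeometry,
                   params: MeasureParams | None = None) -> SynapseMeasurement:
    """Run the full puncta chain on one embryo and average per embryo.

    ``image`` is the (3, rows, cols) stack; channels 1 and 2 hold the pre-
    and postsynaptic labels.  Hemisegments whose ROI does not fit inside the
    image are skipped; embryos with fewer than four valid hemisegments are
    returned with ``usable=False``.
    """
    params = params or MeasureParams()
    per_hemi: dict[str, list[PunctaStats]] = {"pre": [], "post": [],
                                              "overlap": []}
    n_valid = 0
    for h in params.hemisegments:
        try:
            rois = {"pre": extract_roi(image[1], geometry, h),
                    "post": extract_roi(image[2], geometry, h)}
        except ValueError:
            continue
        n_valid += 1
        corrected = {k: subtract_background(v, params.background_radius_um,
                                            geometry.pixel_size)
                     for k, v in rois.items()}
        masks = {k: binarize(v, params.threshold_fraction)
                 for k, v in corrected.items()}
        meas_img = corrected if params.intensity_on == "subtracted" else rois
        for k in ("pre", "post"):
            per_hemi[k].append(quantify_puncta(
                masks[k], meas_img[k], geometry.pixel_size,
                params.min_size_px))
        per_hemi["overlap"].append(overlap_stats(
            masks["pre"], masks["post"], meas_img["pre"],
            geometry.pixel_size, params.min_size_px))

    usable = n_valid >= 4
    empty = PunctaStats.empty()
    return SynapseMeasurement(
        pre=_average(per_hemi["pre"]) if usable else empty,
        post=_average(per_hemi["post"]) if usable else empty,
        overlap=_average(per_hemi["overlap"]) if usable else empty,
        n_hemisegments=n_valid, usable=usable,
    )
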