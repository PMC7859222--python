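"""Puncta detection: LoG filtering, thresholding, labelling, cell assignment.

MVE (CD63) and miRNA puncta are detected by a scale-normalised
Laplacian-of-Gaussian filter tuned to the expected physical diameter,
followed by a global threshold on the filter response and connected-
component labelling.  Intensity statistics are measured on the original
image.  Spots are assigned to cells by the cell label under their
centroid, so each spot belongs to exactly one cell.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .core import CellMap, Spot, SpotSet, require_same_shape


def log_sigma_px(expected_diameter_nm: float, pixel_size_nm: float) -> float:
    """LoG scale for a blob of the given diameter.

    sigma = d / (2*sqrt(2)) places the LoG zero-crossing at the blob
    radius (the standard blob-scale relation).
    """
    return expected_diameter_nm / (2.0 * math.sqrt(2.0) * pixel_size_nm)


def _log_dc_gain(sigma_px: float) -> float:
    """Response of the discrete LoG operator to a unit constant.

    The truncated Gaussian-derivative kernel does not sum exactly to
    zero; subtracting this gain restores the true LoG's zero DC response
    so constant images map to (numerically) exact zero.
    """
    half = int(4.0 * sigma_px + 0.5)
    size = 2 * (2 * half) + 1
    probe = ndi.gaussian_laplace(np.ones((size, size)), sigma_px)
    return float(probe[size // 2, size // 2])


def log_filter(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Negated, sigma^2-normalised Laplacian-of-Gaussian response.

    Bright blobs of radius ~ sigma*sqrt(2) give positive peaks; the
    sigma^2 factor makes peak height scale-invariant.  Linear in the
    input, and exactly zero on constant images (the discrete operator's
    small DC gain is subtracted).
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    img = np.asarray(image, dtype=np.float64)
    resp = ndi.gaussian_laplace(img, sigma_px) - _log_dc_gain(sigma_px) * img
    return -(sigma_px ** 2) * resp


def detect_puncta(image: np.ndarray, expected_diameter_nm: float,
                  pixel_size_nm: float, threshold_method: str = "otsu",
                  min_area_px: int = 1, max_area_px: int | None = None,
                  threshold_value: float | None = None,
                  channel_role: str = "") -> SpotSet:
    """Detect puncta of a given physical size in a 2D image.

    The LoG response is thresholded (Otsu over the positive response
    values by default; ``>=`` comparison so ties resolve toward the lower
    threshold), 8-connected components are labelled, area-filtered, and
    measured on the original image.  An image with no positive response
    yields an empty SpotSet.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if expected_diameter_nm < pixel_size_nm:
        raise ValueError("expected diameter must be at least one pixel")
    sigma = log_sigma_px(expected_diameter_nm, pixel_size_nm)
    resp = log_filter(img, sigma)

    positive = resp[resp > 0]
    empty = SpotSet(channel_role=channel_role, spots=[],
                    label_image=np.zeros(img.shape, dtype=np.int32))
    if positive.size == 0:
        return empty
    if threshold_method == "otsu":
        if np.ptp(positive) == 0:
            thr = float(positive[0])
        else:
            thr = float(threshold_otsu(positive))
    elif threshold_method == "fixed":
        if threshold_value is None:
            raise ValueError("fixed threshold requires a value")
        thr = float(threshold_value)
    elif threshold_method == "percentile":
        if threshold_value is None:
            raise ValueError("percentile threshold requires a value")
        thr = float(np.percentile(positive, threshold_value))
    else:
        raise ValueError(f"unknown threshold method: {threshold_method!r}")

    mask = resp >= thr
    labels = cc_label(mask, connectivity=2)
    if labels.max() == 0:
        return empty

    out_labels = np.zeros(img.shape, dtype=np.int32)
    spots: list[Spot] = []
    next_id = 0
    for prop in regionprops(labels, intensity_image=img):
        area = int(prop.area)
        if area < min_area_px:
            continue
        if max_area_px is not None and area > max_area_px:
            continue
        next_id += 1
        out_labels[labels == prop.label] = next_id
        total = float(prop.intensity_mean) * area
        # weighted centroid undefined for zero-intensity components
        centroid = prop.centroid_weighted if total > 0 else prop.centroid
        spots.append(Spot(
            label=next_id,
            centroid=tuple(float(c) for c in centroid),
            area_px=area,
            mean_intensity=float(prop.intensity_mean),
            total_intensity=total,
            equivalent_diameter_px=2.0 * math.sqrt(area / math.pi),
        ))
    return SpotSet(channel_role=channel_role, spots=spots, label_image=out_labels)


def estimate_multiplicity(spot_set: SpotSet) -> dict[int, int]:
    """Estimate how many unresolved puncta each detected object contains.

    Puncta closer than the optical resolution merge into one connected
    component, but integrated intensity is additive, so an object's flux
    in units of the typical single-spot flux counts its constituents.
    The unit is the median object flux (robust as long as most objects
    are single spots); each weight is ``max(1, round(flux / unit))``.
    """
    totals = np.array([s.total_intensity for s in spot_set.spots])
    if totals.size == 0:
        return {}
    unit = float(np.median(totals))
    if unit <= 0:
        return {s.label: 1 for s in spot_set.spots}
    return {s.label: max(1, int(round(s.total_intensity / unit)))
            for s in spot_set.spots}


def spot_mask(spot_set: SpotSet) -> np.ndarray:
    """Union of all retained spot pixels (input to the AND gate)."""
    return spot_set.source_mask.copy()


def assign_spots_to_cells(spot_set: SpotSet, cell_map: CellMap,
                          policy: str = "centroid") -> SpotSet:
    """Assign each spot the cell label under its centroid.

    Spots on background or inside border-touching cells get ``cell_id
    None`` and are excluded from per-cell summaries downstream.  Returns
    a new SpotSet; the input is not modified.
    """
    if policy != "centroid":
        raise ValueError(f"unknown assignment policy: {policy!r}")
    require_same_shape(spot_set.label_image, cell_map.cell_labels)
    h, w = cell_map.shape
    out: list[Spot] = []
    for s in spot_set.spots:
        r = min(max(int(round(s.centroid[0])), 0), h - 1)
        c = min(max(int(round(s.centroid[1])), 0), w - 1)
        cid = int(cell_map.cell_labels[r, c])
        if cid == 0 or cid in cell_map.border_touching:
            cid = None
        out.append(Spot(label=s.label, centroid=s.centroid, area_px=s.area_px,
                        mean_intensity=s.mean_intensity,
                        total_intensity=s.total_intensity,
                        equivalent_diameter_px=s.equivalent_diameter_px,
                        cell_id=cid))
    return SpotSet(channel_role=spot_set.channel_role, spots=out,
                   label_image=spot_set.label_image.copy())
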