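"""Single-cell segmentation from nucleus and cytoplasm channels.

The scheme mirrors the imaging workflow the pipeline quantifies: a
maximum-intensity projection of the z-stack, nuclei from the Hoechst
channel (smooth, threshold, fill, distance-transform watershed to split
touching nuclei), then cell bodies from the evenly cytoplasmic Ago2
channel via a nucleus-seeded watershed.  Cells touching the image border
are flagged and excluded from all per-cell statistics.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import h_maxima
from skimage.segmentation import watershed

from .core import CellMap, ImageStack, Projection

logger = logging.getLogger(__name__)


def max_intensity_projection(stack: ImageStack) -> Projection:
    """Per-channel, per-pixel maximum over z."""
    if stack.data.size == 0 or stack.n_z < 1:
        raise ValueError("cannot project an empty stack")
    return Projection(
        data=stack.data.max(axis=1),
        channel_roles=dict(stack.channel_roles),
        pixel_size_nm=stack.pixel_size_nm,
    )


def _drop_small(labels: np.ndarray, min_area_px: int) -> np.ndarray:
    """Zero out labelled components with fewer than ``min_area_px`` pixels."""
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_area_px)
    out = labels.copy()
    out[np.isin(out, small[small > 0])] = 0
    return out


def _has_contrast(smoothed: np.ndarray, mask: np.ndarray,
                  min_separation: float = 4.0) -> bool:
    """True when the thresholded foreground is genuinely brighter than the
    background (mean separation > ``min_separation`` background SDs).

    Guards against pure-noise images, where a global threshold splits the
    noise distribution in half and hallucinates foreground.
    """
    fg = smoothed[mask]
    bg = smoothed[~mask]
    if fg.size == 0 or bg.size == 0:
        return fg.size > 0
    return float(fg.mean() - bg.mean()) > min_separation * float(bg.std())


def _threshold(values: np.ndarray, method: str, value: float | None) -> float:
    """Foreground threshold on a 1D sample of intensities."""
    if method == "otsu":
        return float(threshold_otsu(values))
    if method == "fixed":
        if value is None:
            raise ValueError("fixed threshold requires a value")
        return float(value)
    if method == "percentile":
        if value is None:
            raise ValueError("percentile threshold requires a value")
        return float(np.percentile(values, value))
    raise ValueError(f"unknown threshold method: {method!r}")


def segment_nuclei(nucleus_image: np.ndarray, smoothing_sigma_px: float = 2.0,
                   threshold_method: str = "otsu", min_area_px: int = 100,
                   threshold_value: float | None = None,
                   split_h: float = 4.0) -> np.ndarray:
    """Label nuclei in a 2D image.

    Smoothing -> global threshold -> hole filling -> distance-transform
    watershed (markers from h-maxima of the distance map, so an elongated
    nucleus keeps a single marker while touching nuclei split at their
    saddle) -> small-object removal.  Labels are consecutive from 1.
    ``split_h`` is the minimum depth (in distance-map pixels) of the
    saddle between two markers; it must exceed the boundary roughness of
    a single noisy nucleus yet stay below the saddle depth of genuinely
    touching nuclei.

    A constant image yields zero nuclei with a logged warning rather than
    an exception.
    """
    img = np.asarray(nucleus_image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if img.size == 0 or np.ptp(img) == 0:
        logger.warning("constant nucleus image: no nuclei segmented")
        return np.zeros(img.shape, dtype=np.int32)

    smoothed = ndi.gaussian_filter(img, smoothing_sigma_px) if smoothing_sigma_px > 0 else img
    thr = _threshold(smoothed.ravel(), threshold_method, threshold_value)
    mask = smoothed >= thr
    if threshold_method == "otsu" and not _has_contrast(smoothed, mask):
        logger.warning("no foreground/background contrast: no nuclei segmented")
        return np.zeros(img.shape, dtype=np.int32)
    mask = ndi.binary_fill_holes(mask)
    mask = _drop_small(cc_label(mask, connectivity=2), int(min_area_px)) > 0
    if not mask.any():
        logger.warning("no foreground above threshold: no nuclei segmented")
        return np.zeros(img.shape, dtype=np.int32)

    dist = ndi.distance_transform_edt(mask)
    # smooth the distance map and dilate the maxima so discretisation
    # plateaus yield a single marker; true saddles (depth >> split_h) keep
    # touching nuclei apart
    dist_s = ndi.gaussian_filter(dist, 1.0)
    peaks = ndi.binary_dilation(h_maxima(dist_s, split_h), iterations=2)
    markers = cc_label(peaks, connectivity=2)
    # guarantee one marker per connected foreground component
    comps = cc_label(mask, connectivity=2)
    for comp_id in range(1, comps.max() + 1):
        comp = comps == comp_id
        if not markers[comp].any():
            flat = np.argmax(np.where(comp, dist, -1.0))
            markers.flat[flat] = markers.max() + 1
    labels = watershed(-dist, markers=markers, mask=mask)
    labels = _drop_small(labels, int(min_area_px))

    # relabel consecutively
    out = np.zeros_like(labels, dtype=np.int32)
    for new_id, old_id in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old_id] = new_id
    return out


def segment_cells(cytoplasm_image: np.ndarray, nucleus_labels: np.ndarray,
                  smoothing_sigma_px: float = 2.0, threshold_method: str = "otsu",
                  threshold_value: float | None = None,
                  pixel_size_nm: float = 1.0) -> CellMap:
    """Partition the cytoplasm foreground into one cell per nucleus.

    The foreground mask (smoothed cytoplasm channel above threshold,
    union-ed with the nucleus masks) is split by a watershed seeded at the
    nuclei.  Nuclei without any surrounding cytoplasm are dropped; cells
    whose mask touches the image border are flagged ``border_touching``.
    Zero nuclei yield a valid empty CellMap.
    """
    img = np.asarray(cytoplasm_image, dtype=np.float64)
    nucleus_labels = np.asarray(nucleus_labels)
    if img.shape != nucleus_labels.shape:
        raise ValueError("cytoplasm image and nucleus labels differ in shape")
    empty = CellMap(
        nucleus_labels=np.zeros(img.shape, dtype=np.int32),
        cell_labels=np.zeros(img.shape, dtype=np.int32),
        pixel_size_nm=pixel_size_nm,
    )
    if nucleus_labels.max() == 0:
        return empty

    smoothed = ndi.gaussian_filter(img, smoothing_sigma_px) if smoothing_sigma_px > 0 else img
    if np.ptp(smoothed) == 0:
        fg = np.zeros(img.shape, dtype=bool)
    else:
        thr = _threshold(smoothed.ravel(), threshold_method, threshold_value)
        fg = smoothed >= thr
        if threshold_method == "otsu" and not _has_contrast(smoothed, fg):
            logger.warning("cytoplasm channel has no contrast; using nuclei only")
            fg = np.zeros(img.shape, dtype=bool)
    fg |= nucleus_labels > 0

    cells = watershed(-smoothed, markers=nucleus_labels.astype(np.int32), mask=fg)

    # drop cells with empty cytoplasm (cell mask identical to nucleus mask)
    keep: list[int] = []
    for cid in np.unique(cells[cells > 0]):
        if ((cells == cid) & (nucleus_labels != cid)).any():
            keep.append(int(cid))
        else:
            logger.warning("cell %d has no cytoplasm; dropped", cid)

    cell_out = np.zeros(img.shape, dtype=np.int32)
    nuc_out = np.zeros(img.shape, dtype=np.int32)
    border: set[int] = set()
    for new_id, old_id in enumerate(sorted(keep), start=1):
        cmask = cells == old_id
        cell_out[cmask] = new_id
        nuc_out[nucleus_labels == old_id] = new_id
        if (cmask[0, :].any() or cmask[-1, :].any()
                or cmask[:, 0].any() or cmask[:, -1].any()):
            border.add(new_id)
    return CellMap(nucleus_labels=nuc_out, cell_labels=cell_out,
                   pixel_size_nm=pixel_size_nm, border_touching=frozenset(border))


def cytoplasm_region(cell_map: CellMap, cell_id: int) -> np.ndarray:
    """Binary mask of a cell minus its nucleus (non-empty by construction)."""
    return cell_map.cell_mask(cell_id) & ~cell_map.nucleus_mask(cell_id)


def segment_field(projection: Projection, smoothing_sigma_px: float = 2.0,
                  threshold_method: str = "otsu", min_nucleus_area_px: int = 100) -> CellMap:
    """Convenience: nuclei then cells from a projected field."""
    nuclei = segment_nuclei(projection.channel("nucleus"),
                            smoothing_sigma_px=smoothing_sigma_px,
                            threshold_method=threshold_method,
                            min_area_px=min_nucleus_area_px)
    return segment_cells(projection.channel("cytoplasm"), nuclei,
                         smoothing_sigma_px=smoothing_sigma_px,
                         threshold_method=threshold_method,
                         pixel_size_nm=projection.pixel_size_nm)
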