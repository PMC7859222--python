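"""Object-based co-localization: AND-gate masks, per-cell counting,
MVE classification, nuclear-accumulation scoring, pixelwise Pearson r.

An object counts as co-localized with another channel when at least
``min_overlap_px`` of its pixels survive the AND gate of the two binary
masks.  Rates are reported per retained (non-border) cell; a cell with
no objects gets a missing rate, not zero, and is excluded from means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import CellMap, SpotSet, require_same_shape
from .segment import cytoplasm_region

logger = logging.getLogger(__name__)


def and_gate(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Pixelwise logical AND of two binary masks of equal shape."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    require_same_shape(a, b)
    return a & b


def _overlap_per_spot(spot_set: SpotSet, other_mask: np.ndarray) -> dict[int, int]:
    """Pixels of each spot surviving the AND gate with ``other_mask``."""
    gated = and_gate(spot_set.source_mask, other_mask)
    labels = spot_set.label_image
    counts = np.bincount(labels[gated].ravel(), minlength=labels.max() + 1)
    return {s.label: int(counts[s.label]) if s.label < len(counts) else 0
            for s in spot_set.spots}


def object_coloc_counts(spot_set: SpotSet, other_mask: np.ndarray,
                        cell_map: CellMap, min_overlap_px: int = 1,
                        weights: dict[int, int] | None = None) -> pd.DataFrame:
    """Per-cell object co-localization counts.

    For every retained cell: ``n_obj`` objects of ``spot_set`` assigned to
    it, ``n_coloc`` of them with >= ``min_overlap_px`` pixels inside the
    AND gate of the spot mask and ``other_mask``, and
    ``coloc_rate = n_coloc / n_obj`` (missing when ``n_obj`` = 0).

    ``weights`` (label -> multiplicity, e.g. from
    :func:`mircoloc.puncta.estimate_multiplicity`) counts each object that
    many times, correcting rates for unresolved merged puncta; without it
    every object counts once.
    """
    if min_overlap_px < 1:
        raise ValueError("min_overlap_px must be >= 1")
    require_same_shape(spot_set.label_image, cell_map.cell_labels)
    overlap = _overlap_per_spot(spot_set, other_mask)
    rows = []
    for cid in cell_map.retained_cell_ids:
        in_cell = [s for s in spot_set.spots if s.cell_id == cid]
        n_obj = n_coloc = 0
        for s in in_cell:
            w = 1 if weights is None else weights.get(s.label, 1)
            n_obj += w
            if overlap[s.label] >= min_overlap_px:
                n_coloc += w
        rows.append({
            "cell_id": cid,
            "n_obj": n_obj,
            "n_coloc": n_coloc,
            "coloc_rate": (n_coloc / n_obj) if n_obj > 0 else np.nan,
        })
    return pd.DataFrame(rows, columns=["cell_id", "n_obj", "n_coloc", "coloc_rate"])


def chance_overlap_probability(target_mask: np.ndarray, spot_radius_px: float,
                               region_mask: np.ndarray) -> float:
    """Probability that a randomly placed punctum overlaps ``target_mask``.

    A disk-shaped punctum of the given radius dropped uniformly in
    ``region_mask`` hits the target iff its centre falls inside the
    target dilated by the punctum radius; the returned value is that
    dilated area fraction.  Used to correct object co-localization rates
    for chance overlap (the object-level analogue of randomisation
    controls in pixel co-localization).
    """
    from scipy import ndimage as ndi

    region = np.asarray(region_mask, dtype=bool)
    denom = int(region.sum())
    if denom == 0:
        return float("nan")
    r = max(int(round(spot_radius_px)), 0)
    if r > 0:
        yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
        structure = (yy ** 2 + xx ** 2) <= r ** 2
        dilated = ndi.binary_dilation(target_mask, structure=structure)
    else:
        dilated = np.asarray(target_mask, dtype=bool)
    return float((dilated & region).sum()) / denom


def chance_corrected_rate(raw_rate: float, chance_p: float) -> float:
    """Excess-over-chance co-localization rate.

    ``(raw - chance) / (1 - chance)``, clipped to [0, 1]: the fraction of
    objects co-localized beyond what random placement already produces.
    """
    if not np.isfinite(raw_rate) or not np.isfinite(chance_p):
        return float("nan")
    if chance_p >= 1.0:
        return float("nan")
    return float(np.clip((raw_rate - chance_p) / (1.0 - chance_p), 0.0, 1.0))


@dataclass
class ColocPerCell:
    """Classification of a cell's sampled MVEs by miRNA co-localization.

    Four exclusive classes (single / guide-only / passenger-only / both)
    always sum to ``n_evaluated``; the 3-way projection used for
    reporting counts "both" MVEs in each positive class
    (``n_guide_pos = guide-only + both`` and likewise for passenger).
    """

    cell_id: int
    n_mve: int
    n_evaluated: int
    n_single: int
    n_guide_only: int
    n_passenger_only: int
    n_both: int

    @property
    def n_guide_pos(self) -> int:
        return self.n_guide_only + self.n_both

    @property
    def n_passenger_pos(self) -> int:
        return self.n_passenger_only + self.n_both

    @property
    def coloc_rate(self) -> float:
        """Fraction of evaluated MVEs co-localized with either strand."""
        if self.n_evaluated == 0:
            return float("nan")
        return 1.0 - self.n_single / self.n_evaluated


def classify_mves(mve_spots: SpotSet, guide_mask: np.ndarray,
                  passenger_mask: np.ndarray, cell_map: CellMap,
                  sample_n: int = 20, rng: np.random.Generator | None = None,
                  min_overlap_px: int = 1) -> list[ColocPerCell]:
    """Classify up to ``sample_n`` randomly sampled MVEs per cell.

    Per retained cell, min(sample_n, n_mve) MVEs are sampled without
    replacement (in spot-label order, so the draw is reproducible for a
    given seeded ``rng``), then each is placed in exactly one of
    {single, guide-only, passenger-only, both} by the AND-gate overlap
    rule against each miRNA mask.  ``sample_n=20`` matches the 20
    points/cell convention of the imaging protocol being reproduced.
    """
    if sample_n < 1:
        raise ValueError("sample_n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    g_overlap = _overlap_per_spot(mve_spots, guide_mask)
    p_overlap = _overlap_per_spot(mve_spots, passenger_mask)

    results: list[ColocPerCell] = []
    for cid in cell_map.retained_cell_ids:
        in_cell = sorted((s for s in mve_spots.spots if s.cell_id == cid),
                         key=lambda s: s.label)
        n_mve = len(in_cell)
        k = min(sample_n, n_mve)
        idx = rng.choice(n_mve, size=k, replace=False) if k else np.array([], int)
        single = gonly = ponly = both = 0
        for i in idx:
            s = in_cell[int(i)]
            g = g_overlap[s.label] >= min_overlap_px
            p = p_overlap[s.label] >= min_overlap_px
            if g and p:
                both += 1
            elif g:
                gonly += 1
            elif p:
                ponly += 1
            else:
                single += 1
        results.append(ColocPerCell(cell_id=cid, n_mve=n_mve, n_evaluated=k,
                                    n_single=single, n_guide_only=gonly,
                                    n_passenger_only=ponly, n_both=both))
    return results


def classification_table(results: list[ColocPerCell]) -> pd.DataFrame:
    df = pd.DataFrame([
        {
            "cell_id": r.cell_id, "n_mve": r.n_mve, "n_evaluated": r.n_evaluated,
            "n_single": r.n_single, "n_guide_only": r.n_guide_only,
            "n_passenger_only": r.n_passenger_only, "n_both": r.n_both,
            "n_guide_pos": r.n_guide_pos, "n_passenger_pos": r.n_passenger_pos,
            "coloc_rate": r.coloc_rate,
        }
        for r in results
    ])
    df.attrs["projection"] = "both-positive MVEs counted in each positive class"
    return df


@dataclass
class NuclearAccumulationResult:
    """Per-cell nuclear/cytoplasm intensity ratios and the field fraction."""

    per_cell: pd.DataFrame
    fraction_accumulated: float
    ratio_threshold: float


def nuclear_accumulation(mirna_image: np.ndarray, cell_map: CellMap,
                         ratio_threshold: float = 1.5) -> NuclearAccumulationResult:
    """Score cells whose miRNA signal accumulates in the nucleus.

    A cell is "accumulated" when its mean nuclear intensity is at least
    ``ratio_threshold`` times its mean cytoplasmic intensity.  Cells with
    zero cytoplasmic mean are skipped with a warning.
    """
    if ratio_threshold <= 0:
        raise ValueError("ratio_threshold must be positive")
    img = np.asarray(mirna_image, dtype=np.float64)
    require_same_shape(img, cell_map.cell_labels)
    rows = []
    for cid in cell_map.retained_cell_ids:
        nuc = img[cell_map.nucleus_mask(cid)]
        cyto = img[cytoplasm_region(cell_map, cid)]
        nuc_mean = float(nuc.mean()) if nuc.size else np.nan
        cyto_mean = float(cyto.mean()) if cyto.size else 0.0
        if cyto_mean == 0:
            logger.warning("cell %d has zero cytoplasm mean; skipped", cid)
            continue
        ratio = nuc_mean / cyto_mean
        rows.append({"cell_id": cid, "nuclear_mean": nuc_mean,
                     "cytoplasm_mean": cyto_mean, "ratio": ratio,
                     "accumulated": bool(ratio >= ratio_threshold)})
    per_cell = pd.DataFrame(
        rows, columns=["cell_id", "nuclear_mean", "cytoplasm_mean",
                       "ratio", "accumulated"])
    frac = float(per_cell["accumulated"].mean()) if len(per_cell) else np.nan
    return NuclearAccumulationResult(per_cell=per_cell,
                                     fraction_accumulated=frac,
                                     ratio_threshold=ratio_threshold)


def pearson_coefficient(image_a: np.ndarray, image_b: np.ndarray,
                        mask: np.ndarray | None = None) -> float:
    """Sample Pearson correlation of two channels over a pixel mask.

    The classic pixel-intensity co-localization coefficient, computed
    without Costes thresholding.  Raises on fewer than two mask pixels or
    zero variance in either channel.
    """
    a = np.asarray(image_a, dtype=np.float64)
    b = np.asarray(image_b, dtype=np.float64)
    require_same_shape(a, b)
    if mask is None:
        x, y = a.ravel(), b.ravel()
    else:
        m = np.asarray(mask, dtype=bool)
        require_same_shape(a, m)
        x, y = a[m], b[m]
    if x.size < 2:
        raise ValueError("mask must select at least 2 pixels")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a channel: Pearson r undefined")
    return float(sps.pearsonr(x, y).statistic)
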