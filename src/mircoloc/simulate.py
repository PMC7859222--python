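"""Synthetic fluorescence-microscopy fields of resealed cells with ground truth.

The simulator emulates the imaging geometry of the co-localization
experiments this package quantifies: 9-slice confocal z-stacks of adherent
cells, CD63-positive MVE puncta of ~500 nm diameter and diffraction-limited
miRNA spots of ~200 nm, with a controllable true co-localization fraction.
Every downstream stage (segmentation, LoG spot detection, AND-gated object
co-localization) can therefore be tested against exact truth tables without
any external data.

Model summary
-------------
* Cells are random non-overlapping ellipses; each contains one concentric
  elliptical nucleus.  Geometry is 2D (constant across z) — all analysis
  happens after maximum-intensity projection.
* MVE centres are uniform over each cell's cytoplasm (cell minus nucleus).
* Each miRNA spot is, independently, placed inside a randomly chosen MVE
  footprint (offset < 1/4 MVE diameter) with probability ``coloc_fraction``,
  otherwise uniformly in the cytoplasm.  A fraction of guide spots can be
  diverted to the nucleus to emulate early-time-point nuclear accumulation.
* Spots render as isotropic Gaussians whose sigma combines the physical
  spot size (sigma = diameter / (2*sqrt(2 ln 2))) with the optical PSF in
  quadrature; region channels (nucleus, cytoplasm) render as filled,
  PSF-blurred areas.  Per-pixel Poisson shot noise and additive Gaussian
  read noise follow, clipped at zero.
* Truth co-localization: a miRNA spot is colocalized iff it was *placed* at
  an MVE (centre offset < 1/4 MVE diameter), which guarantees pixel-level
  mask overlap after rendering at the default sizes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .core import CHANNEL_ROLES, ImageStack

logger = logging.getLogger(__name__)

#: full width at half maximum of a unit-sigma Gaussian
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class PlacementError(RuntimeError):
    """Requested cells could not be packed into the field."""


def _default_background() -> dict[str, float]:
    return {role: 10.0 for role in CHANNEL_ROLES}


def _default_amplitude() -> dict[str, float]:
    return {
        "nucleus": 150.0,
        "cytoplasm": 60.0,
        "mve": 300.0,
        "mirna_guide": 300.0,
        "mirna_passenger": 300.0,
    }


@dataclass
class SimulationParams:
    """All knobs of the synthetic field generator.

    Defaults reproduce the study conditions the pipeline was built for:
    9-slice z-stacks, ~500 nm MVEs, ~200 nm miRNA spots, HeLa-sized cells,
    and spot amplitudes giving a peak SNR well above 10 over background.
    """

    field_size_px: tuple[int, int] = (1024, 1024)
    n_z: int = 9
    pixel_size_nm: float = 80.0
    n_cells: int = 8
    cell_radius_um: tuple[float, float] = (7.0, 9.0)
    nucleus_radius_um: tuple[float, float] = (2.5, 3.5)
    mve_per_cell_mean: float = 12.0
    mve_diameter_nm: float = 500.0
    mirna_spot_diameter_nm: float = 200.0
    guide_spots_per_cell_mean: float = 15.0
    passenger_spots_per_cell_mean: float = 15.0
    coloc_fraction_guide: float = 0.5
    coloc_fraction_passenger: float = 0.2
    nuclear_fraction_guide: float = 0.0
    psf_sigma_nm: float = 100.0
    background_level: dict[str, float] = field(default_factory=_default_background)
    spot_amplitude: dict[str, float] = field(default_factory=_default_amplitude)
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        h, w = self.field_size_px
        if h < 1 or w < 1:
            raise ValueError("field_size_px must be positive")
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for name in ("coloc_fraction_guide", "coloc_fraction_passenger",
                     "nuclear_fraction_guide"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("mve_per_cell_mean", "guide_spots_per_cell_mean",
                     "passenger_spots_per_cell_mean", "mve_diameter_nm",
                     "mirna_spot_diameter_nm", "psf_sigma_nm", "read_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for mapping in (self.background_level, self.spot_amplitude):
            for role, v in mapping.items():
                if v < 0:
                    raise ValueError(f"amplitude/background for {role} must be >= 0")
        lo, hi = self.cell_radius_um
        nlo, nhi = self.nucleus_radius_um
        if not (0 < lo <= hi) or not (0 < nlo <= nhi):
            raise ValueError("radius ranges must be positive and ordered")
        if nhi >= lo:
            raise ValueError("nucleus radius max must be smaller than cell radius min")

    # -- unit helpers -------------------------------------------------
    def um_to_px(self, um: float) -> float:
        return um * 1000.0 / self.pixel_size_nm

    def nm_to_px(self, nm: float) -> float:
        """nm -> px, floored at 1 px so sub-resolution spots stay representable."""
        return max(nm / self.pixel_size_nm, 1.0)

    def spot_sigma_px(self, diameter_nm: float) -> float:
        """Rendered sigma: physical size and PSF combined in quadrature."""
        size_px = self.nm_to_px(diameter_nm) / FWHM_PER_SIGMA
        psf_px = self.psf_sigma_nm / self.pixel_size_nm
        return math.hypot(size_px, psf_px)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["field_size_px"] = list(self.field_size_px)
        d["cell_radius_um"] = list(self.cell_radius_um)
        d["nucleus_radius_um"] = list(self.nucleus_radius_um)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationParams":
        d = dict(d)
        for key in ("field_size_px", "cell_radius_um", "nucleus_radius_um"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Simulator truth tables.

    ``spots`` has one row per punctum (MVEs included, role ``mve``) with
    columns ``channel_role, x_px, y_px, z, cell_id, mve_id, coloc_flag``;
    ``cells`` one row per cell with ellipse geometry and border flag;
    ``per_cell_truth`` per-cell counts and true co-localization rates.
    """

    spots: pd.DataFrame
    cells: pd.DataFrame
    per_cell_truth: pd.DataFrame

    def recompute_per_cell_truth(self) -> pd.DataFrame:
        """Brute-force per-cell truth from the spot table (for invariants)."""
        rows = []
        for cell_id in self.cells["cell_id"]:
            sub = self.spots[self.spots["cell_id"] == cell_id]
            row = {"cell_id": int(cell_id)}
            row["n_mve"] = int((sub["channel_role"] == "mve").sum())
            for role, tag in (("mirna_guide", "guide"), ("mirna_passenger", "passenger")):
                rsub = sub[sub["channel_role"] == role]
                row[f"n_{tag}"] = len(rsub)
                row[f"true_coloc_rate_{tag}"] = (
                    float(rsub["coloc_flag"].sum()) / len(rsub) if len(rsub) else np.nan
                )
            rows.append(row)
        return pd.DataFrame(
            rows,
            columns=["cell_id", "n_mve", "n_guide", "n_passenger",
                     "true_coloc_rate_guide", "true_coloc_rate_passenger"],
        )


# ---------------------------------------------------------------------------
# geometry


def _ellipse_mask(shape, cy, cx, a, b, theta):
    """Boolean mask of the ellipse with semi-axes a (along theta) and b."""
    h, w = shape
    r0 = max(int(math.floor(cy - a)) - 1, 0)
    r1 = min(int(math.ceil(cy + a)) + 2, h)
    c0 = max(int(math.floor(cx - a)) - 1, 0)
    c1 = min(int(math.ceil(cx + a)) + 2, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - cy
    dx = xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask = np.zeros(shape, dtype=bool)
    mask[r0:r1, c0:c1] = inside
    return mask


def _inside_ellipse(y, x, cy, cx, a, b, theta):
    ct, st = math.cos(theta), math.sin(theta)
    u = (x - cx) * ct + (y - cy) * st
    v = -(x - cx) * st + (y - cy) * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_cell_geometry(params: SimulationParams, rng: np.random.Generator):
    """Place non-overlapping elliptical cells with concentric nuclei.

    Returns ``(cell_labels, nucleus_labels, cells_df)`` where the label
    images are ``H x W`` int32 (label k = cell k, 0 = background).

    Raises
    ------
    PlacementError
        If the requested cells cannot be packed after a bounded number of
        rejection-sampling attempts; the message names the count achieved.
    """
    h, w = params.field_size_px
    cell_labels = np.zeros((h, w), dtype=np.int32)
    nucleus_labels = np.zeros((h, w), dtype=np.int32)
    columns = ["cell_id", "center_row", "center_col", "cell_a_px", "cell_b_px",
               "theta", "nucleus_a_px", "nucleus_b_px", "border_touching"]
    if params.n_cells == 0:
        return cell_labels, nucleus_labels, pd.DataFrame(columns=columns)

    placed = []  # (cy, cx, a)
    rows = []
    max_attempts = 500 * params.n_cells
    attempts = 0
    rmin_px = params.um_to_px(params.cell_radius_um[0])
    rmax_px = params.um_to_px(params.cell_radius_um[1])
    nmin_px = params.um_to_px(params.nucleus_radius_um[0])
    nmax_px = params.um_to_px(params.nucleus_radius_um[1])

    for cell_id in range(1, params.n_cells + 1):
        ok = False
        while attempts < max_attempts:
            attempts += 1
            a = rng.uniform(rmin_px, rmax_px)
            b = a * rng.uniform(0.7, 1.0)
            theta = rng.uniform(0.0, math.pi)
            if 2 * (a + 1) >= min(h, w):
                raise PlacementError(
                    f"cell of semi-major {a:.0f} px cannot fit the "
                    f"{h}x{w} field; placed {cell_id - 1} of {params.n_cells}"
                )
            cy = rng.uniform(a + 1, h - a - 1)
            cx = rng.uniform(a + 1, w - a - 1)
            if all((cy - py) ** 2 + (cx - px) ** 2 > (a + pa + 1) ** 2
                   for py, px, pa in placed):
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"placed {cell_id - 1} of {params.n_cells} cells after "
                f"{max_attempts} attempts"
            )
        na = min(rng.uniform(nmin_px, nmax_px), 0.85 * b)
        nb = na * rng.uniform(0.7, 1.0)
        cmask = _ellipse_mask((h, w), cy, cx, a, b, theta)
        nmask = _ellipse_mask((h, w), cy, cx, na, nb, theta)
        cell_labels[cmask] = cell_id
        nucleus_labels[nmask] = cell_id
        border = bool(
            cmask[0, :].any() or cmask[-1, :].any()
            or cmask[:, 0].any() or cmask[:, -1].any()
        )
        placed.append((cy, cx, a))
        rows.append({
            "cell_id": cell_id, "center_row": cy, "center_col": cx,
            "cell_a_px": a, "cell_b_px": b, "theta": theta,
            "nucleus_a_px": na, "nucleus_b_px": nb, "border_touching": border,
        })
    return cell_labels, nucleus_labels, pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# puncta placement


def _sample_in_region(rng, crow, ccol, a, b, theta, accept, n_max=10000):
    """Rejection-sample one point inside the cell ellipse passing `accept`."""
    for _ in range(n_max):
        u = rng.uniform(-1.0, 1.0)
        v = rng.uniform(-1.0, 1.0)
        if u * u + v * v > 1.0:
            continue
        ct, st = math.cos(theta), math.sin(theta)
        x = ccol + a * u * ct - b * v * st
        y = crow + a * u * st + b * v * ct
        if accept(y, x):
            return y, x
    raise RuntimeError("rejection sampling failed (degenerate region)")


def place_puncta(cell_labels, nucleus_labels, cells: pd.DataFrame,
                 params: SimulationParams, rng: np.random.Generator) -> pd.DataFrame:
    """Draw MVE centres and miRNA spots with known co-localization flags.

    Per-cell random substreams are spawned from ``rng`` in cell-id order,
    so adding cells to a field never perturbs earlier cells.
    """
    spot_rows = []
    mve_counter = 0
    n = len(cells)
    streams = rng.spawn(n) if n else []
    spot_cols = ["channel_role", "x_px", "y_px", "z", "cell_id", "mve_id", "coloc_flag"]

    for (_, cell), crng in zip(cells.iterrows(), streams):
        cid = int(cell["cell_id"])
        cy, cx = cell["center_row"], cell["center_col"]
        a, b, theta = cell["cell_a_px"], cell["cell_b_px"], cell["theta"]
        na, nb = cell["nucleus_a_px"], cell["nucleus_b_px"]

        def in_cytoplasm(y, x):
            return not _inside_ellipse(y, x, cy, cx, na, nb, theta)

        def in_nucleus(y, x):
            return _inside_ellipse(y, x, cy, cx, na, nb, theta)

        cyto_area = math.pi * (a * b - na * nb)
        if cyto_area <= 0:
            logger.warning("cell %d has zero cytoplasm area; skipped", cid)
            continue

        # MVEs: uniform over the cytoplasm
        n_mve = int(crng.poisson(params.mve_per_cell_mean))
        mve_xy = []
        for _ in range(n_mve):
            y, x = _sample_in_region(crng, cy, cx, a, b, theta, in_cytoplasm)
            mve_counter += 1
            z_mve = int(crng.integers(params.n_z))
            mve_xy.append((mve_counter, x, y, z_mve))
            spot_rows.append({
                "channel_role": "mve", "x_px": x, "y_px": y,
                "z": z_mve, "cell_id": cid,
                "mve_id": mve_counter, "coloc_flag": False,
            })

        max_offset_px = params.nm_to_px(params.mve_diameter_nm) / 4.0

        for role, mean, coloc_frac, nuc_frac in (
            ("mirna_guide", params.guide_spots_per_cell_mean,
             params.coloc_fraction_guide, params.nuclear_fraction_guide),
            ("mirna_passenger", params.passenger_spots_per_cell_mean,
             params.coloc_fraction_passenger, 0.0),
        ):
            n_spots = int(crng.poisson(mean))
            for _ in range(n_spots):
                mve_id = None
                coloc = False
                if nuc_frac > 0 and crng.uniform() < nuc_frac:
                    y, x = _sample_in_region(crng, cy, cx, na, nb, theta, in_nucleus)
                    z = int(crng.integers(params.n_z))
                elif mve_xy and crng.uniform() < coloc_frac:
                    mid, mx, my, mz = mve_xy[int(crng.integers(len(mve_xy)))]
                    # uniform offset within a disk of radius < 1/4 MVE diameter;
                    # a spot accumulated at an MVE shares the MVE's z plane
                    r = max_offset_px * math.sqrt(crng.uniform())
                    phi = crng.uniform(0.0, 2.0 * math.pi)
                    x, y = mx + r * math.cos(phi), my + r * math.sin(phi)
                    mve_id, coloc, z = mid, True, mz
                else:
                    y, x = _sample_in_region(crng, cy, cx, a, b, theta, in_cytoplasm)
                    z = int(crng.integers(params.n_z))
                spot_rows.append({
                    "channel_role": role, "x_px": x, "y_px": y,
                    "z": z, "cell_id": cid,
                    "mve_id": mve_id, "coloc_flag": coloc,
                })

    return pd.DataFrame(spot_rows, columns=spot_cols)


# ---------------------------------------------------------------------------
# rendering


def _render_gaussian(plane: np.ndarray, row: float, col: float,
                     amplitude: float, sigma: float) -> None:
    """Add a peak-normalised 2D Gaussian to ``plane`` in place."""
    h, w = plane.shape
    half = int(math.ceil(4.0 * sigma))
    r0 = max(int(round(row)) - half, 0)
    r1 = min(int(round(row)) + half + 1, h)
    c0 = max(int(round(col)) - half, 0)
    c1 = min(int(round(col)) + half + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy = np.arange(r0, r1, dtype=np.float64) - row
    xx = np.arange(c0, c1, dtype=np.float64) - col
    g = np.exp(-(yy[:, None] ** 2 + xx[None, :] ** 2) / (2.0 * sigma * sigma))
    plane[r0:r1, c0:c1] += amplitude * g


def render_stack(cell_labels, nucleus_labels, spots: pd.DataFrame,
                 params: SimulationParams, rng: np.random.Generator) -> ImageStack:
    """Render the five-channel z-stack with shot and read noise."""
    from scipy.ndimage import gaussian_filter

    h, w = params.field_size_px
    psf_px = params.psf_sigma_nm / params.pixel_size_nm
    data = np.zeros((len(CHANNEL_ROLES), params.n_z, h, w), dtype=np.float64)

    # region channels: constant across z
    region_2d = {
        "nucleus": (nucleus_labels > 0).astype(np.float64),
        "cytoplasm": ((cell_labels > 0) & (nucleus_labels == 0)).astype(np.float64),
    }
    role_sigma = {
        "mve": params.spot_sigma_px(params.mve_diameter_nm),
        "mirna_guide": params.spot_sigma_px(params.mirna_spot_diameter_nm),
        "mirna_passenger": params.spot_sigma_px(params.mirna_spot_diameter_nm),
    }

    for ci, role in enumerate(CHANNEL_ROLES):
        amp = float(params.spot_amplitude.get(role, 0.0))
        bg = float(params.background_level.get(role, 0.0))
        if role in region_2d:
            img = region_2d[role] * amp
            if psf_px > 0:
                img = gaussian_filter(img, psf_px)
            data[ci] += img[None, :, :]
        else:
            sigma = role_sigma[role]
            sub = spots[spots["channel_role"] == role] if len(spots) else spots
            for _, s in sub.iterrows():
                _render_gaussian(data[ci, int(s["z"])], float(s["y_px"]),
                                 float(s["x_px"]), amp, sigma)
        data[ci] += bg

    if params.shot_noise:
        data = rng.poisson(data).astype(np.float64)
    if params.read_noise_sd > 0:
        data = data + rng.normal(0.0, params.read_noise_sd, size=data.shape)
    np.clip(data, 0.0, None, out=data)

    roles = {i: r for i, r in enumerate(CHANNEL_ROLES)}
    return ImageStack(data.astype(np.float32), roles, params.pixel_size_nm)


def simulate_field(params: SimulationParams, seed: int | None = None):
    """Generate one field: ``(ImageStack, GroundTruth)``.

    Fully determined by ``(params, seed)``; ``seed=None`` uses
    ``params.seed``.  Three independent substreams drive geometry, puncta
    placement (further split per cell) and noise, in that fixed order.
    """
    if seed is None:
        seed = params.seed
    geom_rng, spot_rng, noise_rng = np.random.default_rng(int(seed)).spawn(3)
    cell_labels, nucleus_labels, cells = generate_cell_geometry(params, geom_rng)
    spots = place_puncta(cell_labels, nucleus_labels, cells, params, spot_rng)
    stack = render_stack(cell_labels, nucleus_labels, spots, params, noise_rng)
    truth = GroundTruth(spots=spots, cells=cells,
                        per_cell_truth=pd.DataFrame())
    truth.per_cell_truth = truth.recompute_per_cell_truth()
    return stack, truth
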