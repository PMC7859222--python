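"""Core in-memory containers shared by the imaging pipeline.

The pipeline works on multi-channel fluorescence fields of resealed cells.
Channels are addressed by *role* rather than index, because acquisition
order varies between experiments:

``nucleus``          Hoechst 33342 counterstain, used for nucleus segmentation.
``cytoplasm``        anti-Ago2 immunostain, evenly cytoplasmic, used to
                     delineate cell bodies.
``mve``              anti-CD63 immunostain marking multivesicular endosomes.
``mirna_guide``      Cy3-labelled guide strand of the introduced miRNA mimic.
``mirna_passenger``  Cy5-labelled passenger strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: canonical channel roles, in the order the simulator emits them
CHANNEL_ROLES = ("nucleus", "cytoplasm", "mve", "mirna_guide", "mirna_passenger")


class RoleError(KeyError):
    """A required channel role is absent or ambiguous."""


@dataclass
class ImageStack:
    """A channels x z x height x width intensity volume.

    Parameters
    ----------
    data
        Non-negative intensities, shape ``(C, Z, H, W)``.
    channel_roles
        Map from channel index to role name; one entry per channel.
    pixel_size_nm
        Lateral pixel size in nanometres.
    """

    data: np.ndarray
    channel_roles: Mapping[int, str]
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected (C, Z, H, W) data, got shape {self.data.shape}")
        self.channel_roles = dict(self.channel_roles)
        if len(self.channel_roles) != self.data.shape[0]:
            raise ValueError(
                f"{self.data.shape[0]} channels but {len(self.channel_roles)} roles"
            )
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.data.size and float(self.data.min()) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def shape_2d(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def index_of(self, role: str) -> int:
        for idx, r in self.channel_roles.items():
            if r == role:
                return idx
        raise RoleError(f"role unresolved: {role}")

    def channel(self, role: str) -> np.ndarray:
        """Return the ``(Z, H, W)`` volume for one channel role."""
        return self.data[self.index_of(role)]


@dataclass
class Projection:
    """A 2D multi-channel image, typically a maximum-intensity projection."""

    data: np.ndarray  # (C, H, W)
    channel_roles: Mapping[int, str]
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected (C, H, W) data, got shape {self.data.shape}")
        self.channel_roles = dict(self.channel_roles)

    def index_of(self, role: str) -> int:
        for idx, r in self.channel_roles.items():
            if r == role:
                return idx
        raise RoleError(f"role unresolved: {role}")

    def channel(self, role: str) -> np.ndarray:
        return self.data[self.index_of(role)]


@dataclass
class CellMap:
    """Per-cell regions produced by nucleus-seeded watershed segmentation.

    ``nucleus_labels`` and ``cell_labels`` share label values: nucleus *k*
    lies inside cell *k*.  Label 0 is background.  Cells whose mask touches
    the image border are listed in ``border_touching`` and are excluded
    from all per-cell statistics downstream.
    """

    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    pixel_size_nm: float
    border_touching: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.nucleus_labels = np.asarray(self.nucleus_labels)
        self.cell_labels = np.asarray(self.cell_labels)
        if self.nucleus_labels.shape != self.cell_labels.shape:
            raise ValueError("nucleus and cell label images differ in shape")
        self.border_touching = frozenset(int(c) for c in self.border_touching)

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_labels.shape

    @property
    def cell_ids(self) -> list[int]:
        ids = np.unique(self.cell_labels)
        return [int(i) for i in ids if i != 0]

    @property
    def retained_cell_ids(self) -> list[int]:
        """Cells kept for per-cell statistics (border cells dropped)."""
        return [c for c in self.cell_ids if c not in self.border_touching]

    @property
    def nucleus_to_cell(self) -> dict[int, int]:
        return {c: c for c in self.cell_ids}

    def cell_mask(self, cell_id: int) -> np.ndarray:
        self._check(cell_id)
        return self.cell_labels == cell_id

    def nucleus_mask(self, cell_id: int) -> np.ndarray:
        self._check(cell_id)
        return self.nucleus_labels == cell_id

    def _check(self, cell_id: int) -> None:
        if cell_id not in self.cell_ids:
            raise KeyError(f"unknown cell id: {cell_id}")


@dataclass
class Spot:
    """One detected punctum (connected component of the detection mask)."""

    label: int
    centroid: tuple[float, float]  # (row, col), intensity-weighted
    area_px: int
    mean_intensity: float
    total_intensity: float
    equivalent_diameter_px: float
    cell_id: int | None = None


@dataclass
class SpotSet:
    """Detected puncta for one channel role.

    ``label_image`` carries each retained spot's pixels under its label;
    ``source_mask`` is the union of all retained spot pixels.
    """

    channel_role: str
    spots: list[Spot] = field(default_factory=list)
    label_image: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.label_image is not None:
            self.label_image = np.asarray(self.label_image)

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def source_mask(self) -> np.ndarray:
        if self.label_image is None:
            raise ValueError("spot set has no label image")
        return self.label_image > 0

    def spot_pixels(self, label: int) -> np.ndarray:
        return self.label_image == label

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "label": s.label,
                "row": s.centroid[0],
                "col": s.centroid[1],
                "area_px": s.area_px,
                "mean_intensity": s.mean_intensity,
                "total_intensity": s.total_intensity,
                "equivalent_diameter_px": s.equivalent_diameter_px,
                "cell_id": s.cell_id,
            }
            for s in self.spots
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "label",
                "row",
                "col",
                "area_px",
                "mean_intensity",
                "total_intensity",
                "equivalent_diameter_px",
                "cell_id",
            ],
        )


def require_same_shape(*arrays: np.ndarray) -> None:
    shapes = {np.asarray(a).shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"shape mismatch: {sorted(shapes)}")
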