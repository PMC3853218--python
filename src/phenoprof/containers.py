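"""Core in-memory containers shared across the pipeline.

An :class:`ImagePlane` is one grayscale fluorescence channel of one imaging
position (a *frame*) in one well of a microtiter plate.  A
:class:`ChannelStack` groups the registered planes of all markers for that
frame.  A :class:`FeatureTable` holds the per-cell feature matrix produced by
feature extraction, together with the cell index (well, frame, cell label and
centroid) that makes every row traceable back to a segmented object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Columns identifying each cell in a FeatureTable, in storage order.
CELL_INDEX_COLUMNS = (
    "well_id",
    "frame_index",
    "cell_label",
    "centroid_row",
    "centroid_col",
)


@dataclass
class ImagePlane:
    """A single-channel intensity image for one (well, frame, marker).

    Parameters
    ----------
    pixels : ndarray
        2-D non-negative integer intensity array.
    bit_depth : int
        8 or 16; all pixel values must fit in this depth.
    marker : str
        Fluorescent marker name (e.g. ``"DNA"``, ``"Actin"``).
    well_id : str
        Well identifier on the plate (e.g. ``"A01"``).
    frame_index : int
        Imaging position within the well, 0-based.
    """

    pixels: np.ndarray
    bit_depth: int
    marker: str = ""
    well_id: str = ""
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("pixels must be a 2-D array with both dimensions >= 1")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.pixels.size and (
            self.pixels.min() < 0 or self.pixels.max() > 2**self.bit_depth - 1
        ):
            raise ValueError(
                f"pixel values outside [0, 2^{self.bit_depth} - 1]"
            )
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ChannelStack:
    """Registered multi-channel planes for one (well, frame)."""

    planes: dict[str, ImagePlane]
    well_id: str = ""
    frame_index: int = 0

    def __post_init__(self) -> None:
        if not self.planes:
            raise ValueError("a ChannelStack needs at least one plane")
        shapes = {p.shape for p in self.planes.values()}
        if len(shapes) != 1:
            raise ValueError(f"planes have mismatched dimensions: {shapes}")
        for marker, plane in self.planes.items():
            if plane.marker and plane.marker != marker:
                raise ValueError(
                    f"plane registered under {marker!r} carries marker {plane.marker!r}"
                )

    @property
    def markers(self) -> list[str]:
        return list(self.planes)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.planes.values())).shape

    def __getitem__(self, marker: str) -> ImagePlane:
        return self.planes[marker]


@dataclass
class FeatureTable:
    """Cells x features matrix with a per-cell index.

    ``values`` is float64 with one row per cell and one column per feature in
    ``feature_names`` order.  ``cells`` is a DataFrame with the columns in
    :data:`CELL_INDEX_COLUMNS` aligned row-wise with ``values``.
    """

    values: np.ndarray
    feature_names: list[str]
    cells: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x features)")
        self.feature_names = list(self.feature_names)
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{self.values.shape[1]} columns but "
                f"{len(self.feature_names)} feature names"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.cells.empty and self.values.shape[0] > 0:
            self.cells = pd.DataFrame(
                {
                    "well_id": [""] * self.values.shape[0],
                    "frame_index": 0,
                    "cell_label": np.arange(1, self.values.shape[0] + 1),
                    "centroid_row": np.nan,
                    "centroid_col": np.nan,
                }
            )
        if len(self.cells) != self.values.shape[0]:
            raise ValueError("cell index length must match the number of rows")
        self.cells = self.cells.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        """Cell index columns followed by one column per feature."""
        feat = pd.DataFrame(self.values, columns=self.feature_names)
        return pd.concat([self.cells.reset_index(drop=True), feat], axis=1)

    def select_columns(self, names: list[str]) -> "FeatureTable":
        pos = [self.feature_names.index(n) for n in names]
        return FeatureTable(self.values[:, pos], names, self.cells.copy())

    def select_rows(self, mask: np.ndarray) -> "FeatureTable":
        mask = np.asarray(mask)
        return FeatureTable(
            self.values[mask], list(self.feature_names), self.cells[mask].copy()
        )


def concat_tables(tables: list[FeatureTable]) -> FeatureTable:
    """Stack FeatureTables sharing an identical feature-name list."""
    if not tables:
        raise ValueError("need at least one table")
    names = tables[0].feature_names
    for t in tables[1:]:
        if t.feature_names != names:
            raise ValueError("tables have differing feature names")
    values = np.vstack([t.values for t in tables]) if tables else np.empty((0, 0))
    cells = pd.concat([t.cells for t in tables], ignore_index=True)
    return FeatureTable(values, names, cells)
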