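"""Image I/O, the HDF5 result store, CSV export and selective loading.

Images are single-plane grayscale 8- or 16-bit TIFF or PNG; label masks are
written as 16-bit images.  All per-run results live in one self-describing
HDF5 file laid out as::

    /meta/{markers, config, version, failed}
    /wells/<well>/frames/<k>/masks/{nuclei, cells}
    /features/{matrix, names, cell_index}

Frame-level datasets let independent workers produce disjoint results that
a single writer serializes into the store.  ``load_wells`` pulls selected
wells and glob-selected feature columns back out as a
:class:`~phenoprof.containers.FeatureTable`.
"""

from __future__ import annotations

import fnmatch
import warnings
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .containers import CELL_INDEX_COLUMNS, FeatureTable, ImagePlane

FORMAT_VERSION = "1.0"

_CSV_FLOAT_FMT = "%.17g"


class UnsupportedImageError(ValueError):
    """Raised for RGB, multi-page, or non-8/16-bit input images."""


def read_image(
    path: str | Path, marker: str = "", well_id: str = "", frame_index: int = 0
) -> ImagePlane:
    """Read a grayscale TIFF/PNG, preserving integer values bit-exactly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            if len(tf.pages) != 1:
                raise UnsupportedImageError(
                    f"{path}: multi-page TIFF is not supported"
                )
            arr = tf.pages[0].asarray()
    elif suffix == ".png":
        arr = iio.imread(path)
    else:
        raise UnsupportedImageError(f"{path}: unsupported extension {suffix!r}")
    arr = np.asarray(arr)
    if arr.ndim != 2:
        raise UnsupportedImageError(
            f"{path}: expected a single grayscale plane, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise UnsupportedImageError(
            f"{path}: unsupported pixel type {arr.dtype} (need uint8/uint16)"
        )
    return ImagePlane(arr, depth, marker, well_id, frame_index)


def write_image(pixels: np.ndarray, path: str | Path) -> Path:
    """Write a uint8/uint16 array as TIFF or PNG by extension."""
    path = Path(path)
    pixels = np.asarray(pixels)
    if pixels.dtype not in (np.uint8, np.uint16):
        raise UnsupportedImageError(f"cannot write dtype {pixels.dtype}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    elif suffix == ".png":
        iio.imwrite(path, pixels)
    else:
        raise UnsupportedImageError(f"unsupported extension {suffix!r}")
    return path


def write_label_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a label mask as a 16-bit image, labels preserved bit-exactly."""
    mask = np.asarray(mask)
    if mask.size and mask.max() > 65535:
        raise OverflowError(
            f"mask has {int(mask.max())} labels; 16-bit output holds <= 65535"
        )
    if mask.size and mask.min() < 0:
        raise ValueError("label masks are non-negative")
    return write_image(mask.astype(np.uint16), path)


# ---------------------------------------------------------------------------
# HDF5 result store


class EmptyStoreError(RuntimeError):
    """Raised when an operation needs features the store does not hold."""


class ResultStore:
    """One HDF5 file holding masks, features and run metadata.

    Open with mode ``"w"`` to create, ``"r"`` to read, ``"a"`` to append.
    Usable as a context manager.
    """

    def __init__(self, path: str | Path, mode: str = "r"):
        self.path = Path(path)
        self._f = h5py.File(self.path, mode)
        if mode == "w":
            self._f.create_group("meta")
            self._f.create_group("wells")

    # -- lifecycle ---------------------------------------------------------
    def close(self) -> None:
        self._f.close()

    def __enter__(self) -> "ResultStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- metadata ----------------------------------------------------------
    def set_meta(self, markers: list[str], config_text: str = "") -> None:
        meta = self._f.require_group("meta")
        for key in ("markers", "config", "version"):
            if key in meta:
                del meta[key]
        meta.create_dataset("markers", data=np.array(markers, dtype="S"))
        meta.create_dataset("config", data=config_text)
        meta.create_dataset("version", data=FORMAT_VERSION)

    @property
    def markers(self) -> list[str]:
        return [m.decode() for m in self._f["meta/markers"][()]]

    @property
    def config_text(self) -> str:
        raw = self._f["meta/config"][()]
        return raw.decode() if isinstance(raw, bytes) else str(raw)

    def record_failed(self, well_id: str, frame_index: int, message: str) -> None:
        failed = self._f.require_group("meta/failed")
        failed.create_dataset(f"{well_id}_{frame_index}", data=message)

    @property
    def failed_frames(self) -> dict[str, str]:
        if "meta/failed" not in self._f:
            return {}
        grp = self._f["meta/failed"]
        return {k: (grp[k][()].decode() if isinstance(grp[k][()], bytes)
                    else str(grp[k][()])) for k in grp}

    # -- masks -------------------------------------------------------------
    def add_masks(
        self, well_id: str, frame_index: int,
        nuclei: np.ndarray, cells: np.ndarray,
    ) -> None:
        grp = self._f.require_group(
            f"wells/{well_id}/frames/{frame_index}/masks"
        )
        for name, arr in (("nuclei", nuclei), ("cells", cells)):
            if name in grp:
                del grp[name]
            arr = np.asarray(arr)
            dtype = np.uint16 if arr.max(initial=0) <= 65535 else np.uint32
            grp.create_dataset(name, data=arr.astype(dtype))

    def get_masks(
        self, well_id: str, frame_index: int
    ) -> tuple[np.ndarray, np.ndarray]:
        grp = self._f[f"wells/{well_id}/frames/{frame_index}/masks"]
        return grp["nuclei"][()].astype(np.int32), grp["cells"][()].astype(np.int32)

    @property
    def wells(self) -> list[str]:
        return sorted(self._f["wells"]) if "wells" in self._f else []

    def frames(self, well_id: str) -> list[int]:
        key = f"wells/{well_id}/frames"
        return sorted(int(k) for k in self._f[key]) if key in self._f else []

    # -- features ----------------------------------------------------------
    def set_features(self, table: FeatureTable) -> None:
        if "features" in self._f:
            del self._f["features"]
        grp = self._f.create_group("features")
        grp.create_dataset("matrix", data=table.values.astype(np.float64))
        grp.create_dataset(
            "names", data=np.array(table.feature_names, dtype="S")
        )
        idx = table.cells
        dt = np.dtype(
            [
                ("well_id", h5py.string_dtype()),
                ("frame_index", np.int32),
                ("cell_label", np.int32),
                ("centroid_row", np.float64),
                ("centroid_col", np.float64),
            ]
        )
        rec = np.empty(len(idx), dtype=dt)
        for col in CELL_INDEX_COLUMNS:
            rec[col] = idx[col].to_numpy()
        grp.create_dataset("cell_index", data=rec)

    @property
    def has_features(self) -> bool:
        return "features" in self._f

    @property
    def feature_names(self) -> list[str]:
        self._require_features()
        return [n.decode() for n in self._f["features/names"][()]]

    def get_features(self) -> FeatureTable:
        self._require_features()
        rec = self._f["features/cell_index"][()]
        cells = pd.DataFrame(
            {
                "well_id": [w.decode() if isinstance(w, bytes) else w
                            for w in rec["well_id"]],
                "frame_index": rec["frame_index"].astype(int),
                "cell_label": rec["cell_label"].astype(int),
                "centroid_row": rec["centroid_row"],
                "centroid_col": rec["centroid_col"],
            }
        )
        return FeatureTable(
            self._f["features/matrix"][()], self.feature_names, cells
        )

    def _require_features(self) -> None:
        if "features" not in self._f:
            raise EmptyStoreError(f"{self.path} holds no extracted features")

    # -- profiles ----------------------------------------------------------
    def set_profiles(self, profile_set) -> None:
        grp = self._f.require_group("profiles")
        method = profile_set.method
        if method in grp:
            del grp[method]
        sub = grp.create_group(method)
        sub.create_dataset("matrix", data=profile_set.to_matrix())
        sub.create_dataset(
            "treatments",
            data=np.array([p.treatment_id for p in profile_set.profiles],
                          dtype="S"),
        )
        sub.create_dataset(
            "groups",
            data=np.array([p.group_id or "" for p in profile_set.profiles],
                          dtype="S"),
        )

    def get_profiles(self, method: str):
        from .profiling import Profile, ProfileSet

        sub = self._f[f"profiles/{method}"]
        mat = sub["matrix"][()]
        treatments = [t.decode() for t in sub["treatments"][()]]
        groups = [g.decode() or None for g in sub["groups"][()]]
        return ProfileSet(
            [Profile(mat[i], treatments[i], method, groups[i])
             for i in range(len(treatments))],
            method,
        )


def export_features_csv(store: ResultStore, path: str | Path) -> Path:
    """Write the feature matrix as RFC-4180 CSV, one row per cell.

    Leading columns are the cell index; undefined (NaN) features are
    written as the literal ``NA``; floats carry 17 significant digits so a
    re-parse reproduces the stored values exactly.
    """
    table = store.get_features()
    df = table.to_dataframe()
    path = Path(path)
    df.to_csv(path, index=False, na_rep="NA", float_format=_CSV_FLOAT_FMT)
    return path


def load_wells(
    store: ResultStore,
    well_ids: list[str],
    feature_name_patterns: list[str] = ("*",),
) -> FeatureTable:
    """Load selected wells and glob-matched feature columns from a store.

    Column order follows the store's feature-name order; rows keep the
    stored cell order restricted to the requested wells.
    """
    table = store.get_features()
    available = sorted(set(table.cells["well_id"]))
    unknown = [w for w in well_ids if w not in available]
    if unknown:
        raise KeyError(
            f"unknown well(s) {unknown}; available wells: {available}"
        )
    names = [
        n for n in table.feature_names
        if any(fnmatch.fnmatchcase(n, p) for p in feature_name_patterns)
    ]
    if not names:
        warnings.warn(
            f"patterns {list(feature_name_patterns)} match no features",
            stacklevel=2,
        )
    row_mask = table.cells["well_id"].isin(well_ids).to_numpy()
    sub = table.select_rows(row_mask)
    if not names:
        return FeatureTable(np.empty((sub.n_cells, 0)), [], sub.cells)
    return sub.select_columns(names)
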