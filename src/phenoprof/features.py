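"""Combinatorial single-cell feature extraction.

A feature is a (type, sub-measure, markers, regions) combination, named by
the grammar::

    <type[_submeasure]>:<Marker>[-<Marker>]:<region>[-<region>]

for example ``fraction_total_intensity:ERK:dna_region-cell_region`` (fraction
of the total ERK intensity of the cell that falls in the nucleus) or
``total_intensity_ratio:Tubulin-ERK:nondna_region-dna_region`` (total
cytoplasmic tubulin over total nuclear ERK).  Morphology features carry no
marker and render with an empty marker segment, e.g.
``morphology_area::cell_region``.

A feature configuration selects, per feature type, the markers and region
tokens of interest; :func:`enumerate_features` expands it deterministically
into the full list of named features (ratios over all ordered pairs of the
selected regions, fractions over nested region pairs only), and
:func:`extract_features` evaluates them for every segmented cell.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd
from skimage.measure import regionprops

from .containers import CELL_INDEX_COLUMNS, ChannelStack, FeatureTable
from .regions import REGION_TOKENS, RegionMasks, derive_regions, is_nested
from .segmentation import SegmentationResult

FEATURE_TYPES = (
    "morphology",
    "intensity",
    "fraction_total_intensity",
    "total_intensity_ratio",
    "pixel_correlation",
)

#: Morphology sub-measures (region-geometry, marker-free).
MORPHOLOGY_MEASURES = (
    "area",
    "perimeter",
    "form_factor",
    "eccentricity",
    "solidity",
    "equivalent_diameter",
    "major_axis_length",
    "minor_axis_length",
)

#: Intensity sub-measures over the masked pixels of one marker.
INTENSITY_MEASURES = ("total", "mean", "std", "median", "mad", "min", "max")


class FeatureNameError(ValueError):
    """Raised for a feature name that does not conform to the grammar."""


@dataclass(frozen=True)
class FeatureSpec:
    """One named feature: type, optional sub-measure, markers and regions."""

    feature_type: str
    sub_measure: str = ""
    markers: tuple[str, ...] = ()
    regions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.feature_type!r}")
        for r in self.regions:
            if r not in REGION_TOKENS:
                raise ValueError(f"unknown region token {r!r}")
        t = self.feature_type
        nm, nr = len(self.markers), len(self.regions)
        ok = {
            "morphology": nm == 0 and nr == 1,
            "intensity": nm == 1 and nr == 1,
            "fraction_total_intensity": nm == 1 and nr == 2,
            "total_intensity_ratio": nm in (1, 2) and nr == 2,
            "pixel_correlation": nm == 2 and nr == 1,
        }[t]
        if not ok:
            raise ValueError(
                f"{t} cannot take {nm} markers and {nr} regions"
            )
        if t in ("morphology", "intensity") and not self.sub_measure:
            raise ValueError(f"{t} requires a sub-measure")
        if t not in ("morphology", "intensity") and self.sub_measure:
            raise ValueError(f"{t} takes no sub-measure")


def render_name(spec: FeatureSpec) -> str:
    """Render a FeatureSpec as its canonical feature name."""
    head = spec.feature_type
    if spec.sub_measure:
        head = f"{head}_{spec.sub_measure}"
    return ":".join([head, "-".join(spec.markers), "-".join(spec.regions)])


def parse_name(name: str) -> FeatureSpec:
    """Parse a feature name back into a FeatureSpec (inverse of render)."""
    parts = name.split(":")
    if len(parts) != 3:
        raise FeatureNameError(
            f"{name!r}: expected 3 colon-separated segments, got {len(parts)}"
        )
    head, marker_seg, region_seg = parts
    ftype = next(
        (t for t in sorted(FEATURE_TYPES, key=len, reverse=True)
         if head == t or head.startswith(t + "_")),
        None,
    )
    if ftype is None:
        raise FeatureNameError(f"{name!r}: unknown feature type in {head!r} "
                               f"(error at position 0)")
    sub = head[len(ftype) + 1:] if head != ftype else ""
    if ftype == "morphology" and sub not in MORPHOLOGY_MEASURES:
        raise FeatureNameError(f"{name!r}: unknown morphology measure {sub!r}")
    if ftype == "intensity" and sub not in INTENSITY_MEASURES:
        raise FeatureNameError(f"{name!r}: unknown intensity measure {sub!r}")
    markers = tuple(m for m in marker_seg.split("-") if m)
    regions = tuple(_split_regions(region_seg, name))
    try:
        return FeatureSpec(ftype, sub, markers, regions)
    except ValueError as exc:
        raise FeatureNameError(f"{name!r}: {exc}") from exc


def _split_regions(seg: str, name: str) -> list[str]:
    # region tokens contain underscores but never hyphens, so '-' separates
    out = [r for r in seg.split("-") if r]
    for r in out:
        if r not in REGION_TOKENS:
            pos = name.index(r) if r in name else len(name)
            raise FeatureNameError(
                f"{name!r}: unknown region token {r!r} (error at position {pos})"
            )
    return out


# ---------------------------------------------------------------------------
# configuration expansion


@dataclass
class FeatureConfig:
    """Selected markers/regions per feature type (the selection matrix).

    ``morphology``: list of region tokens.
    ``intensity``: marker -> list of regions (or a flat dict with
    ``markers``/``regions`` lists applied as a full cross product).
    ``fraction_total_intensity``: markers + regions; expanded over nested
    ordered region pairs (numerator a subset of denominator).
    ``total_intensity_ratio``: markers + regions; each single marker is
    expanded over all ordered pairs of distinct regions, and explicit
    ``marker_pairs`` entries likewise.
    ``pixel_correlation``: markers + regions; unordered marker pairs.
    """

    morphology: dict = field(default_factory=dict)
    intensity: dict = field(default_factory=dict)
    fraction_total_intensity: dict = field(default_factory=dict)
    total_intensity_ratio: dict = field(default_factory=dict)
    pixel_correlation: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown feature types in config: {sorted(unknown)}")
        return cls(**{k: (v or {}) for k, v in d.items()})

    def required_markers(self) -> set[str]:
        req: set[str] = set()
        for block in (self.intensity, self.fraction_total_intensity,
                      self.total_intensity_ratio, self.pixel_correlation):
            req.update(block.get("markers", []))
            for pair in block.get("marker_pairs", []):
                req.update(pair)
        return req


def enumerate_features(config: FeatureConfig | dict) -> list[FeatureSpec]:
    """Deterministically expand a feature configuration into FeatureSpecs."""
    if isinstance(config, dict):
        config = FeatureConfig.from_dict(config)
    specs: list[FeatureSpec] = []

    for region in config.morphology.get("regions", []):
        for m in MORPHOLOGY_MEASURES:
            specs.append(FeatureSpec("morphology", m, (), (region,)))

    blk = config.intensity
    for marker in blk.get("markers", []):
        for region in blk.get("regions", []):
            for m in INTENSITY_MEASURES:
                specs.append(FeatureSpec("intensity", m, (marker,), (region,)))

    blk = config.fraction_total_intensity
    for marker in blk.get("markers", []):
        for ra, rb in itertools.permutations(blk.get("regions", []), 2):
            if is_nested(ra, rb) and ra != rb:
                specs.append(
                    FeatureSpec("fraction_total_intensity", "", (marker,), (ra, rb))
                )

    blk = config.total_intensity_ratio
    region_pairs = list(itertools.permutations(blk.get("regions", []), 2))
    for marker in blk.get("markers", []):
        for ra, rb in region_pairs:
            specs.append(
                FeatureSpec("total_intensity_ratio", "", (marker,), (ra, rb))
            )
    for ma, mb in blk.get("marker_pairs", []):
        for ra, rb in region_pairs:
            specs.append(
                FeatureSpec("total_intensity_ratio", "", (ma, mb), (ra, rb))
            )

    blk = config.pixel_correlation
    markers = blk.get("markers", [])
    if markers and len(markers) < 2 and not blk.get("marker_pairs"):
        raise ValueError("pixel_correlation requires at least 2 markers")
    pairs = list(itertools.combinations(markers, 2)) + [
        tuple(p) for p in blk.get("marker_pairs", [])
    ]
    for ma, mb in pairs:
        for region in blk.get("regions", []):
            specs.append(FeatureSpec("pixel_correlation", "", (ma, mb), (region,)))

    names = [render_name(s) for s in specs]
    if len(set(names)) != len(names):
        seen, dup = set(), None
        for n in names:
            if n in seen:
                dup = n
                break
            seen.add(n)
        raise ValueError(f"configuration expands to duplicate feature {dup!r}")
    return specs


# ---------------------------------------------------------------------------
# per-cell measurements


def morphology_features(region_mask: np.ndarray) -> dict[str, float]:
    """Geometric measures of one (possibly non-convex) region mask."""
    mask = np.asarray(region_mask, dtype=bool)
    if not mask.any():
        return {m: float("nan") for m in MORPHOLOGY_MEASURES}
    props = regionprops(mask.astype(np.uint8))[0]
    area = float(props.area)
    perimeter = float(props.perimeter)
    out = {
        "area": area,
        "perimeter": perimeter,
        "form_factor": (4.0 * np.pi * area / perimeter**2
                        if perimeter > 0 else float("nan")),
        "eccentricity": float(props.eccentricity),
        "solidity": float(props.solidity),
        "equivalent_diameter": float(props.equivalent_diameter_area),
        "major_axis_length": float(props.axis_major_length),
        "minor_axis_length": float(props.axis_minor_length),
    }
    return out


def intensity_features(plane: np.ndarray, region_mask: np.ndarray) -> dict[str, float]:
    """Summary statistics of one marker's intensities over a region."""
    mask = np.asarray(region_mask, dtype=bool)
    if not mask.any():
        return {m: float("nan") for m in INTENSITY_MEASURES}
    v = np.asarray(plane, dtype=float)[mask]
    med = float(np.median(v))
    return {
        "total": float(v.sum()),
        "mean": float(v.mean()),
        "std": float(v.std()),  # population SD
        "median": med,
        "mad": float(np.median(np.abs(v - med))),
        "min": float(v.min()),
        "max": float(v.max()),
    }


def fraction_total_intensity(
    plane: np.ndarray, region_a: np.ndarray, region_b: np.ndarray
) -> float:
    """total(plane over A) / total(plane over B); NaN if the denominator is 0."""
    p = np.asarray(plane, dtype=float)
    tot_b = float(p[np.asarray(region_b, dtype=bool)].sum())
    if tot_b == 0:
        return float("nan")
    tot_a = float(p[np.asarray(region_a, dtype=bool)].sum())
    return tot_a / tot_b


def total_intensity_ratio(
    plane_a: np.ndarray,
    region_a: np.ndarray,
    plane_b: np.ndarray,
    region_b: np.ndarray,
) -> float:
    """totalA(regionA) / totalB(regionB); NaN if the denominator is 0."""
    tot_b = float(np.asarray(plane_b, dtype=float)[np.asarray(region_b, bool)].sum())
    if tot_b == 0:
        return float("nan")
    tot_a = float(np.asarray(plane_a, dtype=float)[np.asarray(region_a, bool)].sum())
    return tot_a / tot_b


def pixel_correlation(
    plane_a: np.ndarray, plane_b: np.ndarray, region: np.ndarray
) -> float:
    """Pearson correlation of two markers over a region; NaN if constant."""
    mask = np.asarray(region, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("pixel correlation needs a region of >= 2 pixels")
    a = np.asarray(plane_a, dtype=float)[mask]
    b = np.asarray(plane_b, dtype=float)[mask]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def evaluate_spec(
    spec: FeatureSpec, planes: dict[str, np.ndarray], masks: RegionMasks
) -> float:
    """Evaluate one FeatureSpec for one cell."""
    t = spec.feature_type
    if t == "morphology":
        return morphology_features(masks[spec.regions[0]])[spec.sub_measure]
    if t == "intensity":
        return intensity_features(
            planes[spec.markers[0]], masks[spec.regions[0]]
        )[spec.sub_measure]
    if t == "fraction_total_intensity":
        return fraction_total_intensity(
            planes[spec.markers[0]], masks[spec.regions[0]], masks[spec.regions[1]]
        )
    if t == "total_intensity_ratio":
        ma = spec.markers[0]
        mb = spec.markers[-1]
        return total_intensity_ratio(
            planes[ma], masks[spec.regions[0]], planes[mb], masks[spec.regions[1]]
        )
    if t == "pixel_correlation":
        region = masks[spec.regions[0]]
        if region.sum() < 2:
            return float("nan")
        return pixel_correlation(
            planes[spec.markers[0]], planes[spec.markers[1]], region
        )
    raise AssertionError(f"unhandled feature type {t}")  # pragma: no cover


def extract_features(
    seg: SegmentationResult,
    stack: ChannelStack,
    config: FeatureConfig | dict,
    w_nb: int = 2,
    w_pn: int = 4,
    w_cb: int = 3,
) -> FeatureTable:
    """Compute all configured features for every cell of one frame.

    Rows follow ascending cell label; columns follow enumeration order.
    Cells are processed independently on bounding-box crops.
    """
    if isinstance(config, dict):
        config = FeatureConfig.from_dict(config)
    missing = config.required_markers() - set(stack.markers)
    if missing:
        raise KeyError(
            f"feature config references markers absent from the stack: "
            f"{sorted(missing)}"
        )
    specs = enumerate_features(config)
    names = [render_name(s) for s in specs]

    labels = [int(l) for l in np.unique(seg.cells) if l > 0]
    values = np.full((len(labels), len(specs)), np.nan)
    index_rows = []
    for i, lab in enumerate(labels):
        cell = seg.cells == lab
        rows, cols = np.nonzero(cell)
        r0, r1 = rows.min(), rows.max() + 1
        c0, c1 = cols.min(), cols.max() + 1
        # pad so band morphology is not clipped by the crop
        pad = max(w_nb, w_pn, w_cb) + 1
        r0p, c0p = max(0, r0 - pad), max(0, c0 - pad)
        r1p = min(seg.cells.shape[0], r1 + pad)
        c1p = min(seg.cells.shape[1], c1 + pad)
        sl = (slice(r0p, r1p), slice(c0p, c1p))
        masks = derive_regions(
            cell[sl], (seg.nuclei == lab)[sl], w_nb=w_nb, w_pn=w_pn, w_cb=w_cb
        )
        planes = {m: stack[m].pixels[sl] for m in stack.markers}
        for j, spec in enumerate(specs):
            values[i, j] = evaluate_spec(spec, planes, masks)
        index_rows.append(
            (stack.well_id, stack.frame_index, lab,
             float(rows.mean()), float(cols.mean()))
        )

    cells = pd.DataFrame(index_rows, columns=list(CELL_INDEX_COLUMNS))
    if not labels:
        cells = pd.DataFrame(
            {c: pd.Series(dtype=("float" if "centroid" in c else "object"))
             for c in CELL_INDEX_COLUMNS}
        )
    return FeatureTable(values, names, cells)
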