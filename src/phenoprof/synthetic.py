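"""Seeded synthetic inputs with ground truth for every pipeline stage.

Two generators are provided:

- :func:`generate_scene` renders a multi-channel fluorescence frame
  (DNA plus cytoplasmic markers) of elliptical cells with contained nuclei,
  PSF blur and Gaussian read noise, returning the ground-truth nuclear and
  cell label masks alongside the images.  It emulates a cultured-cell
  monolayer of well-separated (or deliberately overlapping) cells.

- :func:`generate_population` draws per-cell feature populations with
  planted group structure emulating a multi-well siRNA screen: a
  negative-control population, several treatment groups that each shift
  their own block of informative features, and nuisance features that are
  identically distributed in all conditions but have strongly inflated
  variance (the high-variance, non-informative features that defeat naive
  profile averaging).

All randomness flows from one integer seed through ``numpy`` SeedSequence
spawning, so sub-components are independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import ellipse

from .containers import ChannelStack, FeatureTable, ImagePlane
from .segmentation import SegmentationResult

DEFAULT_MARKERS = ("DNA", "Actin", "Tubulin")


@dataclass
class SceneSpec:
    """Parameters of one rendered multi-channel frame.

    Intensity levels are 16-bit counts; radii are semi-axes in pixels.
    ``overlap`` > 0 shrinks the minimum centre separation so neighbouring
    cells (and their foregrounds) can touch.
    """

    shape: tuple[int, int] = (256, 256)
    n_cells: int = 20
    nucleus_radius: tuple[float, float] = (6.0, 9.0)
    cell_radius: tuple[float, float] = (13.0, 17.0)
    overlap: float = 0.0
    markers: tuple[str, ...] = DEFAULT_MARKERS
    dna_level: float = 8000.0
    cyto_level: float = 3000.0
    background: float = 200.0
    noise_sd: float = 100.0
    blur_sigma: float = 1.0
    seed: int = 0
    well_id: str = "A01"
    frame_index: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.nucleus_radius[0] < 2 or self.cell_radius[0] < 2:
            raise ValueError("radii must be >= 2 px")
        if self.nucleus_radius[1] >= self.cell_radius[0]:
            raise ValueError("nuclei must fit inside cells")


def _place_cells(spec: SceneSpec, rng: np.random.Generator):
    """Rejection-sample non-degenerate ellipse parameters for each cell."""
    h, w = spec.shape
    placed = []  # (row, col, cell_a, cell_b, nuc_a, nuc_b, theta)
    max_r = spec.cell_radius[1]
    min_sep_scale = 1.0 - spec.overlap
    for _ in range(spec.n_cells):
        for attempt in range(500):
            a = rng.uniform(*spec.cell_radius)            # major semi-axis
            b = a * rng.uniform(0.75, 1.0)                # minor semi-axis
            theta = rng.uniform(0, np.pi)
            r = rng.uniform(max_r + 2, h - max_r - 3)
            c = rng.uniform(max_r + 2, w - max_r - 3)
            ok = all(
                np.hypot(r - pr, c - pc) >= min_sep_scale * (a + pa) + 2
                for pr, pc, pa, *_ in placed
            )
            if ok:
                nuc_scale = rng.uniform(
                    spec.nucleus_radius[0] / a,
                    min(spec.nucleus_radius[1] / a, 0.95),
                )
                placed.append((r, c, a, b, a * nuc_scale, b * nuc_scale, theta))
                break
        else:
            raise RuntimeError(
                f"could not place {spec.n_cells} cells of radius <= {max_r} "
                f"in a {h}x{w} frame; reduce n_cells or radii"
            )
    return placed


def generate_scene(spec: SceneSpec) -> tuple[ChannelStack, SegmentationResult]:
    """Render one frame and return it with its ground-truth masks."""
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(spec.seed)))
    h, w = spec.shape
    cells = np.zeros(spec.shape, dtype=np.int32)
    nuclei = np.zeros(spec.shape, dtype=np.int32)

    for lab, (r, c, a, b, na, nb, theta) in enumerate(
        _place_cells(spec, rng), start=1
    ):
        rr, cc = ellipse(r, c, a, b, shape=spec.shape, rotation=theta)
        cells[rr, cc] = lab
        rr, cc = ellipse(r, c, na, nb, shape=spec.shape, rotation=theta)
        nuclei[rr, cc] = lab

    planes: dict[str, ImagePlane] = {}
    for marker in spec.markers:
        canvas = np.full(spec.shape, spec.background, dtype=float)
        if marker == "DNA":
            for lab in range(1, spec.n_cells + 1):
                canvas[nuclei == lab] += spec.dna_level * rng.uniform(0.85, 1.15)
        else:
            for lab in range(1, spec.n_cells + 1):
                canvas[cells == lab] += spec.cyto_level * rng.uniform(0.8, 1.2)
        if spec.blur_sigma > 0:
            canvas = ndi.gaussian_filter(canvas, spec.blur_sigma)
        canvas += rng.normal(0.0, spec.noise_sd, size=spec.shape)
        pixels = np.clip(np.rint(canvas), 0, 65535).astype(np.uint16)
        planes[marker] = ImagePlane(
            pixels, 16, marker, spec.well_id, spec.frame_index
        )

    stack = ChannelStack(planes, spec.well_id, spec.frame_index)
    truth = SegmentationResult(nuclei, cells)
    if spec.n_cells and spec.overlap == 0:
        truth.validate()
    return stack, truth


def two_disc_nuclei_frame(
    radius: float = 8.0,
    separation_factor: float = 1.5,
    shape: tuple[int, int] = (96, 96),
    seed: int = 0,
    **scene_kwargs,
) -> tuple[ChannelStack, SegmentationResult]:
    """A frame whose two nuclei are discs ``separation_factor * radius`` apart.

    At separations below 2 radii the discs merge into one connected bright
    blob, exercising the watershed split of touching nuclei.
    """
    rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(seed)))
    spec = SceneSpec(shape=shape, n_cells=0, seed=seed, **scene_kwargs)
    h, w = shape
    sep = separation_factor * radius
    cy, cx = h / 2 + rng.uniform(-3, 3), w / 2 + rng.uniform(-3, 3)
    theta = rng.uniform(0, np.pi)
    dy, dx = sep / 2 * np.sin(theta), sep / 2 * np.cos(theta)
    nuclei = np.zeros(shape, dtype=np.int32)
    for lab, (r, c) in enumerate(((cy - dy, cx - dx), (cy + dy, cx + dx)), 1):
        rr, cc = ellipse(r, c, radius, radius, shape=shape)
        nuclei[rr, cc] = np.where(nuclei[rr, cc] == 0, lab, nuclei[rr, cc])

    canvas = np.full(shape, spec.background, dtype=float)
    canvas[nuclei > 0] += spec.dna_level
    canvas = ndi.gaussian_filter(canvas, spec.blur_sigma)
    canvas += rng.normal(0.0, spec.noise_sd, size=shape)
    pixels = np.clip(np.rint(canvas), 0, 65535).astype(np.uint16)
    plane = ImagePlane(pixels, 16, "DNA", "A01", 0)
    stack = ChannelStack({"DNA": plane}, "A01", 0)
    return stack, SegmentationResult(nuclei, np.where(nuclei > 0, nuclei, 0))


@dataclass
class PopulationSpec:
    """Design of a planted-structure feature population.

    The control population is multivariate Gaussian with zero mean; the
    first ``groups * informative_per_group`` features are informative
    (unit control SD), each group shifting only its own block by
    ``effect_size`` control SDs (jittered ~10% per treatment so treatments
    within a group are similar but not identical).  The remaining
    ``nuisance_features`` share their distribution across all conditions
    but with SD ``sqrt(variance_inflation)`` — high variance, no group
    information.
    """

    groups: int = 4
    treatments_per_group: int = 8
    cells_per_treatment: int = 200
    control_cells: int = 400
    informative_per_group: int = 5
    effect_size: float = 4.0
    nuisance_features: int = 50
    variance_inflation: float = 1600.0
    seed: int = 0
    group_names: tuple[str, ...] = ("actin", "tubulin", "rna_synth", "protein_synth")

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        for f in ("groups", "treatments_per_group", "cells_per_treatment",
                  "control_cells", "informative_per_group"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")

    @property
    def n_features(self) -> int:
        return self.groups * self.informative_per_group + self.nuisance_features

    @property
    def informative_slice(self) -> slice:
        return slice(0, self.groups * self.informative_per_group)

    def group_block(self, g: int) -> slice:
        k = self.informative_per_group
        return slice(g * k, (g + 1) * k)


def _feature_names(spec: PopulationSpec) -> list[str]:
    names = [
        f"informative_g{g}_{i}"
        for g in range(spec.groups)
        for i in range(spec.informative_per_group)
    ]
    names += [f"nuisance_{i}" for i in range(spec.nuisance_features)]
    return names


def _draw_cells(
    n: int, spec: PopulationSpec, shift: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    sd = np.ones(spec.n_features)
    sd[spec.groups * spec.informative_per_group:] = np.sqrt(spec.variance_inflation)
    return shift + rng.normal(0.0, 1.0, size=(n, spec.n_features)) * sd


def generate_population(
    spec: PopulationSpec,
) -> tuple[dict[str, FeatureTable], FeatureTable, dict[str, str]]:
    """Draw the treatment tables, the control table and the group map."""
    ss = np.random.SeedSequence(spec.seed)
    child = ss.spawn(spec.groups * spec.treatments_per_group + 1)
    names = _feature_names(spec)

    def table(values: np.ndarray, well: str) -> FeatureTable:
        cells = pd.DataFrame(
            {
                "well_id": well,
                "frame_index": 0,
                "cell_label": np.arange(1, values.shape[0] + 1),
                "centroid_row": np.nan,
                "centroid_col": np.nan,
            }
        )
        return FeatureTable(values, names, cells)

    rng = np.random.Generator(np.random.Philox(child[0]))
    control = table(
        _draw_cells(spec.control_cells, spec, np.zeros(spec.n_features), rng),
        "CTRL",
    )

    tables: dict[str, FeatureTable] = {}
    group_map: dict[str, str] = {}
    idx = 1
    for g in range(spec.groups):
        gname = (spec.group_names[g] if g < len(spec.group_names)
                 else f"group{g}")
        for t in range(spec.treatments_per_group):
            rng = np.random.Generator(np.random.Philox(child[idx]))
            idx += 1
            shift = np.zeros(spec.n_features)
            jitter = rng.normal(1.0, 0.1, size=spec.informative_per_group)
            shift[spec.group_block(g)] = spec.effect_size * jitter
            tid = f"{gname}_kd{t:02d}"
            tables[tid] = table(
                _draw_cells(spec.cells_per_treatment, spec, shift, rng), tid
            )
            group_map[tid] = gname
    return tables, control, group_map


def informative_feature_names(spec: PopulationSpec) -> list[str]:
    """Names of the planted informative features (all groups' blocks)."""
    return _feature_names(spec)[spec.informative_slice]
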