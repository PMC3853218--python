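"""Two-step seeded-watershed cell segmentation.

Step 1 detects nuclei from the DNA channel: Gaussian smoothing, an h-dome
transform to flatten uneven background while keeping local intensity peaks,
Otsu thresholding of the dome image gated by a negative Laplacian-of-Gaussian
response (bright-blob interiors), morphological cleanup, and a watershed on
the negated distance transform to break apart touching nuclei.

Step 2 detects cell bodies: a composite image is formed as a weighted linear
combination of the fluorescence channels, thresholded with Otsu's method, and
partitioned by a seeded watershed that floods the inverted composite from the
nuclear regions, so every cell inherits the label of its nucleus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology
from skimage.measure import label as cc_label
from skimage.segmentation import relabel_sequential, watershed

from .containers import ChannelStack, ImagePlane

logger = logging.getLogger(__name__)

DNA_MARKER = "DNA"


class DegenerateImageError(ValueError):
    """Raised when an operation needs intensity contrast the image lacks."""


@dataclass
class SegmentationParams:
    """Tunable parameters of the two-step segmentation.

    h : h-dome height in intensity units; ``None`` selects 80% of the
        smoothed plane's dynamic range, so the dome transform removes the
        slowly-varying background while retaining the full amplitude of
        the nuclear blobs rather than just their peak caps.
    log_sigma : scale (pixels) of the Laplacian-of-Gaussian blob gate;
        match to the expected nuclear radius.
    smoothing_sigma : Gaussian pre-smoothing (pixels) applied to both the
        DNA plane and the composite.
    min_nucleus_area / min_cell_area : components smaller than these (pixels)
        are discarded.
    channel_weights : marker -> weight for the composite; ``None`` weights
        every non-DNA marker equally and DNA zero.
    border_policy : ``"keep"`` or ``"remove"`` cells touching the image edge.
    min_contrast_snr : minimum foreground-background contrast, in units of
        the background SD of the smoothed DNA plane, below which a frame is
        treated as empty (guards against thresholding pure noise).
    """

    h: float | None = None
    log_sigma: float = 5.0
    smoothing_sigma: float = 2.0
    min_nucleus_area: int = 40
    min_cell_area: int = 100
    channel_weights: dict[str, float] | None = None
    border_policy: str = "keep"
    min_contrast_snr: float = 5.0
    dna_marker: str = DNA_MARKER

    def __post_init__(self) -> None:
        if self.h is not None and self.h <= 0:
            raise ValueError("h must be positive")
        if self.log_sigma <= 0 or self.smoothing_sigma < 0:
            raise ValueError("sigmas must be positive")
        if self.min_nucleus_area < 1 or self.min_cell_area < 1:
            raise ValueError("minimum areas must be >= 1 pixel")
        if self.border_policy not in ("keep", "remove"):
            raise ValueError("border_policy must be 'keep' or 'remove'")


@dataclass
class SegmentationResult:
    """Paired nuclear and cell label masks.

    Labels are 1..K with no gaps; nucleus k lies inside cell k, so
    ``label_map`` is the identity on 1..K after any public operation.
    """

    nuclei: np.ndarray
    cells: np.ndarray
    label_map: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nuclei = np.asarray(self.nuclei)
        self.cells = np.asarray(self.cells)
        if self.nuclei.shape != self.cells.shape:
            raise ValueError("nuclei and cells masks must share dimensions")
        if not self.label_map:
            self.label_map = {int(k): int(k) for k in np.unique(self.nuclei) if k > 0}

    @property
    def n_cells(self) -> int:
        return int(self.cells.max())

    def validate(self) -> None:
        """Assert the nucleus-inside-cell pairing invariants."""
        nuc_labels = set(np.unique(self.nuclei)) - {0}
        cell_labels = set(np.unique(self.cells)) - {0}
        if nuc_labels != cell_labels:
            raise AssertionError(
                f"nucleus labels {nuc_labels} != cell labels {cell_labels}"
            )
        inside = self.nuclei > 0
        if not np.array_equal(self.nuclei[inside], self.cells[inside]):
            raise AssertionError("some nucleus pixels lie outside their cell")


def hdome(image: np.ndarray, h: float) -> np.ndarray:
    """Extract local intensity peaks of height at most ``h``.

    Grayscale reconstruction by dilation of ``image - h`` under ``image``
    flattens everything but the tops of local maxima; subtracting the
    reconstruction from the image leaves the domes, with values in [0, h].
    """
    if h <= 0:
        raise ValueError("h-dome height h must be positive")
    img = np.asarray(image, dtype=float)
    if img.min() == img.max():
        # an unbounded plateau has no surroundings, hence no domes
        return np.zeros_like(img)
    rec = morphology.reconstruction(img - h, img, method="dilation")
    return np.clip(img - rec, 0.0, h)


def log_filter(image: np.ndarray, sigma: float) -> np.ndarray:
    """Laplacian-of-Gaussian response at scale ``sigma`` (zero-sum kernel).

    Bright blobs of radius ~ sigma*sqrt(2) give a negative response in
    their interior.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    img = np.asarray(image, dtype=float)
    out = ndi.gaussian_laplace(img, sigma)
    # the truncated discrete kernel does not sum exactly to zero; subtract
    # the residual DC gain so a constant image maps to zero response
    eps = float(ndi.gaussian_laplace(np.ones((1, 1)), sigma, mode="reflect")[0, 0])
    return out - eps * img


def otsu_threshold(image: np.ndarray) -> float:
    """Histogram threshold maximizing between-class variance.

    A 256-bin histogram is built over the image's value range and the bin
    centre maximizing the between-class variance of the induced two-class
    split is returned.  Foreground is defined as pixels strictly greater
    than the threshold.
    """
    vals = np.asarray(image, dtype=float).ravel()
    lo, hi = vals.min(), vals.max()
    if lo == hi:
        raise DegenerateImageError("constant image has no Otsu threshold")
    hist, edges = np.histogram(vals, bins=256, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = hist.astype(float)
    cw0 = np.cumsum(w)[:-1]                      # class 0 = bins 0..i
    cw1 = w.sum() - cw0
    csum0 = np.cumsum(w * centers)[:-1]
    mu0 = np.divide(csum0, cw0, out=np.zeros_like(csum0), where=cw0 > 0)
    csum1 = (w * centers).sum() - csum0
    mu1 = np.divide(csum1, cw1, out=np.zeros_like(csum1), where=cw1 > 0)
    sigma_b = cw0 * cw1 * (mu0 - mu1) ** 2
    return float(centers[int(np.argmax(sigma_b))])


def _drop_small(labels: np.ndarray, min_area: int) -> np.ndarray:
    """Zero out labels occupying fewer than ``min_area`` pixels."""
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_area)
    if small.size:
        labels = np.where(np.isin(labels, small[small > 0]), 0, labels)
    return labels


def _split_touching(fg: np.ndarray, smooth_sigma: float = 1.0) -> np.ndarray:
    """Break apart touching components with a distance-transform watershed.

    Seeds are the regional maxima of the Gaussian-smoothed Euclidean
    distance transform; flooding the negated distance map assigns each
    foreground pixel to the nearest seed's basin (4-connected flow).
    """
    if not fg.any():
        return np.zeros(fg.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(fg)
    sm = ndi.gaussian_filter(dist, smooth_sigma)
    peaks = morphology.local_maxima(sm, connectivity=2) & fg
    markers = cc_label(peaks, connectivity=2)
    if markers.max() == 0:
        return cc_label(fg, connectivity=2).astype(np.int32)
    return watershed(-sm, markers=markers, mask=fg, connectivity=1).astype(np.int32)


def detect_nuclei(dna: ImagePlane, params: SegmentationParams) -> np.ndarray:
    """Detect nuclei in the DNA channel; returns a label mask (0=background)."""
    img = np.asarray(dna.pixels, dtype=float)
    smooth = ndi.gaussian_filter(img, params.smoothing_sigma)
    rng = smooth.max() - smooth.min()
    if rng == 0:
        logger.warning("constant DNA plane for well=%s frame=%d; no nuclei",
                       dna.well_id, dna.frame_index)
        return np.zeros(img.shape, dtype=np.int32)
    h = params.h if params.h is not None else 0.8 * rng
    domes = hdome(smooth, h)
    try:
        thr = otsu_threshold(domes)
    except DegenerateImageError:
        return np.zeros(img.shape, dtype=np.int32)
    fg = ndi.binary_fill_holes(domes > thr)

    # contrast guard: a threshold that separates noise from noise is not a
    # nucleus detection; require the foreground to stand clear of the
    # background by several background standard deviations
    bg = ~fg
    if not fg.any() or not bg.any():
        return np.zeros(img.shape, dtype=np.int32)
    contrast = smooth[fg].mean() - smooth[bg].mean()
    if contrast < params.min_contrast_snr * max(smooth[bg].std(), 1e-12):
        logger.warning("foreground/background contrast too low for well=%s "
                       "frame=%d; treating the frame as empty",
                       dna.well_id, dna.frame_index)
        return np.zeros(img.shape, dtype=np.int32)

    # component-level LoG gate: bright blobs have a negative mean response
    # at the matched scale, flat bright debris does not
    logr = log_filter(smooth, params.log_sigma)
    comps = cc_label(fg, connectivity=2)
    mean_log = ndi.mean(logr, labels=comps, index=np.arange(1, comps.max() + 1))
    blobby = np.concatenate([[False], mean_log < 0])
    fg = blobby[comps]
    fg = _drop_small(cc_label(fg, connectivity=2), params.min_nucleus_area) > 0
    if not fg.any():
        logger.warning("no nuclei found for well=%s frame=%d",
                       dna.well_id, dna.frame_index)
        return np.zeros(img.shape, dtype=np.int32)
    labels = _split_touching(fg)
    labels = _drop_small(labels, params.min_nucleus_area)
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def composite_image(
    stack: ChannelStack, channel_weights: dict[str, float]
) -> np.ndarray:
    """Pixelwise weighted sum of the stack's planes, in floating point."""
    missing = set(channel_weights) - set(stack.markers)
    if missing:
        raise KeyError(f"channel weights given for markers absent from the "
                       f"stack: {sorted(missing)}")
    if not any(wgt > 0 for wgt in channel_weights.values()):
        raise ValueError("at least one channel weight must be positive")
    out = np.zeros(stack.shape, dtype=float)
    for marker in sorted(channel_weights):
        out += channel_weights[marker] * stack[marker].pixels.astype(float)
    return out


def default_channel_weights(
    markers: list[str], dna_marker: str = DNA_MARKER
) -> dict[str, float]:
    """Equal weights over non-DNA markers, zero for DNA."""
    others = [m for m in markers if m != dna_marker]
    if not others:  # DNA-only stack: segment cells on the DNA channel
        return {dna_marker: 1.0}
    return {m: (1.0 / len(others) if m in others else 0.0) for m in markers}


def detect_cells(
    composite: np.ndarray, nuclei: np.ndarray, params: SegmentationParams
) -> SegmentationResult:
    """Partition the composite foreground into cells seeded at the nuclei."""
    nuclei = np.asarray(nuclei)
    if nuclei.max() == 0:
        empty = np.zeros(nuclei.shape, dtype=np.int32)
        return SegmentationResult(empty, empty.copy())
    smooth = ndi.gaussian_filter(np.asarray(composite, dtype=float),
                                 params.smoothing_sigma)
    try:
        thr = otsu_threshold(smooth)
        fg = smooth > thr
    except DegenerateImageError:
        fg = np.zeros(smooth.shape, dtype=bool)
    fg |= nuclei > 0
    cells = watershed(-smooth, markers=nuclei, mask=fg,
                      connectivity=1).astype(np.int32)

    drop: set[int] = set()
    labels, counts = np.unique(cells[cells > 0], return_counts=True)
    drop.update(int(l) for l, c in zip(labels, counts)
                if c < params.min_cell_area)
    if params.border_policy == "remove":
        edge = np.concatenate([cells[0], cells[-1], cells[:, 0], cells[:, -1]])
        drop.update(int(l) for l in np.unique(edge) if l > 0)
    if drop:
        kill = np.isin(cells, list(drop))
        cells = np.where(kill, 0, cells)
        nuclei = np.where(np.isin(nuclei, list(drop)), 0, nuclei)

    # one consistent relabelling so paired nucleus/cell labels stay aligned
    cells, fwd, _ = relabel_sequential(cells)
    nuclei = np.asarray(fwd)[nuclei]
    result = SegmentationResult(nuclei.astype(np.int32), cells.astype(np.int32))
    result.validate()
    return result


def segment_frame(
    stack: ChannelStack, params: SegmentationParams | None = None
) -> SegmentationResult:
    """Full two-step segmentation of one frame's channel stack."""
    params = params or SegmentationParams()
    if params.dna_marker not in stack.markers:
        raise KeyError(
            f"DNA marker {params.dna_marker!r} missing from stack markers "
            f"{stack.markers}"
        )
    nuclei = detect_nuclei(stack[params.dna_marker], params)
    weights = params.channel_weights or default_channel_weights(
        stack.markers, params.dna_marker
    )
    comp = composite_image(stack, weights)
    return detect_cells(comp, nuclei, params)
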