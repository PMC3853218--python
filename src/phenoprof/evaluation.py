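"""Accuracy criteria for segmentation masks and phenotypic profiles.

Segmentation is scored against a reference (manual) mask with two indices:

- the *boundary error* — the mean Euclidean distance from each boundary
  pixel of the reference mask to the nearest boundary pixel of the
  automated mask (asymmetric, reference -> automated);
- the *Rand error* — one minus the fraction of pixel pairs on which the two
  masks agree about being co-labelled, i.e. a partition distance in [0, 1].

Profile sets grouped by known biological function are scored with the cosine
dissimilarity d(g, h) = 1 - g.h / (|g||h|):

- ``intra_group`` — the maximum pairwise dissimilarity within each group,
  averaged over groups (compactness; lower is better);
- ``inter_group`` — for each ordered group pair, the mean of the n smallest
  cross-group dissimilarities, summed and scaled by 2/(N(N-1))
  (separation; higher is better).  Because the double sum visits each
  unordered pair twice, the statistic equals twice the mean over unordered
  pairs; method comparisons are unaffected by this monotone scaling.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Coordinates (N x 2, row-major order) of object boundary pixels.

    A foreground pixel is a boundary pixel if any of its 4-neighbours lies
    outside its own label (background or a different label), or if it sits
    on the image edge.
    """
    lab = np.asarray(mask)
    padded = np.pad(lab, 1, constant_values=-1)
    core = padded[1:-1, 1:-1]
    differs = np.zeros(lab.shape, dtype=bool)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neigh = padded[1 + dr:padded.shape[0] - 1 + dr,
                       1 + dc:padded.shape[1] - 1 + dc]
        differs |= neigh != core
    boundary = (lab > 0) & differs
    return np.argwhere(boundary)


def boundary_error(
    manual: np.ndarray, auto: np.ndarray, symmetric: bool = False
) -> float:
    """Mean distance from manual boundary pixels to the nearest auto one.

    With ``symmetric=True``, the average of both directions is returned.
    An empty automated boundary yields +inf with a warning.
    """
    manual = np.asarray(manual)
    auto = np.asarray(auto)
    if manual.shape != auto.shape:
        raise ValueError("masks must share dimensions")
    if symmetric:
        return 0.5 * (boundary_error(manual, auto) + boundary_error(auto, manual))
    b_manual = boundary_pixels(manual)
    if len(b_manual) == 0:
        raise ValueError("manual mask has no boundary pixels")
    b_auto = boundary_pixels(auto)
    if len(b_auto) == 0:
        warnings.warn("automated mask has no boundary pixels; boundary "
                      "error is infinite", stacklevel=2)
        return float("inf")
    # exact Euclidean distance-to-nearest via the distance transform of the
    # complement of the auto boundary set
    on_auto = np.zeros(auto.shape, dtype=bool)
    on_auto[tuple(b_auto.T)] = True
    dist = ndi.distance_transform_edt(~on_auto)
    return float(dist[tuple(b_manual.T)].mean())


def _pair_counts(labels: np.ndarray) -> np.ndarray:
    """Per-region pixel counts, background included as one region."""
    return np.bincount(labels.ravel())


def rand_error(
    manual: np.ndarray, auto: np.ndarray, ignore_background: bool = False
) -> float:
    """Rand error index between two label masks.

    1 - (c + d)/C(N, 2) where c counts pixel pairs co-labelled in both
    partitions and d pairs separated in both.  The background is treated as
    one additional region so that every pixel is partitioned; with
    ``ignore_background=True`` only pixels that are foreground in the
    manual mask enter the pair counts.
    """
    manual = np.asarray(manual).astype(np.int64)
    auto = np.asarray(auto).astype(np.int64)
    if manual.shape != auto.shape:
        raise ValueError("masks must share dimensions")
    m = manual.ravel()
    a = auto.ravel()
    if ignore_background:
        keep = m > 0
        m, a = m[keep], a[keep]
    n = m.size
    if n < 2:
        raise ValueError("need at least 2 pixels to form pairs")

    def sum_c2(counts: np.ndarray) -> float:
        c = counts.astype(float)
        return float((c * (c - 1) / 2).sum())

    # contingency via joint codes
    joint = m * (a.max() + 1) + a
    n_ij = np.bincount(joint)
    total_pairs = n * (n - 1) / 2
    c = sum_c2(n_ij)
    d = total_pairs - sum_c2(np.bincount(m)) - sum_c2(np.bincount(a)) + c
    return float(1.0 - (c + d) / total_pairs)


# ---------------------------------------------------------------------------
# profile dissimilarities


def cosine_dissimilarity(g: np.ndarray, h: np.ndarray) -> float:
    """1 - cos(angle between g and h); range [0, 2]."""
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    if g.shape != h.shape:
        raise ValueError("profiles must have equal length")
    ng, nh = np.linalg.norm(g), np.linalg.norm(h)
    if ng == 0 or nh == 0:
        raise ValueError("cosine dissimilarity undefined for a zero vector")
    return float(1.0 - float(g @ h) / (ng * nh))


def _grouped_vectors(profile_set) -> dict[str, list[np.ndarray]]:
    """group_id -> list of profile vectors, insertion-ordered."""
    groups: dict[str, list[np.ndarray]] = {}
    for p in profile_set.profiles:
        groups.setdefault(p.group_id, []).append(np.asarray(p.values, float))
    return groups


def intra_group(profile_set) -> float:
    """Average over groups of the maximum within-group dissimilarity."""
    groups = _grouped_vectors(profile_set)
    maxima = []
    for gid, vecs in groups.items():
        if len(vecs) < 2:
            raise ValueError(f"group {gid!r} needs >= 2 profiles")
        dmax = max(
            cosine_dissimilarity(vecs[i], vecs[j])
            for i in range(len(vecs))
            for j in range(i + 1, len(vecs))
        )
        maxima.append(dmax)
    return float(np.mean(maxima))


def inter_group(profile_set, n: int) -> float:
    """n-nearest-neighbour inter-group dissimilarity.

    For each ordered pair of distinct groups (j, k), the cross-group
    dissimilarities are sorted ascending and the mean of the n smallest is
    taken; the ordered-pair sums are scaled by 2/(N(N-1)).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    groups = _grouped_vectors(profile_set)
    ids = list(groups)
    n_groups = len(ids)
    if n_groups < 2:
        raise ValueError("need >= 2 groups")
    total = 0.0
    for j in ids:
        for k in ids:
            if j == k:
                continue
            dists = sorted(
                cosine_dissimilarity(g, h)
                for g in groups[j]
                for h in groups[k]
            )
            if n > len(dists):
                raise ValueError(
                    f"n={n} exceeds the {len(dists)} cross distances for "
                    f"groups ({j!r}, {k!r})"
                )
            total += float(np.mean(dists[:n]))
    return float(2.0 / (n_groups * (n_groups - 1)) * total)


def evaluate_masks(
    manual: np.ndarray, auto: np.ndarray, ignore_background: bool = False
) -> dict[str, float]:
    """Both segmentation indices for one frame pair."""
    return {
        "boundary_error": boundary_error(manual, auto),
        "rand_error": rand_error(manual, auto, ignore_background=ignore_background),
    }
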