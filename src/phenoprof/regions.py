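"""Decomposition of a segmented cell into eight subcellular regions.

Given a cell mask and its nucleus mask, the cell is split into nested and
banded regions with disc-structuring-element morphology:

- ``cell_region``            : the whole cell
- ``dna_region``             : the nucleus
- ``inner_dna_region``       : nucleus eroded by ``w_nb``
- ``dna_boundary_region``    : nucleus minus its interior (band of width w_nb)
- ``nondna_region``          : cytoplasm (cell minus nucleus)
- ``peri_dna_region``        : band of width ``w_pn`` around the nucleus,
                               clipped to the cytoplasm
- ``nondna_boundary_region`` : band of width ``w_cb`` inside the cell edge,
                               restricted to cytoplasm, minus the
                               peri-nuclear band (peri-nucleus wins overlaps)
- ``inner_nondna_region``    : remaining cytoplasm

The nucleus/cytoplasm pair partitions the cell; the boundary/inner pairs
partition the nucleus; and the three cytoplasmic subregions are pairwise
disjoint subsets of the cytoplasm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk

#: All region tokens, in canonical order.
REGION_TOKENS = (
    "cell_region",
    "dna_region",
    "dna_boundary_region",
    "inner_dna_region",
    "peri_dna_region",
    "nondna_region",
    "nondna_boundary_region",
    "inner_nondna_region",
)

#: region -> set of regions that are supersets of it (for nested-pair
#: feature enumeration).  Derived from the set identities above.
REGION_SUPERSETS: dict[str, set[str]] = {
    "cell_region": set(),
    "dna_region": {"cell_region"},
    "dna_boundary_region": {"dna_region", "cell_region"},
    "inner_dna_region": {"dna_region", "cell_region"},
    "peri_dna_region": {"nondna_region", "cell_region"},
    "nondna_region": {"cell_region"},
    "nondna_boundary_region": {"nondna_region", "cell_region"},
    "inner_nondna_region": {"nondna_region", "cell_region"},
}


def is_nested(inner: str, outer: str) -> bool:
    """True if region ``inner`` is by construction a subset of ``outer``."""
    return outer in REGION_SUPERSETS.get(inner, set()) or inner == outer


@dataclass
class RegionMasks:
    """The eight boolean region masks of one cell plus the band widths."""

    cell_region: np.ndarray
    dna_region: np.ndarray
    dna_boundary_region: np.ndarray
    inner_dna_region: np.ndarray
    peri_dna_region: np.ndarray
    nondna_region: np.ndarray
    nondna_boundary_region: np.ndarray
    inner_nondna_region: np.ndarray
    w_nb: int = 2
    w_pn: int = 4
    w_cb: int = 3

    def __getitem__(self, token: str) -> np.ndarray:
        if token not in REGION_TOKENS:
            raise KeyError(f"unknown region token {token!r}")
        return getattr(self, token)

    def validate(self) -> None:
        """Assert the partition/nesting/disjointness invariants."""
        cell, dna, nondna = self.cell_region, self.dna_region, self.nondna_region
        assert not (dna & nondna).any(), "dna and nondna overlap"
        assert ((dna | nondna) == cell).all(), "dna+nondna != cell"
        assert not (self.dna_boundary_region & self.inner_dna_region).any()
        assert (
            (self.dna_boundary_region | self.inner_dna_region) == dna
        ).all(), "boundary+inner != dna"
        cyto_sub = (
            self.peri_dna_region,
            self.nondna_boundary_region,
            self.inner_nondna_region,
        )
        for i, a in enumerate(cyto_sub):
            assert not (a & ~nondna).any(), "cytoplasmic subregion escapes cytoplasm"
            for b in cyto_sub[i + 1:]:
                assert not (a & b).any(), "cytoplasmic subregions overlap"
        assert (
            (cyto_sub[0] | cyto_sub[1] | cyto_sub[2]) == nondna
        ).all(), "cytoplasmic subregions do not cover the cytoplasm"


def derive_regions(
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    w_nb: int = 2,
    w_pn: int = 4,
    w_cb: int = 3,
) -> RegionMasks:
    """Derive the eight subcellular regions for one cell.

    Parameters
    ----------
    cell_mask, nucleus_mask : bool arrays
        Masks of a single cell and its nucleus; the nucleus must be a
        nonempty subset of the cell.
    w_nb, w_pn, w_cb : int
        Widths (pixels) of the nuclear-boundary, peri-nuclear and
        cytoplasmic-boundary bands.
    """
    cell = np.asarray(cell_mask, dtype=bool)
    nuc = np.asarray(nucleus_mask, dtype=bool)
    if cell.shape != nuc.shape:
        raise ValueError("cell and nucleus masks must share dimensions")
    if not nuc.any():
        raise ValueError("empty nucleus: nuclei define cells here")
    if (nuc & ~cell).any():
        raise ValueError("nucleus mask is not contained in the cell mask")
    for name, w in (("w_nb", w_nb), ("w_pn", w_pn), ("w_cb", w_cb)):
        if w < 1:
            raise ValueError(f"{name} must be >= 1 pixel")

    inner_dna = ndi.binary_erosion(nuc, structure=disk(w_nb))
    dna_boundary = nuc & ~inner_dna
    nondna = cell & ~nuc
    peri = ndi.binary_dilation(nuc, structure=disk(w_pn)) & nondna
    cell_rim = cell & ~ndi.binary_erosion(cell, structure=disk(w_cb))
    nondna_boundary = cell_rim & nondna & ~peri
    inner_nondna = nondna & ~peri & ~nondna_boundary

    masks = RegionMasks(
        cell_region=cell,
        dna_region=nuc,
        dna_boundary_region=dna_boundary,
        inner_dna_region=inner_dna,
        peri_dna_region=peri,
        nondna_region=nondna,
        nondna_boundary_region=nondna_boundary,
        inner_nondna_region=inner_nondna,
        w_nb=w_nb,
        w_pn=w_pn,
        w_cb=w_cb,
    )
    masks.validate()
    return masks
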