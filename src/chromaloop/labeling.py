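"""Ground-truth label matrices and the genomic-distance evaluation band.

ChIA-PET anchor pairs become a binary symmetric per-pixel label matrix: pixel
``(i, j)`` is positive iff bin ``i`` overlaps one anchor and bin ``j`` the
other anchor of some interaction.  Evaluation is restricted to the band of
genomic distances where interactions live (20 kb - 2 Mb; bins 2-200 at 10 kb,
2-400 at 5 kb).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Set, Tuple

import numpy as np

from .data_io import AnchorPair, GenomeGrid

BAND_MIN_BP = 20_000
BAND_MAX_BP = 2_000_000


@dataclass(frozen=True)
class LabelMatrix:
    grid: GenomeGrid
    labels: np.ndarray  # n x n, {0, 1}, symmetric


@dataclass(frozen=True)
class BandSpec:
    """Genomic-distance band in bins (inclusive bounds)."""

    d_min_bins: int
    d_max_bins: int

    def __post_init__(self) -> None:
        if not (0 < self.d_min_bins <= self.d_max_bins):
            raise ValueError("need 0 < d_min_bins <= d_max_bins")

    @classmethod
    def from_resolution(
        cls, resolution_bp: int, min_bp: int = BAND_MIN_BP, max_bp: int = BAND_MAX_BP
    ) -> "BandSpec":
        """Band bounds in bins from base-pair bounds.

        ``d_min = ceil(min_bp / r)``, ``d_max = floor(max_bp / r)``: bins 2-200
        at 10 kb resolution and 2-400 at 5 kb.
        """
        return cls(math.ceil(min_bp / resolution_bp), max_bp // resolution_bp)


def _anchor_bins(start: int, end: int, grid: GenomeGrid) -> range:
    """Bins whose half-open bp interval intersects [start, end) with length > 0."""
    r = grid.resolution_bp
    lo = max(0, start // r)
    hi = min(grid.n_bins, (end - 1) // r + 1)
    return range(lo, hi)


def anchors_to_label_matrix(
    pairs: Iterable[AnchorPair], grid: GenomeGrid
) -> LabelMatrix:
    """Binary label matrix from anchor pairs by strict interval intersection.

    A pixel is positive iff bin i's interval shares positive length with one
    anchor and bin j's with the other, for any pair; the result is symmetric
    and pixels outside the grid are ignored.
    """
    n = grid.n_bins
    lab = np.zeros((n, n), dtype=np.int8)
    for p in pairs:
        bins1 = _anchor_bins(p.start1, p.end1, grid)
        bins2 = _anchor_bins(p.start2, p.end2, grid)
        for i in bins1:
            for j in bins2:
                lab[i, j] = 1
                lab[j, i] = 1
    return LabelMatrix(grid, lab)


def band_mask(
    grid: GenomeGrid, band: BandSpec, unmappable: Set[int] = frozenset()
) -> Set[Tuple[int, int]]:
    """Upper-triangle pixels (i < j) with d_min <= j - i <= d_max.

    Pixels touching an unmappable bin are excluded.  Each interaction is
    represented once: the lower triangle is redundant by symmetry.
    """
    ii, jj = band_mask_arrays(grid, band, unmappable)
    return set(zip(ii.tolist(), jj.tolist()))


def band_mask_arrays(
    grid: GenomeGrid, band: BandSpec, unmappable: Set[int] = frozenset()
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized variant of :func:`band_mask`: sorted (i, j) index arrays."""
    n = grid.n_bins
    ok = np.ones(n, dtype=bool)
    if unmappable:
        ok[list(unmappable)] = False
    iis = []
    jjs = []
    for d in range(band.d_min_bins, min(band.d_max_bins, n - 1) + 1):
        i = np.arange(0, n - d)
        keep = ok[i] & ok[i + d]
        iis.append(i[keep])
        jjs.append(i[keep] + d)
    if not iis:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    ii = np.concatenate(iis)
    jj = np.concatenate(jjs)
    order = np.lexsort((jj, ii))
    return ii[order], jj[order]


def as_pixel_arrays(mask) -> Tuple[np.ndarray, np.ndarray]:
    """Normalize a pixel mask (set of tuples or pair of arrays) to sorted arrays."""
    if isinstance(mask, tuple) and len(mask) == 2:
        return np.asarray(mask[0], dtype=np.int64), np.asarray(mask[1], dtype=np.int64)
    pix = sorted(mask)
    if not pix:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    arr = np.asarray(pix, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def count_pos_neg(labels: LabelMatrix, mask) -> Tuple[int, int]:
    """Number of positive and negative pixels inside the mask."""
    ii, jj = as_pixel_arrays(mask)
    lab = np.asarray(labels.labels if isinstance(labels, LabelMatrix) else labels)
    n_pos = int(lab[ii, jj].sum())
    return n_pos, int(ii.size) - n_pos
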