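"""Tiled chromosome-wide prediction and deterministic pixel ranking.

A chromosome is tiled along the diagonal exactly as in training; each tile's
per-pixel probabilities are accumulated and every pixel's final score is the
mean over all tiles covering it, after which the matrix is symmetrized by
averaging with its transpose.  With the reference configuration (window 250,
step 50, band 2-200 bins) every evaluated pixel is covered by at least one
tile.  Shuffle controls (permuting the ChIP-seq vector or the Hi-C matrix)
probe what the model actually uses.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .data_io import BinnedTrack, ContactMatrix, GenomeGrid
from .network import DilatedResNet, predict_probs
from .preprocess import (
    NormStats,
    extract_samples,
    log_minmax,
    minmax_track,
    window_origins,
    zscore,
)

log = logging.getLogger(__name__)


@dataclass
class PredictionMatrix:
    grid: GenomeGrid
    probs: np.ndarray  # n x n in [0, 1], symmetric after finalization
    coverage: np.ndarray  # n x n ints, tiles averaged per pixel


def merge_tile_probs(
    tiles: List[Tuple[int, np.ndarray, int]], n: int
) -> Tuple[np.ndarray, np.ndarray]:
    """Average overlapping tile probabilities into one symmetric matrix.

    ``tiles`` holds ``(origin, W x W probs, valid_bins)``; only the valid
    (non-padded) part of each tile contributes.  Final probability is
    ``sum / coverage`` where covered, 0 elsewhere, then the matrix is averaged
    with its transpose (exactly symmetric in IEEE arithmetic).
    """
    sums = np.zeros((n, n), dtype=np.float64)
    cov = np.zeros((n, n), dtype=np.int64)
    for origin, probs, valid in tiles:
        sums[origin : origin + valid, origin : origin + valid] += probs[:valid, :valid]
        cov[origin : origin + valid, origin : origin + valid] += 1
    out = np.divide(sums, cov, out=np.zeros_like(sums), where=cov > 0)
    out = (out + out.T) / 2.0
    return out, cov


def predict_chromosome(
    model: DilatedResNet,
    hic: Optional[ContactMatrix],
    chip: Optional[BinnedTrack],
    stats: Dict[str, NormStats],
    W: int = 250,
    step: int = 50,
    mode: str = "both",
    batch_size: int = 1,
    shuffle: Optional[str] = None,
    shuffle_seed: int = 0,
) -> PredictionMatrix:
    """Predict one chromosome with frozen normalization statistics.

    ``shuffle`` ("shuffleHiC" / "shuffleChIPseq") applies the corresponding
    control permutation to the normalized input before tiling.
    """
    if hic is None and chip is None:
        raise ValueError("need Hi-C and/or ChIP-seq input")
    grid = hic.grid if hic is not None else chip.grid
    n = grid.n_bins
    use_hic = mode in ("hic_only", "both")
    use_chip = mode in ("chip_only", "both")
    if use_hic and hic is None:
        raise ValueError(f"mode {mode!r} requires Hi-C input")
    if use_chip and chip is None:
        raise ValueError(f"mode {mode!r} requires ChIP-seq input")

    hic_z = zscore(log_minmax(hic), stats["hic"]) if use_hic else None
    chip_z = zscore(minmax_track(chip), stats["chip"]) if use_chip else None
    if shuffle == "shuffleHiC":
        if hic_z is None:
            raise ValueError("shuffleHiC needs a Hi-C channel")
        hic_z = shuffle_control(hic_z, "shuffleHiC", shuffle_seed)
    elif shuffle == "shuffleChIPseq":
        if chip_z is None:
            raise ValueError("shuffleChIPseq needs a ChIP-seq channel")
        chip_z = shuffle_control(chip_z, "shuffleChIPseq", shuffle_seed)
    elif shuffle is not None:
        raise ValueError(f"unknown shuffle control {shuffle!r}")

    samples = extract_samples(hic_z, chip_z, None, W, step, mode, grid.chromosome_name)
    tiles: List[Tuple[int, np.ndarray, int]] = []
    for k0 in range(0, len(samples), batch_size):
        batch = samples[k0 : k0 + batch_size]
        x = np.stack([s.channels for s in batch])
        probs = predict_probs(model, x)[:, 0]
        for s, p in zip(batch, probs):
            tiles.append((s.origin_bin, p, s.valid_bins))
    probs, cov = merge_tile_probs(tiles, n)
    return PredictionMatrix(grid, probs, cov)


def rank_pixels(pred, mask) -> List[Tuple[int, int, float]]:
    """Band pixels sorted by descending probability, ties by ascending (i, j)."""
    from .labeling import as_pixel_arrays

    probs = pred.probs if isinstance(pred, PredictionMatrix) else np.asarray(pred)
    ii, jj = as_pixel_arrays(mask)
    p = probs[ii, jj]
    order = np.lexsort((jj, ii, -p))
    return [(int(ii[k]), int(jj[k]), float(p[k])) for k in order]


def shuffle_control(x: np.ndarray, which: str, seed: int) -> np.ndarray:
    """Seeded input-randomization controls.

    ``shuffleChIPseq`` permutes the 1D bin vector (before 2D broadcasting);
    ``shuffleHiC`` permutes the strictly-upper-triangle entries of the matrix
    and mirrors them so the input remains a valid symmetric contact map (the
    diagonal, which lies outside the evaluated band, is left in place).  The
    multiset of shuffled values is preserved exactly.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x)
    if which == "shuffleChIPseq":
        if x.ndim != 1:
            raise ValueError("shuffleChIPseq expects a 1D vector")
        return x[rng.permutation(x.size)]
    if which == "shuffleHiC":
        if x.ndim != 2 or x.shape[0] != x.shape[1]:
            raise ValueError("shuffleHiC expects a square matrix")
        out = x.copy()
        iu = np.triu_indices(x.shape[0], k=1)
        vals = x[iu][rng.permutation(iu[0].size)]
        out[iu] = vals
        out[(iu[1], iu[0])] = vals
        return out
    raise ValueError(f"unknown shuffle control {which!r}")


def band_coverage_ok(n: int, W: int, step: int, d_max: int) -> bool:
    """True iff every band pixel (j - i <= d_max) is covered by >= 1 tile.

    A pixel (i, j), i <= j, is covered iff some origin o satisfies
    ``o <= i`` and ``j < o + W``; it suffices to check the largest origin <= i.
    """
    origins = np.asarray(window_origins(n, W, step))
    for d in range(0, min(d_max, n - 1) + 1):
        i = np.arange(0, n - d)
        # index of largest origin <= i
        oi = origins[np.searchsorted(origins, i, side="right") - 1]
        if not np.all(i + d < oi + W):
            return False
    return True
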