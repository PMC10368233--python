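"""Normalization and diagonal sliding-window sample extraction.

Hi-C matrices are rescaled by ``log2(x + 1)`` followed by per-chromosome
min-max normalization to [0, 1]; ChIP-seq tracks get per-chromosome min-max
only.  A single pooled mean/SD pair, fitted once on the training windows and
then frozen, z-scores both data types so that models transfer across datasets.
Samples are W x W tiles cut along the matrix diagonal with a fixed step
(250/50 at 10 kb, 500/100 at 5 kb), with ChIP-seq broadcast row- and
column-wise into two extra channels.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .data_io import BinnedTrack, ContactMatrix

log = logging.getLogger(__name__)

SD_FLOOR = 1e-8

CHANNEL_MODES = ("hic_only", "chip_only", "both")
#: channel order for mode "both": Hi-C, ChIP broadcast row-wise, column-wise
CHANNEL_ORDER = ("hic", "chip_row", "chip_col")


@dataclass(frozen=True)
class NormStats:
    """Frozen pooled mean/SD used for the final z-score step."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass
class WindowSample:
    """One diagonal W x W tile: input channels, label tile, and provenance."""

    origin_bin: int
    window_bins: int
    channels: np.ndarray  # (C, W, W) float32
    label_tile: np.ndarray  # (W, W) int8
    valid_bins: int
    chrom: str = ""


def log_minmax(m: ContactMatrix) -> np.ndarray:
    """``log2(x + 1)`` then per-chromosome min-max to [0, 1].

    A constant matrix (no dynamic range) maps to all zeros.
    """
    x = np.log2(np.asarray(m.counts if isinstance(m, ContactMatrix) else m) + 1.0)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def minmax_track(t: BinnedTrack) -> np.ndarray:
    """Per-chromosome min-max of a coverage track; constant vector -> zeros."""
    x = np.asarray(t.values if isinstance(t, BinnedTrack) else t, dtype=np.float64)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def fit_reference_stats(samples: Iterable[np.ndarray]) -> NormStats:
    """Pooled mean and population SD over all elements of all samples.

    Fitted once on the training windows of the reference dataset and reused
    (frozen) on every other dataset.  SD below 1e-8 is floored with a warning.
    """
    flat = [np.asarray(s, dtype=np.float64).ravel() for s in samples]
    if not flat:
        raise ValueError("need at least one sample")
    allv = np.concatenate(flat)
    mean = float(allv.mean())
    sd = float(allv.std())  # population SD
    if sd < SD_FLOOR:
        log.warning("reference SD %.3g below floor; flooring to %.0e", sd, SD_FLOOR)
        sd = SD_FLOOR
    return NormStats(mean, sd)


def zscore(x: np.ndarray, stats: NormStats) -> np.ndarray:
    return (np.asarray(x, dtype=np.float64) - stats.mean) / stats.sd


def window_origins(n_bins: int, W: int, step: int) -> List[int]:
    """Ordered origins of the diagonal sliding windows.

    Origins are ``0, step, 2*step, ...`` while the window fits (``o + W <= n``);
    a final clipped origin ``n - W`` is appended (deduplicated) so chromosome
    tails are covered.  If ``n < W`` there is a single zero-padded window at 0.
    """
    if W <= 0 or step <= 0:
        raise ValueError("W and step must be positive")
    if n_bins < W:
        return [0]
    origins = list(range(0, n_bins - W + 1, step))
    if origins[-1] != n_bins - W:
        origins.append(n_bins - W)
    return origins


def assemble_channels(
    hic_tile: Optional[np.ndarray],
    chip_window: Optional[np.ndarray],
    config: str = "both",
) -> np.ndarray:
    """Stack the model input channels for one window.

    ``both`` -> (3, W, W): Hi-C tile, then the 1D ChIP-seq window copied
    row-wise (``channel[i, j] = chip[i]``) and column-wise
    (``channel[i, j] = chip[j]``).  ``hic_only`` -> (1, W, W); ``chip_only``
    -> (2, W, W) with only the two broadcast channels.
    """
    if config not in CHANNEL_MODES:
        raise ValueError(f"unknown channel config {config!r}")
    chans = []
    W = None
    if config in ("hic_only", "both"):
        if hic_tile is None:
            raise ValueError("hic_tile required")
        hic_tile = np.asarray(hic_tile)
        if hic_tile.ndim != 2 or hic_tile.shape[0] != hic_tile.shape[1]:
            raise ValueError("hic_tile must be square 2D")
        W = hic_tile.shape[0]
        chans.append(hic_tile)
    if config in ("chip_only", "both"):
        if chip_window is None:
            raise ValueError("chip_window required")
        chip_window = np.asarray(chip_window)
        if W is None:
            W = chip_window.shape[0]
        if chip_window.shape != (W,):
            raise ValueError("chip_window length inconsistent with tile size")
        chans.append(np.repeat(chip_window[:, None], W, axis=1))  # row-wise
        chans.append(np.repeat(chip_window[None, :], W, axis=0))  # column-wise
    return np.stack(chans).astype(np.float32)


def n_channels(config: str) -> int:
    return {"hic_only": 1, "chip_only": 2, "both": 3}[config]


def extract_samples(
    hic_z: Optional[np.ndarray],
    chip_z: Optional[np.ndarray],
    labels: Optional[np.ndarray],
    W: int,
    step: int,
    mode: str = "both",
    chrom: str = "",
) -> List[WindowSample]:
    """Cut z-scored inputs into diagonal window samples.

    Tiles short of ``W`` bins (chromosome shorter than the window) are
    zero-padded and carry ``valid_bins < W`` so padded pixels can be ignored
    downstream.
    """
    ref = hic_z if hic_z is not None else chip_z
    if ref is None:
        raise ValueError("need at least one of hic_z / chip_z")
    n = ref.shape[0]
    samples = []
    for o in window_origins(n, W, step):
        valid = min(W, n - o)
        hic_tile = None
        if hic_z is not None:
            hic_tile = np.zeros((W, W), dtype=np.float64)
            hic_tile[:valid, :valid] = hic_z[o : o + valid, o : o + valid]
        chip_win = None
        if chip_z is not None:
            chip_win = np.zeros(W, dtype=np.float64)
            chip_win[:valid] = chip_z[o : o + valid]
        lab = np.zeros((W, W), dtype=np.int8)
        if labels is not None:
            lab[:valid, :valid] = labels[o : o + valid, o : o + valid]
        samples.append(
            WindowSample(
                origin_bin=o,
                window_bins=W,
                channels=assemble_channels(hic_tile, chip_win, mode),
                label_tile=lab,
                valid_bins=valid,
                chrom=chrom,
            )
        )
    return samples


def normalize_chromosome(
    hic: Optional[ContactMatrix],
    chip: Optional[BinnedTrack],
    hic_stats: Optional[NormStats],
    chip_stats: Optional[NormStats],
):
    """Apply the full normalization chain to one chromosome's inputs."""
    hic_z = None
    if hic is not None:
        if hic_stats is None:
            raise ValueError("hic_stats required")
        hic_z = zscore(log_minmax(hic), hic_stats)
    chip_z = None
    if chip is not None:
        if chip_stats is None:
            raise ValueError("chip_stats required")
        chip_z = zscore(minmax_track(chip), chip_stats)
    return hic_z, chip_z
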