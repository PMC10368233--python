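"""Readers and writers for the text formats the pipeline touches.

All coordinates are 0-based half-open (BED-family convention); bin ``b`` at
resolution ``r`` covers base pairs ``[b*r, (b+1)*r)`` and ``bin(bp) = bp // r``.
Supported formats: Juicer-dump-style sparse triplet text and dense whitespace
matrices for Hi-C, bedGraph for ChIP-seq coverage, and BEDPE (6+ columns) for
ChIA-PET interaction anchors.  Every reader transparently accepts gzip
(``.gz``) input.
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import Iterable, List, Set, Tuple, Union

import numpy as np

log = logging.getLogger(__name__)

PathLike = Union[str, "os.PathLike[str]"]


def _open_text(path: PathLike):
    p = str(path)
    if p.endswith(".gz"):
        return gzip.open(p, "rt")
    return open(p, "rt")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeGrid:
    """A fixed-resolution binning of one chromosome.

    Parameters
    ----------
    chromosome_name:
        Name as it appears in the input files (e.g. ``"chr1"``).
    resolution_bp:
        Bin size in base pairs; 10000 and 5000 are the typical choices.
    n_bins:
        Number of bins covering the chromosome.
    """

    chromosome_name: str
    resolution_bp: int
    n_bins: int

    def __post_init__(self) -> None:
        if self.resolution_bp <= 0:
            raise ValueError("resolution_bp must be positive")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")

    def bin_of(self, bp: int) -> int:
        return int(bp) // self.resolution_bp

    def bin_interval(self, b: int) -> Tuple[int, int]:
        r = self.resolution_bp
        return b * r, (b + 1) * r


@dataclass
class ContactMatrix:
    """Dense symmetric Hi-C contact matrix for one chromosome."""

    grid: GenomeGrid
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        n = self.grid.n_bins
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match grid ({n}, {n})"
            )


@dataclass
class BinnedTrack:
    """Per-bin mean ChIP-seq coverage on a :class:`GenomeGrid`."""

    grid: GenomeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.grid.n_bins,):
            raise ValueError("values length does not match grid.n_bins")


@dataclass(frozen=True)
class AnchorPair:
    """One intra-chromosomal ChIA-PET interaction (two anchor intervals)."""

    chromosome_name: str
    start1: int
    end1: int
    start2: int
    end2: int

    def __post_init__(self) -> None:
        if self.start1 >= self.end1 or self.start2 >= self.end2:
            raise ValueError("anchor intervals must satisfy start < end")


# ---------------------------------------------------------------------------
# Hi-C readers
# ---------------------------------------------------------------------------

def read_contact_matrix(
    path: PathLike, grid: GenomeGrid, dialect: str = "triplet"
) -> ContactMatrix:
    """Read a Hi-C contact matrix from text.

    ``dialect="triplet"`` expects Juicer-dump-style rows ``bp1  bp2  value``;
    base-pair positions are floored to bins.  Entries are interpreted as one
    triangle and mirrored across the diagonal; a duplicate (unordered) pair
    overwrites the earlier value with a warning.  ``dialect="dense"`` expects
    an ``n x n`` whitespace matrix.
    """
    n = grid.n_bins
    if dialect == "dense":
        with _open_text(path) as fh:
            m = np.loadtxt(fh, dtype=np.float64, ndmin=2)
        if m.shape != (n, n):
            raise ValueError(f"dense matrix shape {m.shape}, expected ({n}, {n})")
        if not np.allclose(m, m.T, equal_nan=True):
            log.warning("dense matrix not symmetric; symmetrizing by averaging")
            m = (m + m.T) / 2.0
        return ContactMatrix(grid, m)
    if dialect != "triplet":
        raise ValueError(f"unknown dialect {dialect!r}")

    counts = np.zeros((n, n), dtype=np.float64)
    seen = np.zeros((n, n), dtype=bool)
    n_dup = n_neg = 0
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"line {ln}: expected 'bp1 bp2 value', got {line!r}")
            try:
                bp1, bp2 = int(float(parts[0])), int(float(parts[1]))
                v = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"line {ln}: unparseable triplet row {line!r}") from exc
            if v < 0:
                n_neg += 1
                continue
            i, j = grid.bin_of(bp1), grid.bin_of(bp2)
            if i >= n or j >= n or i < 0 or j < 0:
                raise ValueError(
                    f"line {ln}: bin index ({i}, {j}) outside grid of {n} bins: {line!r}"
                )
            a, b = (i, j) if i <= j else (j, i)
            if seen[a, b]:
                n_dup += 1
            seen[a, b] = True
            counts[a, b] = v
            counts[b, a] = v
    if n_neg:
        log.warning("rejected %d rows with negative counts", n_neg)
    if n_dup:
        log.warning("%d duplicate symmetric entries overwritten", n_dup)
    return ContactMatrix(grid, counts)


def clean_matrix(m: ContactMatrix) -> Tuple[ContactMatrix, Set[int]]:
    """Replace non-finite entries by 0 and flag unmappable bins.

    Non-finite entries (NaN gaps left by matrix balancing) are zeroed together
    with their mirror entries so the matrix stays symmetric.  Bins whose entire
    row is zero afterwards are returned as *unmappable*; downstream evaluation
    excludes pixels touching them.  Idempotent.
    """
    c = np.array(m.counts, dtype=np.float64, copy=True)
    bad = ~np.isfinite(c)
    bad |= bad.T
    c[bad] = 0.0
    unmappable = set(int(i) for i in np.where(~c.any(axis=1))[0])
    return ContactMatrix(m.grid, c), unmappable


# ---------------------------------------------------------------------------
# ChIP-seq bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph_binned(path: PathLike, grid: GenomeGrid) -> BinnedTrack:
    """Bin a 4-column bedGraph by per-bin averaging.

    Each bin's value is the mean coverage over the bin: intervals contribute
    ``value * overlap_length`` and the total is divided by the bin size, so
    uncovered stretches count as zero (bedGraph gaps are implicit zeros).
    Intervals crossing bin edges are split proportionally.
    """
    n, r = grid.n_bins, grid.resolution_bp
    acc = np.zeros(n, dtype=np.float64)
    n_skipped_chrom = n_bad = 0
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"line {ln}: expected 4 bedGraph columns: {line!r}")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if chrom != grid.chromosome_name:
                n_skipped_chrom += 1
                continue
            if e <= s:
                n_bad += 1
                continue
            s = max(s, 0)
            e = min(e, n * r)
            if e <= s:
                continue
            b0, b1 = s // r, (e - 1) // r
            for b in range(b0, b1 + 1):
                lo = max(s, b * r)
                hi = min(e, (b + 1) * r)
                acc[b] += v * (hi - lo)
    if n_skipped_chrom:
        log.warning(
            "skipped %d bedGraph rows on other chromosomes (grid is %s)",
            n_skipped_chrom,
            grid.chromosome_name,
        )
    if n_bad:
        log.warning("rejected %d bedGraph rows with end <= start", n_bad)
    return BinnedTrack(grid, acc / r)


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

def read_bedpe(path: PathLike) -> List[AnchorPair]:
    """Read ChIA-PET interactions from BEDPE (6+ tab-separated columns).

    Inter-chromosomal rows are dropped (the pipeline is strictly
    intra-chromosomal) and anchors are normalized so ``start1 <= start2``.
    """
    pairs: List[AnchorPair] = []
    n_inter = 0
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) == 1:  # tolerate space-separated input
                parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"line {ln}: BEDPE needs >= 6 columns: {line!r}")
            try:
                c1, s1, e1 = parts[0], int(parts[1]), int(parts[2])
                c2, s2, e2 = parts[3], int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise ValueError(f"line {ln}: malformed BEDPE row {line!r}") from exc
            if c1 != c2:
                n_inter += 1
                continue
            if s1 > s2:
                s1, e1, s2, e2 = s2, e2, s1, e1
            pairs.append(AnchorPair(c1, s1, e1, s2, e2))
    if n_inter:
        log.info("dropped %d inter-chromosomal BEDPE rows", n_inter)
    return pairs


def write_scored_bedpe(
    pred,
    grid: GenomeGrid,
    path: PathLike,
    min_score: float = 0.0,
    band=None,
) -> int:
    """Write upper-triangle predicted pixels with score >= min_score as BEDPE.

    The 7th column is the predicted probability; rows are sorted by descending
    score (ties broken by ascending ``(i, j)``).  ``band`` optionally restricts
    output to a genomic-distance band (a ``BandSpec``).  Returns the number of
    rows written.
    """
    probs = pred.probs if hasattr(pred, "probs") else np.asarray(pred)
    n = grid.n_bins
    ii, jj = np.triu_indices(n, k=1)
    if band is not None:
        d = jj - ii
        keep = (d >= band.d_min_bins) & (d <= band.d_max_bins)
        ii, jj = ii[keep], jj[keep]
    p = probs[ii, jj]
    keep = p >= min_score
    ii, jj, p = ii[keep], jj[keep], p[keep]
    order = np.lexsort((jj, ii, -p))
    r = grid.resolution_bp
    name = grid.chromosome_name
    count = 0
    with open(str(path), "wt") as fh:
        for k in order:
            i, j = int(ii[k]), int(jj[k])
            fh.write(
                f"{name}\t{i * r}\t{(i + 1) * r}\t{name}\t{j * r}\t{(j + 1) * r}\t{p[k]:.6g}\n"
            )
            count += 1
    return count
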