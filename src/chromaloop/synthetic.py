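"""Seeded generator of coupled Hi-C / ChIP-seq / ChIA-PET chromosomes.

The generative model is the minimal one reproducing the joint structure the
pipeline exploits: Hi-C counts follow a distance-decay power law
``mu(i, j) = A * (1 + |i - j|)^(-alpha)`` modulated by TAD blocks
(multiplicative boost for same-TAD pixels) and planted loops (multiplicative
enrichment at loop pixels), with Poisson sampling; ChIP-seq coverage is
exponential background plus peaks at every loop-anchor bin and at decoy bins
without loops (so ChIP-seq alone cannot classify perfectly), plus Gaussian
jitter; ChIA-PET ground truth is the planted loop pixels' bin intervals.
All randomness flows from one seed, and outputs can be serialized to the
standard text formats and read back through the package's own readers.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .data_io import AnchorPair, BinnedTrack, ContactMatrix, GenomeGrid

log = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """Desk-scale defaults: three chromosomes of ~500 bins at 10 kb with 60
    planted loops each; pipeline constants (window 64, step 16, band 2-48)
    scale down from the reference 250/50/2-200 configuration accordingly."""

    chrom_bins: Dict[str, int] = field(
        default_factory=lambda: {"chrA": 520, "chrB": 560, "chrC": 480}
    )
    resolution_bp: int = 10_000
    decay_amplitude: float = 300.0
    decay_exponent: float = 1.0
    tad_boundaries: Optional[Dict[str, Sequence[int]]] = None  # generated if None
    mean_tad_bins: int = 90
    tad_boost: float = 1.6
    n_loops: int = 60
    loop_distance_range_bins: Tuple[int, int] = (4, 44)
    band: Tuple[int, int] = (2, 48)
    loop_enrichment: float = 4.0
    chip_peak_amplitude: float = 8.0
    chip_background_rate: float = 1.0
    chip_noise_sd: float = 0.3
    decoy_peak_fraction: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.loop_distance_range_bins
        if not (self.band[0] <= lo <= hi <= self.band[1]):
            raise ValueError(
                f"loop distance range {self.loop_distance_range_bins} outside "
                f"evaluation band {self.band}"
            )
        for v in (self.decay_amplitude, self.tad_boost, self.loop_enrichment,
                  self.chip_background_rate):
            if v <= 0:
                raise ValueError("rates and boosts must be positive")
        if self.loop_enrichment <= 1 or self.tad_boost <= 1:
            raise ValueError("loop_enrichment and tad_boost must exceed 1")


@dataclass
class SyntheticChromosome:
    hic: ContactMatrix
    chip: BinnedTrack
    anchors: List[AnchorPair]
    loop_pixels: Set[Tuple[int, int]]  # upper-triangle (i < j)
    tad_boundaries: List[int]


def _make_tads(n: int, mean_size: int, rng: np.random.Generator) -> List[int]:
    bounds = []
    pos = 0
    while pos < n:
        pos += int(rng.integers(max(2, int(0.6 * mean_size)), int(1.4 * mean_size) + 1))
        if pos < n:
            bounds.append(pos)
    return bounds


def _tad_ids(n: int, boundaries: Sequence[int]) -> np.ndarray:
    ids = np.zeros(n, dtype=np.int64)
    for b in boundaries:
        ids[b:] += 1
    return ids


def _plant_loops(
    n: int, n_loops: int, dist_range: Tuple[int, int], rng: np.random.Generator
) -> List[Tuple[int, int]]:
    """Loop pixels with fully distinct anchor bins (rejection sampling)."""
    lo, hi = dist_range
    used: Set[int] = set()
    loops: List[Tuple[int, int]] = []
    attempts = 0
    while len(loops) < n_loops:
        attempts += 1
        if attempts > 100 * n_loops:
            raise RuntimeError("could not place loops with distinct anchors")
        d = int(rng.integers(lo, hi + 1))
        i = int(rng.integers(0, n - d))
        j = i + d
        if i in used or j in used:
            continue
        used.update((i, j))
        loops.append((i, j))
    return sorted(loops)


def expected_hic(
    n: int,
    cfg: SyntheticConfig,
    tad_ids: np.ndarray,
    loop_pixels: Set[Tuple[int, int]],
) -> np.ndarray:
    """Closed-form expected count matrix mu(i, j) of the generator."""
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    mu = cfg.decay_amplitude * (1.0 + d) ** (-cfg.decay_exponent)
    same_tad = tad_ids[:, None] == tad_ids[None, :]
    mu = np.where(same_tad, mu * cfg.tad_boost, mu)
    for i, j in loop_pixels:
        mu[i, j] *= cfg.loop_enrichment
        mu[j, i] *= cfg.loop_enrichment
    return mu


def simulate_trio(cfg: SyntheticConfig) -> Dict[str, SyntheticChromosome]:
    """Generate the coupled data trio for every configured chromosome."""
    out: Dict[str, SyntheticChromosome] = {}
    r = cfg.resolution_bp
    for ci, (chrom, n) in enumerate(sorted(cfg.chrom_bins.items())):
        rng = np.random.default_rng([cfg.seed, ci])
        grid = GenomeGrid(chrom, r, n)
        if cfg.tad_boundaries is not None and chrom in cfg.tad_boundaries:
            tads = list(cfg.tad_boundaries[chrom])
        else:
            tads = _make_tads(n, cfg.mean_tad_bins, rng)
        tid = _tad_ids(n, tads)
        loops = _plant_loops(n, cfg.n_loops, cfg.loop_distance_range_bins, rng)
        loop_set = set(loops)

        mu = expected_hic(n, cfg, tid, loop_set)
        upper = rng.poisson(np.triu(mu))
        counts = np.triu(upper, 1) + np.triu(upper, 1).T + np.diag(np.diag(upper))
        hic = ContactMatrix(grid, counts.astype(np.float64))

        anchor_bins = sorted({b for ij in loops for b in ij})
        non_anchor = np.setdiff1d(np.arange(n), anchor_bins)
        n_decoys = int(round(cfg.decoy_peak_fraction * n))
        decoys = rng.choice(non_anchor, size=min(n_decoys, non_anchor.size),
                            replace=False)
        chip_vals = rng.exponential(cfg.chip_background_rate, size=n)
        chip_vals[anchor_bins] += cfg.chip_peak_amplitude
        chip_vals[decoys] += cfg.chip_peak_amplitude
        chip_vals += rng.normal(0.0, cfg.chip_noise_sd, size=n)
        chip = BinnedTrack(grid, np.clip(chip_vals, 0.0, None))

        anchors = [
            AnchorPair(chrom, i * r, (i + 1) * r, j * r, (j + 1) * r)
            for i, j in loops
        ]
        out[chrom] = SyntheticChromosome(hic, chip, anchors, loop_set, tads)
    return out


def trio_to_dataset(trio: Mapping[str, SyntheticChromosome], outdir) -> dict:
    """Write a simulated trio in the pipeline's text formats.

    Per chromosome: sparse triplet Hi-C (upper triangle, nonzero entries),
    bedGraph ChIP-seq (one exact interval per bin), and BEDPE anchors.  A
    ``manifest.json`` records paths, grid geometry, and planted loop counts.
    Everything round-trips through the package's readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"chromosomes": {}}
    for chrom, syn in trio.items():
        grid = syn.hic.grid
        r, n = grid.resolution_bp, grid.n_bins
        hic_path = outdir / f"{chrom}_hic.txt"
        with open(hic_path, "wt") as fh:
            iu = np.triu_indices(n, k=0)
            for i, j in zip(*iu):
                v = syn.hic.counts[i, j]
                if v != 0:
                    fh.write(f"{i * r}\t{j * r}\t{v:.10g}\n")
        chip_path = outdir / f"{chrom}_chip.bedgraph"
        with open(chip_path, "wt") as fh:
            for b, v in enumerate(syn.chip.values):
                fh.write(f"{chrom}\t{b * r}\t{(b + 1) * r}\t{v:.10g}\n")
        bedpe_path = outdir / f"{chrom}_loops.bedpe"
        with open(bedpe_path, "wt") as fh:
            for a in syn.anchors:
                fh.write(
                    f"{a.chromosome_name}\t{a.start1}\t{a.end1}"
                    f"\t{a.chromosome_name}\t{a.start2}\t{a.end2}\n"
                )
        manifest["chromosomes"][chrom] = {
            "n_bins": n,
            "resolution_bp": r,
            "hic": hic_path.name,
            "chip": chip_path.name,
            "bedpe": bedpe_path.name,
            "n_loops": len(syn.anchors),
            "tad_boundaries": list(syn.tad_boundaries),
        }
    with open(outdir / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
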