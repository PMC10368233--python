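"""End-to-end experiment orchestration on simulated data.

Wires the full protocol together: simulate coupled chromosomes, build labels,
make the leave-one-chromosome-out split, fit frozen normalization statistics
on the training windows, train, predict the held-out chromosome by tiled
averaging, and evaluate with the imbalanced protocol.  Used by the CLI, the
test suite, and the acceptance script so they all exercise one code path.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .evaluation import (
    EvalSpec,
    MetricsReport,
    chip_inner_product_baseline,
    evaluate,
    evaluate_scores,
)
from .inference import PredictionMatrix, predict_chromosome, rank_pixels
from .labeling import BandSpec, LabelMatrix, anchors_to_label_matrix, band_mask_arrays
from .network import DilatedResNet, ModelConfig, build_model
from .preprocess import NormStats, minmax_track
from .synthetic import SyntheticChromosome, SyntheticConfig, simulate_trio
from .training import SplitPlan, TrainConfig, build_samples, make_split, train_model

log = logging.getLogger(__name__)

#: desk-scale tiling constants matching the default SyntheticConfig
DESK_W = 64
DESK_STEP = 16

#: desk-scale model: same architecture family, scaled down for CPU training
DESK_MODEL = ModelConfig(in_channels=3, hidden_dim=16, n_blocks=4)

#: desk-scale optimizer settings: with only one training chromosome there are
#: few gradient steps per epoch, so the smallest batch size and the largest
#: initial learning rate of the standard tuning grid win on validation loss
DESK_TRAIN = TrainConfig(batch_size=4, lr=0.01, max_epochs=60)


@dataclass
class ExperimentResult:
    split: SplitPlan
    model: DilatedResNet
    stats: Dict[str, NormStats]
    history: List[dict]
    pred: PredictionMatrix
    labels: Dict[str, LabelMatrix]
    metrics: Dict[str, MetricsReport]
    band: BandSpec
    data: Dict[str, SyntheticChromosome]
    mode: str
    W: int
    step: int


def label_trio(trio: Dict[str, SyntheticChromosome]) -> Dict[str, LabelMatrix]:
    return {
        chrom: anchors_to_label_matrix(syn.anchors, syn.hic.grid)
        for chrom, syn in trio.items()
    }


def run_experiment(
    syn_cfg: SyntheticConfig,
    test_chrom: str,
    model_cfg: Optional[ModelConfig] = None,
    train_cfg: Optional[TrainConfig] = None,
    W: int = DESK_W,
    step: int = DESK_STEP,
    mode: str = "both",
    eval_spec: Optional[EvalSpec] = None,
    trio: Optional[Dict[str, SyntheticChromosome]] = None,
) -> ExperimentResult:
    """Simulate (or reuse ``trio``), train leave-one-out, predict and evaluate
    the held-out chromosome."""
    from .preprocess import n_channels

    band = BandSpec(*syn_cfg.band)
    if trio is None:
        trio = simulate_trio(syn_cfg)
    labels = label_trio(trio)
    sizes = {c: s.hic.grid.n_bins for c, s in trio.items()}
    split = make_split(sizes, test_chrom)

    if model_cfg is None:
        model_cfg = replace(DESK_MODEL, in_channels=n_channels(mode))
    elif model_cfg.in_channels != n_channels(mode):
        model_cfg = replace(model_cfg, in_channels=n_channels(mode))
    if train_cfg is None:
        train_cfg = replace(DESK_TRAIN, seed=syn_cfg.seed)

    data = {c: (s.hic, s.chip, labels[c]) for c, s in trio.items()}
    train_samples, val_samples, stats = build_samples(data, split, W, step, mode)
    model = build_model(model_cfg, seed=train_cfg.seed)
    best_state, history = train_model(model, train_samples, val_samples, train_cfg)
    model.load_state_dict(best_state)

    held = trio[test_chrom]
    pred = predict_chromosome(
        model,
        held.hic if mode in ("hic_only", "both") else None,
        held.chip if mode in ("chip_only", "both") else None,
        stats,
        W=W,
        step=step,
        mode=mode,
        batch_size=4,
    )
    if eval_spec is None:
        eval_spec = EvalSpec(band=band, seed=syn_cfg.seed)
    metrics = evaluate(pred, labels[test_chrom], eval_spec)
    return ExperimentResult(
        split=split,
        model=model,
        stats=stats,
        history=history,
        pred=pred,
        labels=labels,
        metrics=metrics,
        band=band,
        data=trio,
        mode=mode,
        W=W,
        step=step,
    )


def baseline_metrics(
    trio: Dict[str, SyntheticChromosome],
    labels: Dict[str, LabelMatrix],
    test_chrom: str,
    band: BandSpec,
    eval_spec: EvalSpec,
) -> Dict[str, MetricsReport]:
    """ChIP-seq inner-product baseline metrics on the held-out chromosome."""
    syn = trio[test_chrom]
    grid = syn.hic.grid
    ii, jj = band_mask_arrays(grid, band)
    chip01 = minmax_track(syn.chip)
    scores = chip_inner_product_baseline(chip01, (ii, jj))
    lab = labels[test_chrom].labels[ii, jj] > 0
    order = np.lexsort((jj, ii, -scores))
    return evaluate_scores(scores, lab, eval_spec, ranked_flags=lab[order])


def shuffle_metrics(
    result: ExperimentResult,
    which: str,
    seed: int = 0,
) -> Dict[str, MetricsReport]:
    """Re-predict the held-out chromosome with a shuffle control applied."""
    held = result.data[result.split.test_chrom]
    mode = result.mode
    pred = predict_chromosome(
        result.model,
        held.hic if mode in ("hic_only", "both") else None,
        held.chip if mode in ("chip_only", "both") else None,
        result.stats,
        W=result.W,
        step=result.step,
        mode=mode,
        batch_size=4,
        shuffle=which,
        shuffle_seed=seed,
    )
    spec = EvalSpec(band=result.band, seed=seed)
    return evaluate(pred, result.labels[result.split.test_chrom], spec)
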