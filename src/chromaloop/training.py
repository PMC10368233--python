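"""Leave-one-chromosome-out training with validation-based model selection.

For a held-out test chromosome, validation tiles come from the largest
remaining chromosome and training tiles from all the others, so no test pixel
ever leaks into fitting or model selection.  Optimization is Adam with weight
decay 1e-4; the learning rate starts at 1e-3 and is cut by 10x whenever the
validation loss has not improved for ten epochs.  The checkpoint returned is
the one with the lowest validation loss.  Training consumes every pixel of
every tile — positives and negatives alike — in the weighted BCE loss.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .data_io import BinnedTrack, ContactMatrix
from .labeling import LabelMatrix
from .network import DilatedResNet, Param, weighted_bce
from .preprocess import (
    NormStats,
    WindowSample,
    extract_samples,
    fit_reference_stats,
    log_minmax,
    minmax_track,
    window_origins,
    zscore,
)

log = logging.getLogger(__name__)

#: hg19 chromosome lengths in bp (autosomes + X), used for the human split rule
HG19_CHROM_SIZES_BP: Dict[str, int] = {
    "chr1": 249250621, "chr2": 243199373, "chr3": 198022430, "chr4": 191154276,
    "chr5": 180915260, "chr6": 171115067, "chr7": 159138663, "chr8": 146364022,
    "chr9": 141213431, "chr10": 135534747, "chr11": 135006516, "chr12": 133851895,
    "chr13": 115169878, "chr14": 107349540, "chr15": 102531392, "chr16": 90354753,
    "chr17": 81195210, "chr18": 78077248, "chr19": 59128983, "chr20": 63025520,
    "chr21": 48129895, "chr22": 51304566, "chrX": 155270560,
}


def chrom_bins(sizes_bp: Mapping[str, int], resolution_bp: int) -> Dict[str, int]:
    """Bin counts per chromosome: ``ceil(size / resolution)``."""
    return {c: -(-s // resolution_bp) for c, s in sizes_bp.items()}


def _chrom_sort_key(name: str):
    base = name[3:] if name.lower().startswith("chr") else name
    return (0, int(base)) if base.isdigit() else (1, base)


@dataclass(frozen=True)
class SplitPlan:
    test_chrom: str
    val_chrom: str
    train_chroms: Tuple[str, ...]


@dataclass
class TrainConfig:
    batch_size: int = 16
    lr: float = 1e-3
    weight_decay: float = 1e-4
    plateau_factor: float = 0.1
    plateau_patience: int = 10
    pos_weight: float = 1.0
    max_epochs: int = 60
    seed: int = 0
    #: stop after this many LR reductions without any further improvement
    early_stop_reductions: int = 3
    #: apply pos_weight to the validation loss too (comparable losses)
    val_pos_weight: bool = True

    def __post_init__(self) -> None:
        if min(self.batch_size, self.max_epochs, self.plateau_patience) <= 0:
            raise ValueError("batch_size, max_epochs, plateau_patience must be positive")
        if not (0 < self.plateau_factor < 1):
            raise ValueError("plateau_factor must be in (0, 1)")
        if self.lr < 0 or self.weight_decay < 0 or self.pos_weight <= 0:
            raise ValueError("lr, weight_decay must be >= 0 and pos_weight > 0")


def make_split(chrom_sizes: Mapping[str, int], test_chrom: str) -> SplitPlan:
    """Leave-one-chromosome-out split.

    Validation is the largest (by bin count) non-test chromosome, ties broken
    by lexicographically smallest name; the rest train.  E.g. with human
    chromosome sizes, testing on chr1 trains on chr3..chrX and validates on
    chr2.
    """
    if test_chrom not in chrom_sizes:
        raise ValueError(f"test chromosome {test_chrom!r} not in sizes")
    if len(chrom_sizes) < 3:
        raise ValueError("need at least 3 chromosomes for a train/val/test split")
    others = [c for c in chrom_sizes if c != test_chrom]
    val = min(others, key=lambda c: (-chrom_sizes[c], c))
    train = tuple(sorted((c for c in others if c != val), key=_chrom_sort_key))
    return SplitPlan(test_chrom, val, train)


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with decoupled-from-schedule weight decay added to the gradient
    (the classic L2 formulation)."""

    def __init__(self, params: Sequence[Param], lr: float, weight_decay: float = 0.0,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            if self.wd:
                g = g + self.wd * p.value
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            update = self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            p.value = (p.value - update).astype(p.value.dtype)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

ChromData = Tuple[ContactMatrix, Optional[BinnedTrack], LabelMatrix]


def build_samples(
    data: Mapping[str, ChromData],
    split: SplitPlan,
    W: int,
    step: int,
    mode: str = "both",
) -> Tuple[List[WindowSample], List[WindowSample], Dict[str, NormStats]]:
    """Normalize chromosomes and cut train/val window samples.

    Reference mean/SD are pooled over the *training* windows only, then frozen
    and applied to validation (and later to any prediction target).  Returns
    (train_samples, val_samples, {"hic": NormStats, "chip": NormStats}).
    """
    use_hic = mode in ("hic_only", "both")
    use_chip = mode in ("chip_only", "both")
    scaled: Dict[str, Tuple[Optional[np.ndarray], Optional[np.ndarray]]] = {}
    for chrom in (*split.train_chroms, split.val_chrom):
        hic, chip, _ = data[chrom]
        h = log_minmax(hic) if use_hic else None
        c = minmax_track(chip) if (use_chip and chip is not None) else None
        if use_chip and c is None:
            raise ValueError(f"channel mode {mode!r} needs ChIP-seq for {chrom}")
        scaled[chrom] = (h, c)

    stats: Dict[str, NormStats] = {}
    if use_hic:
        tiles = []
        for chrom in split.train_chroms:
            h = scaled[chrom][0]
            for o in window_origins(h.shape[0], W, step):
                tiles.append(h[o : o + W, o : o + W])
        stats["hic"] = fit_reference_stats(tiles)
    if use_chip:
        vecs = []
        for chrom in split.train_chroms:
            c = scaled[chrom][1]
            for o in window_origins(c.shape[0], W, step):
                vecs.append(c[o : o + W])
        stats["chip"] = fit_reference_stats(vecs)

    def _samples_for(chroms: Sequence[str]) -> List[WindowSample]:
        out = []
        for chrom in chroms:
            h, c = scaled[chrom]
            hz = zscore(h, stats["hic"]) if use_hic else None
            cz = zscore(c, stats["chip"]) if use_chip else None
            out.extend(
                extract_samples(hz, cz, data[chrom][2].labels, W, step, mode, chrom)
            )
        return out

    train_samples = _samples_for(split.train_chroms)
    val_samples = _samples_for([split.val_chrom])
    forbidden = {s.chrom for s in train_samples + val_samples}
    if split.test_chrom in forbidden:
        raise AssertionError("test-chromosome samples leaked into train/val")
    return train_samples, val_samples, stats


def _stack(samples: Sequence[WindowSample]):
    x = np.stack([s.channels for s in samples])
    y = np.stack([s.label_tile for s in samples])[:, None, :, :]
    mask = np.zeros_like(y, dtype=bool)
    for k, s in enumerate(samples):
        mask[k, :, : s.valid_bins, : s.valid_bins] = True
    return x, y, mask


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

def _init_output_prior(model: DilatedResNet, train_samples) -> None:
    """Initialize the output layer's shift to the base-rate logit.

    With positives at a fraction of a percent of all pixels, a freshly
    initialized network spends its first epochs driving every logit toward the
    negative class; that transient passes through a collapsed all-negative
    state whose validation loss can masquerade as a minimum and poison both
    checkpoint selection and the LR-plateau scheduler.  Starting the output
    shift at ``log(p / (1 - p))`` for the training-set positive rate ``p``
    (the standard prior initialization for heavily imbalanced dense
    classification) removes that phase: epoch 0 already sits at the trivial
    optimum and any later improvement reflects real discrimination.
    """
    tot = sum(int(s.label_tile[: s.valid_bins, : s.valid_bins].sum())
              for s in train_samples)
    cnt = sum(s.valid_bins * s.valid_bins for s in train_samples)
    p = min(max(tot / max(cnt, 1), 1e-6), 1 - 1e-6)
    prior = float(np.log(p / (1.0 - p)))
    model.norm_out.beta.value[...] = prior

def train_model(
    model: DilatedResNet,
    train_samples: Sequence[WindowSample],
    val_samples: Sequence[WindowSample],
    cfg: TrainConfig,
) -> Tuple[Dict[str, np.ndarray], List[dict]]:
    """Train and return (best_state_dict, history).

    The best state is from the epoch with minimum validation loss; history
    rows carry epoch, train_loss, val_loss and the learning rate in force.
    Raises on non-finite loss.
    """
    if not train_samples or not val_samples:
        raise ValueError("train and validation sample sets must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    _init_output_prior(model, train_samples)
    opt = Adam(model.parameters(), cfg.lr, cfg.weight_decay)
    val_w = cfg.pos_weight if cfg.val_pos_weight else 1.0

    def _val_loss() -> float:
        tot, cnt = 0.0, 0
        for k0 in range(0, len(val_samples), cfg.batch_size):
            xb, yb, mb = _stack(val_samples[k0 : k0 + cfg.batch_size])
            logits = model.forward(xb, train=False)
            nb = int(mb.sum())
            tot += weighted_bce(logits, yb, val_w, pixel_mask=mb) * nb
            cnt += nb
        return tot / max(cnt, 1)

    history: List[dict] = []
    best_val = math.inf
    best_state = model.state_dict()
    best_epoch = -1
    epochs_since_improve = 0
    reductions = 0

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(train_samples))
        tr_tot, tr_cnt = 0.0, 0
        for k0 in range(0, len(order), cfg.batch_size):
            batch = [train_samples[i] for i in order[k0 : k0 + cfg.batch_size]]
            xb, yb, mb = _stack(batch)
            model.zero_grad()
            logits = model.forward(xb, train=True)
            loss, dlogits = weighted_bce(
                logits, yb, cfg.pos_weight, return_grad=True, pixel_mask=mb
            )
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss!r}"
                )
            model.backward(dlogits)
            opt.step()
            nb = int(mb.sum())
            tr_tot += loss * nb
            tr_cnt += nb
        val_loss = _val_loss()
        if not math.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.append(
            {
                "epoch": epoch,
                "train_loss": tr_tot / max(tr_cnt, 1),
                "val_loss": val_loss,
                "lr": opt.lr,
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
            epochs_since_improve = 0
            reductions = 0
        else:
            epochs_since_improve += 1
            if epochs_since_improve >= cfg.plateau_patience:
                opt.lr *= cfg.plateau_factor
                reductions += 1
                epochs_since_improve = 0
                log.info("epoch %d: reducing lr to %.2e", epoch, opt.lr)
                if reductions >= cfg.early_stop_reductions:
                    log.info("early stop after %d LR reductions", reductions)
                    break
    log.info("best epoch %d, val loss %.5f", best_epoch, best_val)
    return best_state, history


def history_to_tsv(history: Sequence[dict], path) -> None:
    with open(str(path), "wt") as fh:
        fh.write("epoch\ttrain_loss\tval_loss\tlr\n")
        for row in history:
            fh.write(
                f"{row['epoch']}\t{row['train_loss']:.6f}\t{row['val_loss']:.6f}\t{row['lr']:.3e}\n"
            )
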