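"""Imbalanced evaluation protocol: negative sets, AP/AUC/PR, top-N accuracy.

Because negatives outnumber positives by hundreds to one in the evaluated
band, metrics are reported over five negative sets — neg = pos, 5pos, 20pos,
100pos (uniform draws without replacement, averaged over repeated draws) and
neg = All.  Average precision uses the non-interpolated step form with the
same deterministic tie rule as the pixel ranking; ROC-AUC is the
Mann-Whitney pair probability with half credit for ties.  Top-N accuracy is
the percentage of ground-truth pixels among the N highest-ranked band pixels,
with N defaulting to the number of positives.  A ChIP-seq inner-product
baseline scores pixel (i, j) by the dot product of the coverage windows
[i-5, i+5] and [j-5, j+5] (clipped at chromosome ends).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import rankdata

from .data_io import BinnedTrack
from .labeling import BandSpec, LabelMatrix, as_pixel_arrays

log = logging.getLogger(__name__)

NEG_MODES = ("pos", "5pos", "20pos", "100pos", "all")
NEG_MODE_K: Dict[str, Optional[int]] = {
    "pos": 1, "5pos": 5, "20pos": 20, "100pos": 100, "all": None,
}
#: top-N multiples of the positive count reported by default
TOPN_MULTIPLIERS = (0.5, 1.0, 2.0, 5.0)


@dataclass(frozen=True)
class EvalSpec:
    band: BandSpec
    neg_modes: Tuple[str, ...] = NEG_MODES
    seed: int = 0
    n_repeats: int = 10

    def __post_init__(self) -> None:
        for m in self.neg_modes:
            if m not in NEG_MODE_K:
                raise ValueError(f"unknown negative mode {m!r}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class MetricsReport:
    ap: float
    auc: float
    pr_curve: List[Tuple[float, float]] = field(default_factory=list)
    topn: Dict[int, float] = field(default_factory=dict)
    ap_sd: float = 0.0
    auc_sd: float = 0.0


def _score_order(scores: np.ndarray) -> np.ndarray:
    """Descending-score order with deterministic tie-breaking by input index
    (the flat-array analogue of the (i, j) pixel tie rule)."""
    return np.argsort(-np.asarray(scores, dtype=np.float64), kind="stable")


def sample_negatives(
    labels: np.ndarray, mask, mode: str, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw the negative pixel set for one evaluation repeat.

    For mode ``k*pos``, ``min(k * n_pos, n_available)`` distinct negatives are
    drawn uniformly without replacement; ``all`` returns every band negative.
    """
    ii, jj = as_pixel_arrays(mask)
    lab = np.asarray(labels.labels if isinstance(labels, LabelMatrix) else labels)
    is_pos = lab[ii, jj] > 0
    n_pos = int(is_pos.sum())
    if n_pos == 0:
        raise ValueError("no positives in band")
    neg_i, neg_j = ii[~is_pos], jj[~is_pos]
    k = NEG_MODE_K[mode]
    if k is None:
        return neg_i, neg_j
    want = k * n_pos
    if want > neg_i.size:
        log.warning(
            "requested %d negatives but only %d available; capping", want, neg_i.size
        )
        want = neg_i.size
    pick = rng.choice(neg_i.size, size=want, replace=False)
    return neg_i[pick], neg_j[pick]


def average_precision(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Non-interpolated AP: mean precision at the rank of each positive."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.sum() < 1:
        raise ValueError("average_precision needs at least one positive")
    order = _score_order(scores)
    y = labels[order].astype(np.float64)
    ranks = np.arange(1, y.size + 1)
    prec_at = np.cumsum(y) / ranks
    return float(prec_at[y > 0].mean())


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 * P(tie)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels) > 0
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs at least one positive and one negative")
    r = rankdata(scores)  # average ranks handle ties with half credit
    return float((r[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def pr_curve(scores: Sequence[float], labels: Sequence[int]) -> List[Tuple[float, float]]:
    """(recall, precision) at every rank of the tie-broken descending order."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    P = labels.sum()
    if P < 1:
        raise ValueError("pr_curve needs at least one positive")
    order = _score_order(scores)
    y = labels[order].astype(np.float64)
    tp = np.cumsum(y)
    ranks = np.arange(1, y.size + 1)
    return list(zip((tp / P).tolist(), (tp / ranks).tolist()))


def topn_accuracy(ranked: Sequence, labels, N: Optional[int] = None) -> float:
    """Percent of ground-truth pixels among the top-N ranked pixels.

    ``ranked`` is the output of the pixel ranking ((i, j, prob) triples, best
    first); ``labels`` the label matrix.  N defaults to the number of
    positives P among the ranked pixels, in which case this equals recall at
    rank P in percent.
    """
    lab = np.asarray(labels.labels if isinstance(labels, LabelMatrix) else labels)
    flags = np.array([lab[i, j] > 0 for i, j, _ in ranked], dtype=bool)
    P = int(flags.sum())
    if N is None:
        N = P
    if N <= 0:
        raise ValueError("N must be positive")
    if N > len(ranked):
        raise ValueError(f"N={N} exceeds number of ranked pixels {len(ranked)}")
    if P == 0:
        return 0.0
    hits = int(flags[:N].sum())
    return 100.0 * hits / min(N, P)


def chip_inner_product_baseline(
    chip, mask, half_window: int = 5
) -> np.ndarray:
    """ChIP-seq-only baseline score for each mask pixel.

    ``score(i, j) = sum_a chip[i + a] * chip[j + a]`` over offsets
    ``a in [-half_window, half_window]``, with the offset range clipped at the
    chromosome ends to those valid for both anchors.  Returns scores aligned
    with the sorted (i, j) order of the mask.
    """
    c = np.asarray(chip.values if isinstance(chip, BinnedTrack) else chip,
                   dtype=np.float64)
    n = c.size
    ii, jj = as_pixel_arrays(mask)
    scores = np.zeros(ii.size, dtype=np.float64)
    lo = np.maximum(-half_window, np.maximum(-ii, -jj))
    hi = np.minimum(half_window, np.minimum(n - 1 - ii, n - 1 - jj))
    for a in range(-half_window, half_window + 1):
        use = (lo <= a) & (a <= hi)
        scores[use] += c[ii[use] + a] * c[jj[use] + a]
    return scores


def evaluate_scores(
    scores: np.ndarray,
    is_pos: np.ndarray,
    spec: EvalSpec,
    ranked_flags: Optional[np.ndarray] = None,
) -> Dict[str, MetricsReport]:
    """Metrics per negative mode for flat per-pixel scores/labels.

    ``scores`` / ``is_pos`` are aligned over all band pixels.  Sampled modes
    are re-drawn ``n_repeats`` times and the metrics averaged.  If
    ``ranked_flags`` (labels in descending-score order over the full band) is
    given, top-N accuracies at the standard multiples of P are attached.
    """
    scores = np.asarray(scores, dtype=np.float64)
    is_pos = np.asarray(is_pos) > 0
    pos_idx = np.where(is_pos)[0]
    neg_idx = np.where(~is_pos)[0]
    if pos_idx.size == 0:
        raise ValueError("no positives in band")
    P = pos_idx.size

    topn: Dict[int, float] = {}
    if ranked_flags is not None:
        ranked_flags = np.asarray(ranked_flags) > 0
        for mult in TOPN_MULTIPLIERS:
            N = max(1, min(int(round(mult * P)), ranked_flags.size))
            hits = int(ranked_flags[:N].sum())
            topn[N] = 100.0 * hits / min(N, P)

    out: Dict[str, MetricsReport] = {}
    for mode in spec.neg_modes:
        k = NEG_MODE_K[mode]
        aps, aucs = [], []
        curve: List[Tuple[float, float]] = []
        reps = 1 if k is None else spec.n_repeats
        for rep in range(reps):
            if k is None:
                sel_neg = neg_idx
            else:
                rng = np.random.default_rng([spec.seed, NEG_MODES.index(mode), rep])
                want = min(k * P, neg_idx.size)
                sel_neg = neg_idx[rng.choice(neg_idx.size, size=want, replace=False)]
            idx = np.concatenate([pos_idx, sel_neg])
            s, y = scores[idx], is_pos[idx].astype(np.int8)
            aps.append(average_precision(s, y))
            aucs.append(roc_auc(s, y))
            if rep == 0:
                curve = pr_curve(s, y)
        out[mode] = MetricsReport(
            ap=float(np.mean(aps)),
            auc=float(np.mean(aucs)),
            pr_curve=curve,
            topn=dict(topn),
            ap_sd=float(np.std(aps)),
            auc_sd=float(np.std(aucs)),
        )
    return out


def evaluate(pred, labels, spec: EvalSpec, unmappable=frozenset()) -> Dict[str, MetricsReport]:
    """Full evaluation of a prediction matrix against a label matrix.

    Pixels come from the upper-triangle band mask (excluding unmappable bins);
    top-N accuracy is computed on the full band ranking and attached to every
    mode's report.
    """
    from .inference import PredictionMatrix  # cycle-free late import
    from .labeling import band_mask_arrays

    probs = pred.probs if isinstance(pred, PredictionMatrix) else np.asarray(pred)
    lab = np.asarray(labels.labels if isinstance(labels, LabelMatrix) else labels)
    grid_n = probs.shape[0]
    if lab.shape != probs.shape:
        raise ValueError("prediction and label shapes differ")

    class _G:  # minimal grid stand-in for band_mask_arrays
        n_bins = grid_n

    ii, jj = band_mask_arrays(_G, spec.band, unmappable)
    scores = probs[ii, jj]
    is_pos = lab[ii, jj] > 0
    order = np.lexsort((jj, ii, -scores))  # rank_pixels tie rule
    ranked_flags = is_pos[order]
    return evaluate_scores(scores, is_pos, spec, ranked_flags=ranked_flags)
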