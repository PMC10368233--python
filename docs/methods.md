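# Methods

## Problem and model

ChIA-PET assays capture the genome-wide chromatin contacts mediated by one
specific protein (CTCF, RNAPII, cohesin subunits), but the assay is costly
and far less widely available than Hi-C.  `chromaloop` casts ChIA-PET
interaction calling as dense per-pixel binary classification on the binned
contact map: given a chromosome's Hi-C contact matrix (assumed already
balanced upstream, e.g. Knight–Ruiz) and the ChIP-seq coverage track of the
mediating protein, predict for every pixel `(i, j)` the probability that the
corresponding bin pair is joined by a ChIA-PET interaction.

The classifier is a dilated residual convolutional network.  The input is a
`C x W x W` tile cut along the matrix diagonal: channel 0 is the normalized
Hi-C tile, channels 1 and 2 are the normalized 1D ChIP-seq window broadcast
row-wise (`x[i, j] = chip[i]`) and column-wise (`x[i, j] = chip[j]`), so each
pixel sees the coverage at both of its anchor bins.  The network is

    Conv 1x1 (C -> H) -> BatchNorm -> ReLU
    B residual blocks, each: Conv 3x3 (dilated, d1) -> BN -> ReLU ->
                             Conv 3x3 (dilated, d2) -> BN, + skip, ReLU
    Conv 1x1 (H -> 1) -> BatchNorm -> logits

with `H = 128` and `B = 40` in the reference configuration.  The 2B dilated
convolutions take their dilation values cyclically from a configurable
schedule, default `(1, 2, 4, 8, 16)`, so consecutive convolutions in a block
always differ and the receptive field grows past the longest evaluated
genomic distance (200 bins at 10 kb).  Batch normalization is used
throughout; instance and group normalization are available as config
options.  A logistic sigmoid converts logits to probabilities at inference
only; the training loss is the numerically stable positive-weighted binary
cross entropy on logits (default positive weight 1).

The network, its backward pass, and the Adam optimizer are implemented
directly in NumPy (im2col convolutions, hand-derived batch/group-norm
gradients).  The backward pass is verified against central finite
differences in float64 in the test suite.

## Data preparation

All coordinates are 0-based half-open; bin `b` at resolution `r` covers
`[b*r, (b+1)*r)`.  Hi-C is read from Juicer-dump-style triplet text (or a
dense matrix); entries are mirrored across the diagonal, non-finite values
are zeroed together with their mirror entries, and all-zero rows are flagged
unmappable and excluded from evaluation.  ChIP-seq bedGraph intervals are
averaged per bin (overlap-weighted, uncovered stretches count as zero).
ChIA-PET BEDPE anchors label pixel `(i, j)` positive iff bin `i` strictly
intersects one anchor and bin `j` the other; the label matrix is symmetric.

Normalization: Hi-C is `log2(x + 1)` followed by per-chromosome min-max to
[0, 1]; ChIP-seq is per-chromosome min-max.  A single pooled mean/SD pair per
data type, fitted over the training windows and then frozen, applies the
final z-score — new datasets are normalized with the reference statistics
rather than their own, which is what lets a model trained on one cell type
transfer to others.

Tiles of `W x W` are cut along the diagonal with step `s` (`250/50` at
10 kb, `500/100` at 5 kb); a final clipped origin `n - W` is appended so
chromosome tails are always covered (tail handling is this package's
choice).  Every pixel within `W - s` bins of the diagonal — which contains
the whole evaluation band — is covered by at least one tile; the property is
asserted exhaustively in the tests for all chromosome lengths from 250 to
1000 bins.

## Training protocol

For a held-out test chromosome, validation tiles come from the largest
remaining chromosome and training tiles from all others, so no test pixel
influences fitting or model selection.  Optimization is Adam (weight decay
1e-4); the learning rate is multiplied by 0.1 when validation loss has not
improved for 10 epochs, and the returned checkpoint is the epoch with
minimum validation loss.  All pixels of every tile, positive and negative,
enter the loss.  Training stops at `max_epochs` or after 3 learning-rate
reductions without improvement (the epoch budget and stopping rule are this
package's choices).

Because positives are a fraction of a percent of all pixels, a freshly
initialized network spends its first epochs collapsing toward the
all-negative prediction; that transient can masquerade as a validation-loss
minimum and poison both checkpoint selection and the plateau scheduler.  The
output shift is therefore initialized to the training-set base-rate logit
`log(p / (1 - p))` (the standard prior initialization for heavily imbalanced
dense classification), so epoch 0 already sits at the trivial optimum and
any subsequent improvement reflects real discrimination.

## Inference

Tiles are predicted independently; each pixel's score is the mean
probability over all tiles covering it (probabilities, not logits, are
averaged — the averaged quantity is the reported score), and the matrix is
then averaged with its transpose, making it exactly symmetric.  Pixels are
ranked by descending probability with ties broken by ascending `(i, j)`, so
rankings are fully deterministic.

## Evaluation

Only pixels with genomic distance in [20 kb, 2 Mb] are evaluated — bins
2–200 at 10 kb, 2–400 at 5 kb (`d_min = ceil(20 kb / r)`,
`d_max = floor(2 Mb / r)`), upper triangle only, excluding unmappable bins.
Negatives outnumber positives by hundreds to one, so metrics are reported
over five negative sets: `neg = pos, 5pos, 20pos, 100pos` (uniform draws
without replacement, re-drawn 10 times and averaged) and `neg = All`.

* **AP** is non-interpolated average precision (mean precision at each
  positive's rank) with the same tie rule as the pixel ranking.
* **AUC** is the Mann–Whitney pair probability with half credit for ties.
* **Top-N accuracy** is the percentage of ground-truth pixels among the N
  highest-ranked band pixels; N defaults to the positive count P, where it
  equals recall at rank P.

Both AP and AUC are verified against exhaustive brute-force oracles (all
ranks; all positive–negative pairs) to 1e-12, and against scikit-learn on
tie-free inputs.  A ChIP-seq-only baseline scores pixel `(i, j)` by the
inner product of the coverage windows `[i-5, i+5]` and `[j-5, j+5]`
(clipped at chromosome ends).  Shuffle controls permute the ChIP-seq bin
vector, or the upper-triangle Hi-C entries (mirrored to keep the input a
valid symmetric map), before tiling.

## Synthetic data generator

The generator emulates the joint structure the pipeline exploits, with every
random draw flowing from one seed:

| parameter | default | meaning |
| --- | --- | --- |
| `chrom_bins` | chrA 520, chrB 560, chrC 480 | three chromosomes, ~500 bins at 10 kb |
| `decay_amplitude` A | 300 | expected count at distance 0 |
| `decay_exponent` alpha | 1.0 | power-law contact decay `A (1+d)^-alpha` |
| `tad_boost` | 1.6 | multiplicative boost for same-TAD pixels (TADs ~90 bins) |
| `n_loops` | 60 | planted loops per chromosome, distinct anchor bins |
| `loop_distance_range_bins` | (4, 44) | loop distances, inside the band (2, 48) |
| `loop_enrichment` | 4.0 | multiplicative Hi-C enrichment at loop pixels |
| `chip_peak_amplitude` | 8.0 | coverage added at anchor and decoy bins |
| `chip_background_rate` | 1.0 | exponential background coverage |
| `decoy_peak_fraction` | 0.08 | fraction of bins given peaks *without* loops |

Hi-C counts are Poisson draws around the closed-form expectation (checked by
Monte Carlo in the tests); ChIA-PET anchors are the planted loop bins'
intervals, so the derived label matrix equals the planted pixel set exactly.
Decoy ChIP-seq peaks ensure coverage alone cannot classify perfectly, which
is what makes the channel-ablation ordering (both > Hi-C-only > ChIP-only) a
meaningful check rather than a tautology.

What the generator does **not** emulate: balancing-bias artifacts and
unmappable regions, anchor-length variation beyond one bin, distance-
dependent noise correlations, cell-type mixtures, and the sheer scale of
real chromosomes.  Passing the desk-scale tests therefore demonstrates that
the pipeline's machinery — labeling, normalization, tiling, optimization,
merging, evaluation — is correct and that the network can exploit planted
joint structure; it does not certify real-data accuracy levels.

## Desk-scale configuration

The end-to-end tests and the acceptance script run a scaled-down instance:
window 64, step 16, band 2–48 bins, hidden dimension 16, 4 residual blocks,
three ~500-bin chromosomes.  With a single training chromosome there are
only ~7 gradient steps per epoch, so from the standard tuning grid the
smallest batch size (4) and the largest initial learning rate (0.01) win on
validation loss and are the desk-scale defaults (`DESK_TRAIN`); the
reference-scale defaults remain batch 16 / lr 0.001.  A training run takes
about two minutes on one CPU core; the full acceptance computation (three
channel configurations, shuffle controls, baseline) about five.

## Numerical choices and edge cases

* Constant matrices/tracks min-max to all zeros; reference SDs are floored
  at 1e-8 with a warning.
* Duplicate symmetric triplet entries overwrite (with a warning), not sum.
* Negative-count triplet rows are rejected; out-of-grid bins are errors
  naming the offending line.
* Chromosomes shorter than the window produce a single zero-padded tile;
  padded pixels are masked out of the loss and contribute nothing to
  prediction averaging.
* Checkpoints (npz) store weights, model config, normalization statistics,
  and channel order, so prediction never depends on the training session.

## Known limitations

* The per-block dilation schedule of the reference network is exposed in the
  config; the default cycle `(1, 2, 4, 8, 16)` is this package's choice.
* Whether overlapping-tile averaging should combine logits or probabilities
  is underdetermined; probabilities are averaged here.
* Evaluation counts each interaction once (upper triangle); positive counts
  are therefore per unordered pixel pair.
* No loop clustering: outputs are per-pixel, not merged loop calls.
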