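# Methods

## The reverse-homology task

Intrinsically disordered regions (IDRs) evolve quickly in primary sequence
while often conserving function through short linear motifs (SLiMs) and
distributed "bulk" properties (composition, charge, repeats). The package
implements a self-supervised proxy task built on that observation: given a
*query set* S_q of homologous IDRs drawn from one homolog set H_i, the
model must identify the held-out homolog s_t+ among a target set that
otherwise contains only sequences from other homolog sets. Whatever
features let the model do this must be features that evolution preserves
within homolog sets — which is exactly the class of features an IDR
biologist wants surfaced.

Two encoders are trained jointly: g1 embeds each query sequence and the
query-set representation is the arithmetic mean of its members (features
idiosyncratic to a single homolog average out); g2 embeds each target.
The score is the dot product f = g1(S_q) · g2(s_t), and the objective is
the InfoNCE loss

    L = −E[ log exp(f+) / (exp(f+) + Σ_j exp(f−_j)) ],

a categorical cross-entropy over one positive and M−1 negatives, computed
through a numerically stable log-sum-exp. Minimizing it maximizes a lower
bound on the mutual information between query-set and held-out-homolog
representations; a larger target set M tightens the bound.

## Architecture

Each encoder is a deliberately small, interpretable CNN:

| stage | default | purpose |
|---|---|---|
| conv1 | parallel kernels 1/3/5, 64 filters each | residue content up to short motifs |
| conv2 | kernel 7, 256 filters | context integration |
| conv3 | kernel 5, 256 filters | final per-position feature map |
| pooling | max + average over all positions | presence/absence vs distributed signals |
| head | two dense layers, 256 → 256 | combines pooled features into the representation |

All convolutions use same-length zero padding and rectifier activations
(final dense layer linear); per-position activations therefore exist for
every residue, which the interpretation suite relies on. The receptive
field of conv3 is 5 + (7−1) + (5−1) = 15 residues. Max pooling returns a
channel's best window anywhere in the sequence; average pooling returns
its mean activation, multiplied by L_std / RF = 256/15 ≈ 17.07 (printed as
17.06 after truncation) so that a channel active across the whole sequence
and a channel active in a single window land on comparable numerical
scales. The 256 max-pooled plus 256 scaled-average-pooled values are the
512 "pooled features" that all downstream interpretation uses.

The exact per-layer filter counts of the original architecture are not
fully recoverable from its description; the defaults here honor the two
hard constraints that are stated — 512 pooled features (hence 256 conv3
channels) and a 15-residue receptive field — and every count is
configurable. g1 and g2 are independently parameterized by default, with a
`share_weights` flag that makes the score a symmetric kernel (see
*Desk-scale planted-recovery experiment* for when that matters).

The network, backpropagation and Adam are implemented directly in NumPy
(`revhom.nn`): float64 throughout, convolution as an im2col view plus one
tensor contraction, gradients hand-derived and verified against finite
differences in the test suite. All randomness flows through
`numpy.random.Generator`, so training is bitwise reproducible per seed.

## Preprocessing

Sequences enter the model one-hot encoded over the fixed alphabet
ACDEFGHIKLMNPQRSTVWY at a standard length L_std = 256: longer sequences
keep their first and last 128 residues (a `center` crop is available as an
option), shorter ones are repeat-padded ("ACD" → "ACDACD" → clipped at
L_std). Repeat padding rather than a padding token deliberately removes
sequence length as a trivially discriminative cue; for the same reason the
initiator methionine is clipped from N-terminal IDRs. Met clipping runs
before length standardization so padding cannot replicate the artifact.

## Dataset construction

`revhom.homolog_data` reproduces the heuristics used to build homolog sets
from whole-protein alignments (alignment itself, disorder prediction and
ortholog retrieval are consumed as files from external tools):

- IDRs are clipped from each aligned ortholog at the alignment columns
  spanned by the reference IDR interval; all-gap rows are dropped.
- Homologs shorter than 5 aa, containing X or non-standard residues, or
  more than 3× longer/shorter than the reference are removed (exactly 3×
  is kept — the boundary is read permissively).
- Evolutionary distance is the amino-acid F81 method-of-moments estimate
  d = −B ln(1 − p/B), B = 1 − Σπ², with π defaulting to the empirical
  frequencies of the dataset's reference IDRs; p ≥ B is saturated,
  reported as infinite, and capped (default 10 subst/site) when summed.
- Homologs are admitted closest-first, skipping any candidate whose
  distance to an already-admitted member is below `redundancy_factor`
  times its distance to the reference. The published description ("less
  than 5x the distance from the reference") is ambiguous in direction — a
  literal factor of 5 excludes nearly everything — so the default is 0.2
  (= 1/5), with 5.0 reachable through configuration and the factor echoed
  in logs. Admission stops when the total pairwise distance among
  admitted members (reference included; a reference-distances-only total
  is available by flag) reaches 30 substitutions per site.
- Overlapping reference IDRs on one protein are deduplicated keeping the
  longest (ties: smaller start, then id).

External files use 1-based inclusive coordinates; everything internal is
0-based half-open, converted only at I/O boundaries.

## Training

Each epoch visits every training homolog set exactly once: q = 8 members
form the query set and one more is the positive. Batches share one target
list — the B positives plus M − B fillers drawn from sets absent from the
batch — so each episode's positive serves as a negative for the others.
Defaults follow the published recipe: q = 8, M = 400, batch 64, plain
Adam at 1e-4 for 1000 epochs (no schedule, no decay; a decoupled
weight-decay option exists, default 0). The last partial batch of an
epoch is kept with proportionally fewer fillers. Validation is a 90/10
split by set, with any validation set whose reference is homologous to a
training reference (externally supplied pair list) discarded outright.
Episode accuracy counts ties as incorrect. The best-validation checkpoint
is retained alongside the final one.

## Interpretation

*Sequence logos.* For a channel of conv3, sequences reaching ≥ 70% of the
dataset-maximal pooled activation are collected (the top 20 if fewer
qualify). Max-pooled features contribute their single best RF-window with
weight 1; average-pooled features contribute every window weighted by its
activation relative to the sequence's best window. Window positions
hanging over a sequence end contribute nothing to those PFM columns. The
PFM converts to per-column probabilities and an information-content logo
(0 to log2 20 ≈ 4.32 bits, displayed capped at 4.0).

*Mutation maps / letter maps.* Every residue is substituted to every
alternative and the change in the pooled feature value recorded
(L × 20 deltas, zero at the wild type). Deltas are computed on the
standardized sequence but indexed by original coordinates; repeat-padded
copies of a residue are mutated together so one biological substitution
is one matrix entry, and positions removed by cropping are flagged. A
position is drawn above the axis when mutations on balance decrease the
feature (favourability is defined with magnitude Σ|Δ| and the sign of
−ΣΔ); above-axis positions display the residues giving the highest
feature values, below-axis the lowest, up to three letters with
sub-heights proportional to |Δ|. The span of a max-pooled feature on an
IDR is the smallest interval containing all positions whose summed delta
is ≤ −10 (cutoff configurable, applied to ΣΔ).

*Residue-level predictions.* Per-position channel activations are
smoothed with a Gaussian kernel of standard deviation 15 residues
("width 15" is read as the SD; truncation at 4 SD, reflective
boundaries, kernel normalized to sum 1) and residues ranked by the
smoothed trace; recall at a fixed coverage is the fraction of annotated
residues among the top-coverage ranked ones.

## Downstream statistics

Regex features are binarized per position (1 inside any, possibly
overlapping, match); the correlation of a feature with a channel is the
Pearson correlation (Spearman by flag) between the concatenated binarized
traces and the channel's activation traces over all standardized
sequences, maximized over channels, with zero-variance channels scored 0.
Trained models are compared against an identically configured random
initialization feature-by-feature, with a paired t-test per category.
Label enrichment counts, among proteins carrying a label, those whose
nearest neighbor in pooled-feature space (cosine by default, Euclidean by
flag) shares the label, over the label's background frequency. Per-set
feature enrichment is a Welch t-test per feature. Fisher's exact test and
the t-tests delegate to scipy; the test suite cross-checks Fisher against
a from-scratch hypergeometric enumeration. The feature-feature distance
map is 1 − Pearson r across IDRs; 2-D embedding of that matrix is left to
external libraries.

## Synthetic data

`revhom.synthetic` generates homolog sets with exact ground truth.
Background residues are i.i.d. from a disorder-biased composition
(elevated S/T/P/E/K/Q, W and C nearly absent; the vector is in
`DISORDER_FREQS`), lengths log-normal (median ≈ 55) clipped to [5, 600].
A *motif* plant realizes its consensus once per carrier set (per-position
substitution probability at realization — carrier sets are therefore
mutually distinguishable), places it uniformly at least RF/2 from the
ends (togglable), and each homolog inherits the set's variant exactly
with the conservation probability, otherwise the region drifts like
background. A *bulk* plant mixes the set's background composition toward
a target vector. Homologs are derived from the reference by independent
per-site substitution — a star phylogeny with no indels.

What this does **not** emulate: realistic phylogenetic correlation
between homologs, indels and alignment error, heterogeneous set sizes,
shared composition classes between unrelated IDRs, and multi-feature
interactions. Passing the planted-recovery tests therefore shows the
pipeline can learn and surface conserved features under controlled
conditions; it does not certify performance on real proteomes.

## Desk-scale planted-recovery experiment

The end-to-end check trains tiny models on 200 synthetic sets (12 members,
per-site divergence 0.3, half carrying a conserved 6-mer consensus
WFRYPH with per-position realization noise 0.1): 16 filters per branch,
conv2 32, conv3 32 channels, dense head 64/64, L_std = 64 with background
lengths ~24–64, q = 4, M = 50, batch 8, Adam 1e-3, 30 epochs — about 40 s
per training on one CPU core. At this data scale independent encoders
memorize the training sets, so the experiment uses the `share_weights`
option; the full-scale defaults keep independent encoders.

Two quantities are asserted over ten seeds: mean accuracy on freshly
drawn episodes (the positive held out from its query set, negatives from
other sets) of ≈ 0.6 against a 2% chance level, and — in at least 9 of 10
seeds — a higher maximal channel correlation with the planted consensus
regex for the trained model than for an untrained twin. The stricter
generalization number, accuracy on homolog sets excluded from training
entirely, is logged by `train()` and reaches ≈ 0.24–0.50 here; it grows
with dataset size and epochs (≈ 0.5 by 100 epochs) and is the quantity
comparable to the published full-scale held-out accuracies.

## Numerical and degenerate-input conventions

- InfoNCE is computed via log-sum-exp; uniform scores give exactly ln M.
- Accuracy ties count as incorrect (conservative).
- Dead features (never activating) are an error in logo construction,
  excluded with a warning in distance maps, and excluded from z-score
  rankings when constant.
- Saturated F81 distances sort last, always pass the redundancy test and
  enter totals at the saturation cap.
- Zero-variance channels/regexes yield correlation 0 / a flagged NaN
  rather than raising.
- Fisher's test requires positive margins; proportion ratios require a
  nonzero denominator proportion.
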