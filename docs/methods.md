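# Methods

## The procedure

`layerprune` implements single-layer ablation profiling for encoder-only
transformer classifiers of variant-centred DNA sequences, and the
structured-pruning decisions built on top of it.

For a pretrained encoder with layers indexed 0 … n−1 (layer 0 is the
first encoder block; embeddings are never removable), the profiling grid
runs one *condition* per layer plus one baseline condition:

1. clone the pretrained model;
2. remove the condition's layer (baseline: remove nothing);
3. fine-tune the clone on the training split;
4. evaluate on the test split (accuracy, AUROC, F1, %TP = TP/(TP+FN)·100,
   all percents, plus the confusion counts and wall times).

Every condition is repeated once per seed in a shared seed list and
aggregated as mean μ and sample standard deviation σ (n−1 denominator;
σ = 0 when a condition has a single run, with a logged warning). The
seed controls everything downstream of the pretrained weights — the
fresh classification head and the per-epoch shuffling — while the
pretrained weights themselves are never re-drawn.

Two fine-tuning regimes are provided, mirroring the practical trade-off
between convergence training and a fixed compute budget:

* `to_convergence`: stop when validation loss has not improved by more
  than `convergence_tol` (default 1e-4, absolute) for `patience`
  consecutive epochs (default 5), capped at `max_epochs` (default 50);
  the best-validation-loss weights are restored.
* `fixed_epochs`: exactly `fixed_epochs` epochs (default 5), final
  weights kept.

## Layer-type rules

Let μ_m,b be the baseline mean of metric m and μ_m,ℓ the mean with layer
ℓ removed. Two deterministic rules categorise each layer:

* **Unfavourable** — removal leaves performance at or above baseline.
  Per metric the criterion is μ_m,ℓ ≥ μ_m,b − tol_m, where tol_m is one
  standard deviation of m (by default the ablated condition's own σ
  across its repeated runs; the baseline's σ or a pooled RMS σ can be
  selected instead). A reduction within one σ counts as equal
  performance; equality satisfies the criterion; with a single run the
  tolerance degenerates to 0 and the comparison is strict. The layer is
  unfavourable when at least 3 of the 4 criteria hold (`min_criteria`).
* **Cornerstone** — removal makes *every* metric at least 5% worse than
  baseline (`cornerstone_drop = 0.05`). "5% worse" is ambiguous between
  a relative drop and absolute percentage points; the default is the
  relative reading, μ_m,ℓ ≤ 0.95·μ_m,b, because it is scale-free across
  metrics, and an `absolute_points` mode implements the other reading.
  A value exactly on the cutoff counts as dropped.

Everything else is "other". The categories are mutually exclusive and
exhaustive; should extreme tolerances ever make a layer satisfy both
rules, cornerstone wins and the layer is flagged as a rule conflict.
No multiple-testing correction is applied: the rules are a decision
procedure, not a hypothesis test.

From a classification, two pruned variants are built — always from the
pretrained weights, never from an ablation run — and compared with the
baseline under identical data, configuration and seeds:

* `minus_unfavourable`: all unfavourable layers removed;
* `cornerstone_only`: all non-cornerstone layers removed.

Fine-tuning and evaluation wall times are reported as proportions of the
baseline, computed within seed and then averaged; absolute seconds are
never compared across platforms. A profile can legitimately contain no
cornerstone layer (a well-trained small model often recovers fully from
any single-layer removal); the strict variant constructor treats an
empty cornerstone set as an error, while the pipeline skips the
infeasible variant and records why.

## The tiny reference encoder

The reference model is a pre-LayerNorm transformer encoder implemented
directly in numpy (float64) with hand-derived backpropagation and a
standard Adam optimizer. Inputs are tokenized one nucleotide per token
(A, C, G, T, N, plus padding) with a leading classification token;
pooling is the classification-token state (a padding-aware mean is
available); the head is a linear map to 2 logits trained with softmax
cross-entropy. Defaults: 4 layers, width 32, 4 heads, feed-forward 64,
≈39k parameters.

The implementation is verified by central-difference gradient checks
over every parameter tensor (agreement to ~1e-10 absolute) and is
bit-reproducible for a given seed on a given platform, which is what
makes byte-identical pipeline reruns possible. Dropout is omitted: at
this scale it is not needed for the signal to be learned, and its
absence keeps runs exactly reproducible; seed-to-seed variation comes
from head initialisation and data ordering.

Because the published genomic language models arrive pretrained while
the tiny encoder starts from random weights, the pipeline gives it a
supervised pretraining phase — convergence training on the training
split — before the ablation grid begins. The grid then fine-tunes
clones of this pretrained reference exactly as it would clones of an
external checkpoint. The learning rate default is 1e-3 with batch 32:
at width 32 the commonly used smaller rates (≈3e-4) converge so slowly
that convergence-mode patience can trigger before the motif detector
forms.

External checkpoints (e.g. DNABERT-2-class or Nucleotide
Transformer-class encoders) participate through an adapter contract
that only requires an enumerable encoder-layer stack; the adapter needs
`torch`/`transformers` at call time and raises a resource error when
they are unavailable. Tokenizer internals and positional-encoding
schemes of such models are deliberately out of scope.

## The synthetic benchmark

The generator emulates the *structure* of an eQTL causal-variant
classification task: fixed-length sequences centred on a variant
position (0-based index ⌊L/2⌋), binary pathogenic/benign labels, exact
class balance before label noise. The signal is a planted motif:

* pathogenic sequences contain the causal motif (default `TATAAT`,
  length 6) with its centre within `placement_window` (default 2)
  positions of the sequence centre — so the motif always overlaps the
  variant position itself, the geometry of a causal variant creating or
  disrupting a binding site at its own locus;
* benign sequences are rejection-sampled (cap 1000 draws per record)
  until they contain no occurrence of the motif anywhere;
* optional decoy motifs appear in both classes at uniform positions and
  carry no label information; optional label noise flips a seeded
  fraction of labels after planting, leaving sequences untouched.

With zero label noise an exhaustive substring scan is therefore a
perfect classifier, giving every downstream accuracy a known ceiling of
100%. Generation is a pure function of its arguments and seed, and the
CSV serialization (`id,sequence,label`) round-trips losslessly.

What the generator does *not* model: real regulatory grammar, chromatin
context, linkage between variants, distributional shift between train
and test, or realistic effect sizes. Passing tests on this benchmark
demonstrate that the *machinery* — surgery, training, metrics, rules,
reporting — is correct and that the reference encoder can learn a
planted signal; they say nothing about the predictive performance of
any model on real non-coding variants.

## Problem sizes and defaults of the desk-scale study

The packaged end-to-end study (also what `scripts/acceptance.py` runs)
uses: n_train = 2000, n_val = 200, n_test = 400, L = 64, label noise 0;
a 4-layer width-32 encoder; pretraining to convergence; fine-tuning for
3 fixed epochs per condition; seeds {s, s+1, s+2}. This yields
1 + 4 = 5 conditions × 3 seeds = 15 fine-tune runs for the profile and
completes in minutes on one CPU. Under these conditions the pretrained
baseline reaches ≈97% test accuracy (motif-scan oracle: 100%), single
layer removals are largely recovered within 3 epochs of fine-tuning,
and the unfavourable rule consequently marks most layers — the expected
behaviour for a small, fully-converged model on a saturated task.

Verification oracles run alongside the study: rank-based AUROC against
exhaustive positive–negative pair counting (1,000 random sets, n ≤ 50),
the 3-of-4 rule against enumeration of all 16 criterion assignments
(5 positives), the cornerstone rule against direct arithmetic in both
drop modes (1,000 random aggregate pairs), planted-category recovery on
1,000 simulated noisy profiles (≥ 99% required when per-metric noise SD
stays below half the rule margins), and parameter-count conservation
over every removal set of size ≤ 2.

## Numerical choices

* All metrics are percents in [0, 100]; predictions are
  `score ≥ threshold ⇒ positive` with threshold 0.5 (config-exposed).
* AUROC uses the midrank tie convention (ties count ½), matching the
  pair-counting definition exactly.
* F1 is the positive-class harmonic mean, defined as 0 when precision
  and recall are both 0; %TP is recall·100.
* Aggregation uses the sample SD (ddof = 1).
* Training is float64 throughout; losses are guarded against non-finite
  values (named-epoch error rather than silent corruption).
* Profile persistence streams each finished run to disk; resuming
  verifies a digest of data, configuration, seeds and pretrained
  weights and refuses stale directories.

## Known limitations

* The equal-performance tolerance collapses to strict comparison with a
  single run per condition, making the unfavourable rule brittle there.
* Wall-time proportions measured at desk scale are noisy; they are
  reported for protocol completeness, not as efficiency claims.
* The reference encoder's single-nucleotide tokenizer and small width
  are not representative of production genomic language models; the
  adapter contract exists precisely so the same procedure can be
  applied to them where their frameworks are available.
* The benchmark loader reports the class counts it actually finds and
  takes no position on discrepancies in published dataset descriptions.
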