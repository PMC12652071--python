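# layerprune

Layer-wise ablation profiling and structured pruning of transformer
encoders for non-coding variant effect prediction.

Genomic language models classify single-nucleotide variants as
pathogenic or benign from a variant-centred DNA window, but their size
makes fine-tuning and inference expensive. Not all encoder layers
contribute equally: some are redundant and some are load-bearing. This
toolkit measures each layer's contribution empirically and prunes
accordingly. It is aimed at researchers profiling DNA sequence
classifiers who want a reproducible, CPU-friendly harness for the
ablate → classify → prune protocol, with an adapter contract for real
pretrained checkpoints.

## The procedure

For a pretrained encoder with layers 0 … n−1, the profile runs a
baseline condition plus one condition per layer: clone the pretrained
model, remove that single layer, fine-tune the clone, evaluate. Each
condition is repeated over a shared seed list and aggregated as
μ ± σ (sample SD) for accuracy, AUROC, F1 and %TP = TP/(TP+FN)·100.

Layers are then categorised by two decision rules:

* **unfavourable** — removal leaves performance at or above baseline:
  μ_m,layer ≥ μ_m,baseline − σ_m must hold for at least 3 of the 4
  metrics (a reduction within one SD counts as equal performance);
* **cornerstone** — removal makes *every* metric at least 5% worse:
  μ_m,layer ≤ 0.95·μ_m,baseline for all m (an absolute-points mode is
  also available);
* everything else is **other**.

Finally two pruned variants — the model minus all unfavourable layers,
and the model keeping only cornerstone layers — are fine-tuned from the
pretrained weights and compared with the baseline, including fine-tune
and evaluation time as proportions of the baseline.

Everything runs on one CPU: the package ships a tiny numpy transformer
encoder (hand-verified backpropagation, bit-reproducible) and a
synthetic planted-motif benchmark that emulates the structure of an
eQTL causal-variant task, so the whole pipeline is testable without
GPUs or downloads. See `docs/methods.md` for the model, the rules'
edge cases and the generator's scope.

## Worked example

```python
from layerprune import (
    EncoderConfig, FineTuneConfig, LayerAblation, MotifModel,
    build_tiny_encoder, fine_tune, generate_dataset,
)

# synthetic eQTL-like task: 64-bp variant-centred windows, balanced labels,
# causal motif TATAAT planted over the central position in pathogenic records
train, val, test = generate_dataset(2000, 200, 400, L=64,
                                    motif_model=MotifModel(), seed=0)

# the tiny reference encoder plays the pretrained model: train to convergence
encoder = build_tiny_encoder(EncoderConfig(), seed=0)
pretrained, _ = fine_tune(encoder, train, val,
                          FineTuneConfig(mode="to_convergence", reinit_head=False))

# profile: baseline + one condition per layer, 3 seeds each (15 runs)
model = LayerAblation(pretrained, train, val, test,
                      finetune_config=FineTuneConfig(mode="fixed_epochs",
                                                     fixed_epochs=3),
                      seeds=[0, 1, 2])
results = model.fit()
print(results.summary())
```

```
Layer Ablation Results
==============================================================================
Layers: 4      Seeds per condition: 3    Parameters: 38626
------------------------------------------------------------------------------
 removed        accuracy           auroc              f1          pct_tp  category
------------------------------------------------------------------------------
    none    97.00±0.43     98.41±0.33     97.07±0.45     99.33±1.15   baseline
       0    90.42±1.91     96.25±0.66     91.16±1.46     98.33±2.08   other
       1    97.08±0.58     98.33±0.20     97.17±0.55    100.00±0.00   unfavourable
       2    96.50±1.09     98.24±0.20     96.63±1.02    100.00±0.00   unfavourable
       3    96.67±0.63     98.24±0.62     96.78±0.59    100.00±0.00   unfavourable
------------------------------------------------------------------------------
Layer types: cornerstone=0, unfavourable=3, other=1 (of 4)
```

Reading the table: the baseline (no layer removed) reaches 97.0% test
accuracy on the planted-motif task (a motif-scan oracle reaches 100% by
construction). Removing layer 0 costs ~6.6 accuracy points — the first
layer carries most of the motif detector — but because %TP barely moves,
not *all* metrics drop 5%, so it is "other" rather than cornerstone.
Layers 1–3 are unfavourable: the model recovers fully within three
epochs of fine-tuning, so they are candidates for removal. Downstream:

```python
clf = results.classify()            # per-layer categories + rule detail
report = results.compare_variants() # baseline vs pruned variants
print(report.to_dataframe())
```

```
      removed  finetune_time_prop  eval_time_prop   accuracy      auroc         f1
0        none            1.000000        1.000000  97.000000  98.406667  97.066309
1       1,2,3            0.272348        0.236606  96.583333  98.372500  96.652513
```

Removing the three unfavourable layers keeps accuracy within half a
point of baseline while cutting fine-tuning time to ~27% — the
qualitative signature that motivates informed structured pruning.

The same study runs from the shell:

```bash
layerprune simulate --out data/            # planted-motif CSV splits
layerprune run --config examples/study.yaml
layerprune classify --profile out/profile/profile.json --cornerstone-drop 0.05
layerprune report --profile out/profile/profile.json
```

Real data and real checkpoints enter through the same contracts:
`load_benchmark_split()` reads the eQTL causal-variant benchmark
(Hugging Face `datasets` required, or a local CSV cache), and
`load_external_encoder()` wraps any encoder-only transformer checkpoint
whose layer stack is enumerable (torch + transformers required).

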