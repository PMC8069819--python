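# kernelfc

Single-trial Gaussian-kernel functional connectivity (GFC) features for
motor-related EEG decoding.

## The problem

Decoding motor imagery or motor execution from EEG usually leans on
spatial filtering (CSP) of band power, which degrades under the strong
inter- and intra-subject variability that drives BCI inefficiency.  An
alternative is to decode from *functional connectivity* — statistical
dependencies between channel pairs — estimated on single trials.
`kernelfc` implements such a pipeline around a Gaussian-kernel
connectivity measure and two standard baselines, for researchers who
want a reproducible, fully tested reference implementation that runs on
synthetic ground-truth data out of the box.

## The method

For each trial, the signal is decomposed with a Butterworth filter bank
(e.g. 17 overlapped 4 Hz bands over 4–40 Hz for motor imagery) and
overlapping sliding windows (τ ∈ [0.5, 2] s, 75% overlap).  For every
(band *n*, window *t*) split and channel pair (c, c′), connectivity is

- **GFC**: κ_G(x_c, x_c′) = exp(−‖x_c − x_c′‖² / 2σ²), with σ from the
  median heuristic (median pairwise channel distance per split, averaged
  over splits of the training trials);
- **CCF**: Pearson correlation of the windowed series;
- **PLV**: |mean_t exp(j(φ_c − φ_c′))| with Hilbert-transform phases.

The vectorized (band, window, pair) features are matched to the 0/1
labels by an elastic net (MSE + α₁‖v‖₁ + α₂‖v‖₂², penalties chosen by
seeded inner CV), whose sparse coefficients both select features for a
shrinkage LDA classifier — scored by stratified 10-fold CV — and provide
relevance weights for interpretation: per-pair and per-channel relevance
maps, links above the 99th relevance percentile, and t-SNE + k-means
clustering of subjects into performance groups I/II/III.  A CSP-style
generalized eigendecomposition (S₁w = λ(S₁+S₂)w) applied to the FC
matrices is available as an alternative feature representation.

Everything is validated on a synthetic coupled-oscillator EEG generator
that plants class-dependent shared-source coupling in chosen bands,
windows and channel pairs, with 1/f + white noise at a configurable SNR.

## Worked example

```python
import kernelfc as kfc

# simulate one subject: 8 channels, 100 trials/class, one planted
# 8-12 Hz coupling on channel pair (0, 1) at gain 0.9, SNR 5 dB
epochs, truth = kfc.generate(kfc.strong_coupling_spec(seed=1))

bank = kfc.strong_coupling_bank()           # five 4 Hz bands, 4-24 Hz
result = kfc.decode_cv(epochs, k=10, seed=1, bank=bank, tau=1.0, measure="gfc")
print(f"GFC 10-fold accuracy: {result.mean_accuracy:.3f} ± {result.std_accuracy:.3f}")

# relevance model on all trials, and where the information sits
windower = kfc.FilterBankWindower(fs=epochs.fs, bank=bank, tau=1.0, overlap=0.75)
seg = windower.fit(epochs.data).transform_epochs(epochs)
X, index_map = kfc.vectorize(kfc.connectivity_tensor(seg, "gfc", kfc.median_sigma(seg)))
model = kfc.fit_relevance(X, epochs.labels.astype(float), seed=1)
pair_rel = kfc.pair_relevance(model, index_map, n_pairs=28)
print("top link:", kfc.top_links(pair_rel, 8, percentile=90)[0])
truth_cols = kfc.resolve_truth(truth, bank, kfc.WindowSpec(1.0, 0.75))
print("support recovery:", kfc.recovery_score(model, truth_cols, 2 * len(truth_cols)))
```

prints

```
GFC 10-fold accuracy: 0.965 ± 0.032
top link: (0, 1, 1.0)
support recovery: 1.0
```

i.e. the kernel features decode the planted coupling almost perfectly,
the strongest relevance link is exactly the coupled channel pair, and
every ground-truth (band, window, pair) feature column is recovered
within twice the truth-set size.

The same pipeline is scriptable from the shell:

```bash
kernelfc simulate --preset strong-coupling --seed 1 --out subject.h5
kernelfc evaluate --in subject.h5 --measure gfc --tau 1.0 --out result.json
kernelfc sweep --config experiment.yaml     # tau x measure comparison table
```

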