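# amanet

Motor-imagery EEG decoding toolkit: sliding-window / CSP / amplitude-scaling
data augmentation, a multi-scale temporal attention convolutional network
with efficient channel attention (ECA), and a cross-validation, ablation and
parameter-sweep harness. Everything runs on synthetic EEG with known class
structure, so the full pipeline is testable without external recordings.

The network and training loop are implemented in NumPy (no deep-learning
framework dependency): explicit forward/backward passes per layer, verified
against finite differences in the test suite, trained with Adam.

## Architecture

Input windows `(1, C1, T1)` flow through:

1. **MS-Block** — three parallel temporal convolutions (kernels 8/16/24,
   `F1` filters each, batch-norm + ELU) fused back to `F1` channels by a
   pointwise convolution (or an element-wise sum, `ms_fusion=sum`).
2. **ST-Block** — grouped spatial convolution collapsing the `C1` axis
   (multiplier `D`), a temporal convolution of length `K1/4`, average
   pooling (1, 4) and dropout.
3. **ECA** — global average pooling per channel, a bias-free 1-d
   convolution across the channel axis (fixed `k=3` or the adaptive rule
   `k ≈ (log2 C + 1)/2` rounded to the nearest odd integer), sigmoid gate.
4. **DSF-Block** — depthwise temporal convolution (kernel `K2`), pointwise
   1×1 fusion, average pooling (1, 8) and dropout.
5. **Classifier** — dense 240 → 32 → `n_classes`, raw logits into a stable
   softmax cross-entropy.

For the default four-class configuration (`C1=12`, `T1=500`) the stage
shapes are `(8, 12, 500) → (16, 1, 125) → (16, 1, 15) → 240 → 32 → 4`;
`amanet inspect` prints the chain.

The augmentation stage windows each trial (window 500, stride 125 → five
windows per 1000-sample trial), fits a CSP filter bank **on training
windows only** (binary: filter pairs from the generalized eigenproblem
`Σ₁w = λ(Σ₁+Σ₂)w`; multiclass: one-vs-rest, `C1/n_classes` filters per
class), projects both sides, and scales training windows by β ~ U[0.9, 1.1].

## CLI

```bash
amanet simulate --preset easy --channels 22 --seed 1 --out trials.npz
amanet cv      --data trials.npz --cfg run.yaml --out report.json
amanet train   --data trials.npz --cfg run.yaml --out result.json
amanet ablate  --data trials.npz --name AMNet --out ablation.json
amanet sweep   --data trials.npz --cfg sweep.yaml --out sweep.csv
amanet augment --in trials.npz --cfg run.yaml --out epochs.npz
amanet inspect --cfg run.yaml
```

Data containers are NPZ or HDF5 with arrays `X` (trials × channels ×
samples), `y` (trials) and scalar `sfreq`. Run configs are YAML
(see `amanet.io.RunConfig`); reports are JSON, sweep tables CSV.

Named ablation variants: `AMANet` (full), `AMNet` (no ECA), `CMNet`
(CSP, no augmentation), `WMANet` (ECA, no CSP), `WMNet` (neither), plus
independent block toggles `no_multiscale`, `no_attention`,
`no_augmentation`, `no_st_block`, `no_dsf_block`.

### Using BCI-competition-style data

GDF/EDF parsing is out of scope; convert with MNE in two lines and feed the
NPZ to the CLI:

```python
raw = mne.io.read_raw_gdf("A01T.gdf", preload=True)
# ... epoch as usual, then:
np.savez("trials.npz", X=epochs.get_data(), y=labels, sfreq=raw.info["sfreq"])
```

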