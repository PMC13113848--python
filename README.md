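# flexbeam

Flexible-transducer ultrasound beamforming: artificial-curvature simulation,
delay-and-sum reconstruction, and adversarial RF-to-delayed-RF prediction
(DNPAD), with a frequency-domain evaluation suite.

## The problem

Flexible ultrasound arrays conform to the body surface — attractive for
image-guided radiotherapy of moving targets (e.g. pancreatic tumours under
respiration) because they avoid the compression and operator dependence of
rigid probes. But a bent array invalidates every fixed-geometry delay:
delay-and-sum (DAS) beamforming needs the per-focal-point time of flight

    ToF(q; s, ch) = (|p_tx(s) − q| + |q − p_ch|) / c,

which depends on the unknown element positions. This package implements, end
to end and at workstation scale, a study of the alternative: train a network
to map raw (pre-delay) RF channel data directly to properly delayed RF, so
that plain channel summation yields the image with no shape estimate and no
explicit delay matrix.

Because curved acquisitions of a rigid phantom are physically impossible,
training pairs are manufactured by **artificial curvature**: from flat-array
RF, compute the flat ToF `T_f` and the curved ToF `T_c` for a chosen arc
radius, and time-warp each trace so that reading the warped trace at `T_c`
reproduces the ground truth `flat(T_f)`. Sweeping the radius 300–800 mm in
5 mm steps turns one acquisition into 101 paired samples.

**DNPAD** (deep-network-predicted after-delay) is a conditional adversarial
pair trained per scanline section: a 3-level U-Net generator
(1 → 64 → 128 → 256 channels, 512-channel bottleneck, 128 × 1024 → 16 × 128)
against a five-layer convolutional discriminator, with loss
`BCE(D(x, G(x)), 1) + 10 · |G(x) − y|₁`, Adam (β₁ = 0.5, β₂ = 0.999), cosine
annealing from 1e-4, batch size 4, and three input-noise variants (INO — no
injected noise; GN0.001 / GN0.01 — Gaussian noise of that std on the
normalized input). The neural-network layer stack, including
backpropagation and Adam, is implemented in-repo on numpy
(`flexbeam.nn`) and gradient-checked against finite differences.

Evaluation works in two domains: image MSE against the DAS reference, and
shifted 2-D spectra with `log(1 + |F₁ − F₂|)` difference maps — RF-level
variation from curvature or noise is often invisible in B-mode (envelope
detection and log compression suppress it) but clear in the spectrum.

## Worked example

A complete desk-scale study: simulate two voltage settings, expand each
acquisition over a 3-radius curvature sweep, split by held-out acquisitions,
train DNPAD, and score the reconstructions.

```python
import flexbeam as fb
from flexbeam.dataset import build_split
from flexbeam.dnpad import (DNPADModel, GeneratorConfig, DiscriminatorConfig,
                            TrainConfig, pair_reconstruction_mse)

spec = fb.desk_spec()                       # 16-element desk array
phantom = fb.cirs_like_phantom(max_depth=4.5, lateral_span=8.0)
grid = fb.default_focal_grid(spec, 128)

pairs = []
for exp, voltage in enumerate([30.0, 50.0], start=1):
    acq = fb.AcquisitionConfig(voltage_gain=voltage, noise_sigma=0.002, seed=exp)
    for a, rf in enumerate(fb.emulate_experiment_series(phantom, spec, 3, acq,
                                                        seed=exp), 1):
        pairs += fb.curvature_sweep(rf, 300, 800, 250, spec, grid,
                                    meta={"experiment_id": exp,
                                          "acquisition_id": a,
                                          "voltage": voltage})

split = build_split(pairs, n_experiments=2, seed=0)
print(f"pairs: {len(pairs)}  train/val/test: "
      f"{len(split.train)}/{len(split.val)}/{len(split.test)}")

model = DNPADModel(split, GeneratorConfig(base_channels=4),
                   DiscriminatorConfig(base_channels=4),
                   TrainConfig(epochs=10, seed=0))
res = model.fit()
print(res.summary())
mse = {p.meta["radius_mm"]: round(pair_reconstruction_mse(res.generator, p), 1)
       for p in split.test if p.meta["experiment_id"] == 1}
print("test reconstruction MSE by radius (dB^2):", mse)
```

Output:

```
pairs: 18  train/val/test: 6/6/6
DNPAD adversarial delay-prediction model
============================================
variant:            INO
epochs:             10
batch size:         4
lr (init, cosine):  0.0001
lambda_L1:          10
train scanlines:    96
final G loss:       1.6620
final L1 term:      0.0985
final D loss:       0.6956
final val MSE:      0.017702
test reconstruction MSE by radius (dB^2): {300.0: 171.9, 550.0: 144.2, 800.0: 134.3}
```

Each of the 18 pairs is one (curved pre-delay RF, ground-truth delayed RF)
tensor pair; the split holds one acquisition per experiment out for test and
one for validation. `final L1 term` is the mean absolute prediction error on
the normalized RF (here ~0.10 after 10 epochs, down from ~0.19 at epoch 1);
`val MSE` is the prediction error on held-out scanlines. The per-radius
image MSE compares the B-mode reconstructed from the predicted cube with the
DAS reference of the ground-truth cube, in dB² of the 60 dB display range —
a 10-epoch desk model is still far from the reference, and the spread across
radii is the curvature-robustness signal studied here.

The same study runs from the shell:

```
flexbeam run-study --seed 1 --out runs/demo            # full pipeline
flexbeam make-dataset --out data.h5                    # or stage by stage
flexbeam beamform --in data.h5 --shape convex:600 --out bmode.png
```

producing the HDF5 dataset, three trained variants (INO/GN0.001/GN0.01),
an MSE report CSV, spectral difference panels, and a manifest with every
derived seed and content hash.

## Layout

| Module | Contents |
| --- | --- |
| `flexbeam.geometry` | array parameters, flat/convex element positions |
| `flexbeam.phantom` | point-scatterer RF simulator, experiment series |
| `flexbeam.curvature` | ToF maps, delay maps, artificial-curvature warp, radius sweep |
| `flexbeam.beamform` | delay-and-sum, envelope detection, log compression |
| `flexbeam.dataset` | axial resize, [0, 1] normalization, noise variants, splits, HDF5 |
| `flexbeam.nn` | numpy conv-net framework (layers, U-Net, discriminator, Adam) |
| `flexbeam.dnpad` | DNPAD model/results, losses, training loop, reconstruction |
| `flexbeam.spectral` | shifted 2-D spectra, log-scale maps, difference panels, MSE |
| `flexbeam.pipeline`, `flexbeam.cli`, `flexbeam.config` | study orchestration and the `flexbeam` command |

See `docs/methods.md` for the model assumptions, numerical choices, and
known limitations.
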