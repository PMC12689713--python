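# synxqsl

Diffusion MRI quantifies tissue microstructure by fitting signal models
to diffusion-weighted images (DWI).  For diffusional kurtosis imaging
(DKI) the signal at diffusion weighting `b` is

    S(b) = S0 · exp(−b·D + b²·D²·K/6)

with baseline signal `S0`, diffusion coefficient `D` (reported in
×10⁻³ mm²/s) and kurtosis `K`.  Voxelwise least-squares fitting (LSF) of
this model is noisy — especially for `K` — at clinically realistic noise
levels.

`synxqsl` implements **synthetic X-Q space learning**: regressors for
`D` and `K` trained entirely on *synthetic* data.  A training sample is
a 3×3 patch of DKI parameters built from a random centre triple plus a
random combination of flat/linear/quadratic basis patterns, forward-
modelled at all b-values and corrupted with magnitude noise
(`S' = √(S² + g²)`, `g ~ N(0, σ)`, noise ratio `NR = σ / S̄0`).  The
regressor maps the 9N decay ratios `E_ij = S_ij/S_i0` of a voxel's 3×3
neighbourhood to the centre parameter, exploiting spatial smoothness as
an implicit regulariser.  The single-voxel variant (synQSL, N inputs)
and LSF are included as baselines, along with a region-wise digital
phantom and map-quality metrics (RMSE, SNR, CNR, SSIM) for benchmarking.

The package is aimed at quantitative-MRI researchers who want a
reproducible, fully synthetic pipeline for studying noise robustness of
learned dMRI parameter estimators — no scanner data is required
anywhere.

## Worked example

Train a kurtosis regressor on synthetic patches at noise ratio 0.1 and
apply it to a noisy uniform test volume:

```python
import numpy as np
from synxqsl import (DEFAULT_SCHEME, DKIVolumeModel, SynthesisConfig,
                     generate_dataset, train_mlp, dki_signal, make_rng,
                     predict_volume)
from synxqsl.regress import DESK_HYPERPARAMS, evaluate

train = generate_dataset(SynthesisConfig(n=20_000, mode=6, nr=0.1, seed=1))
test = generate_dataset(SynthesisConfig(n=2_000, mode=6, nr=0.1, seed=2))
model = train_mlp(train, DESK_HYPERPARAMS, target="K", window="synxqsl", seed=0)
print(f"test RMSE(K): {evaluate(model, test):.3f}")

# a noisy uniform volume with S0=320, D=1.0e-3 mm^2/s, K=0.75 (NR = 0.1)
sig = dki_signal(DEFAULT_SCHEME.b, S0=320.0, D=1.0e-3, K=0.75)
rng = make_rng(3)
vol = np.sqrt(sig**2 + rng.normal(0, 32.0, (24, 24, 4, 7)) ** 2)
res = DKIVolumeModel(vol, DEFAULT_SCHEME).fit()          # LSF baseline
print(f"LSF:     K mean {res.k.mean():.3f}, SD {res.k.std():.3f}")
kmap, _ = predict_volume(vol, DEFAULT_SCHEME, model)
print(f"synXQSL: K mean {kmap.mean():.3f}, SD {kmap.std():.3f}")
```

Output:

```
test RMSE(K): 0.272
LSF:     K mean 0.844, SD 0.132
synXQSL: K mean 0.742, SD 0.100
```

Read: on held-out synthetic patches the regressor estimates `K` to
about ±0.27 at this (heavy) noise level and modest training size.  On
the noisy uniform volume (true K = 0.75) least squares is biased upward
(+0.09 — it fits the noise-inflated signals at face value) with larger
voxel-to-voxel scatter, while the learned 3×3-window estimator, trained
on data carrying the same noise, is nearly unbiased with smaller
scatter — the noise-ratio matching the method is designed around.

## Command line

```sh
synxqsl synth --n 100000 --mode quadratic --nr 0.1 --seed 1 --out data/train
synxqsl train --data data/train --target K --window synxqsl --out models/k
synxqsl predict --dwi dwi.nii.gz --bvals dwi.bval --model models/k --out-prefix maps
synxqsl lsf --dwi dwi.nii.gz --bvals dwi.bval --out-prefix lsf
synxqsl phantom --shape 96 96 36 --sigma 32 --out-prefix phantom/ph
synxqsl cross-test --out-prefix results/xt      # train/test noise-ratio matrix
synxqsl phantom-bench --out-prefix results/pb   # LSF vs synQSL vs synXQSL
```

`--full-scale` on the experiment commands restores the full-scale
settings (10⁶ samples per split, the full 243-point hyperparameter
grid, 128³ phantom) at proportionate cost.

## Scientific notes

See `docs/methods.md` for the model and generator assumptions, the
noise-model's high-SNR behaviour, sampling near the `D·K < 3/b_max`
constraint boundary, hyperparameter handling, and known limitations.
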