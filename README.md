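# ivimfun

Functional perfusion imaging with **intravoxel incoherent motion (IVIM)
MRI**: a Python library for quantifying microvascular blood flow changes —
for example during visual stimulation — from multi-b-value diffusion-weighted
images, without any contrast agent and independently of blood oxygenation.

It is aimed at researchers analysing single-slice IVIM fMRI block-design
experiments and at methodologists studying the statistical behaviour of the
segmented IVIM fit.

## The model and the method

The diffusion-weighted signal of a voxel is modelled as two compartments:

```
S(b)/S0 = f · exp(−b·D*) + (1 − f) · exp(−b·D)
```

* `f` — perfusion fraction: the share of the MR signal from flowing blood;
* `D*` — pseudo-diffusion coefficient of blood traversing the quasi-random
  capillary network (mm²/s, typically an order of magnitude above `D`);
* `D` — thermal diffusion coefficient of tissue water (mm²/s);
* `f·D*` — the flow-related parameter, empirically the most precise of the
  three perfusion quantities.

Fitting is **segmented, in two steps**: (1) ordinary least squares on
`ln S(b)` for `b > 200 s/mm²`, where the vascular signal has decayed, gives
`D` and the tissue amplitude; (2) with `D` fixed, `f` and `D*` are fitted
over all b-values by bounded trust-region nonlinear least squares
(Levenberg–Marquardt class). Voxel-wise fits produce parameter maps; for
quantitative ROI statistics the signal is averaged over the ROI per b-value
*before* fitting, which avoids any ad-hoc rejection of misfitted voxels.

IVIM parameters convert to standard perfusion units through capillary
topology constants (MRI-visible water content λ = 0.78, total capillary
length L = 2 mm, mean segment length ⟨l⟩ = 0.108 mm):

```
CBV [ml/100ml]     = 0.78 · f[%]
CBF [ml/100ml/min] = 130 · fD*[10⁻³ mm²/s]     (factor derived, not hard-coded)
```

The package also contains Monte-Carlo fit-quality simulations (fit bias and
dispersion as a function of SNR, of true `f`, and of true `D*`), a
repeat-based SNR estimator, group statistics for block-design studies
(percent variation and one-tailed paired t-tests), and a fully synthetic
digital phantom that emulates the acquisition — 16 b-values from 0 to
900 s/mm², 3 orthogonal directions, alternating stimulation/baseline blocks
— so that every stage is testable end to end without any data download.

## Worked example

```python
import numpy as np
import ivimfun as iv

truth  = iv.IVIMParameters(f=0.04, D=0.7e-3, Dstar=17e-3)   # gray matter at rest
scheme = iv.AcquisitionScheme.default()                      # 16 b-values, 0–900
noise  = iv.NoiseModel.constant_snr(150, scheme)
curve  = iv.simulate_noisy_curve(truth, scheme, noise, np.random.default_rng(1))

fit = iv.fit_ivim(curve)
print(fit.params)
# IVIMParameters(f=0.0383..., D=0.000702..., Dstar=0.01721...)

print(iv.cbf_from_fDstar(fit.params.fDstar * 1e3))  # -> 85.7 ml/100ml/min
print(iv.cbv_from_f(fit.params.f * 100))            # -> 2.99 ml/100ml
```

The fitted perfusion fraction (3.8% vs the true 4%), pseudo-diffusion
(17.2 vs 17 ×10⁻³ mm²/s) and tissue diffusivity (0.702 vs 0.7) show the
typical single-curve accuracy at SNR 150; the converted values are the
voxel's cerebral blood flow and volume. The `examples/` directory walks
through each capability: the signal model (`01`), the segmented fit (`02`),
the SNR sweep (`03`), unit conversion (`04`), and a complete synthetic
group study with its statistics table (`05`).

A thin CLI mirrors the workflow for file-based use
(`ivimfun phantom | fit | sweep | analyze`, NIfTI in/out, YAML config).

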