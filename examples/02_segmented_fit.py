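"""Fit a noisy IVIM curve with the two-step segmented procedure.

Step 1 estimates the tissue diffusion coefficient D from the log-signal at
b > 200 s/mm2 (where the vascular signal has decayed); step 2 fixes D and
fits the perfusion fraction f and pseudo-diffusion D* over all b-values by
bounded Levenberg-Marquardt-class least squares.
"""

import numpy as np

import ivimfun as iv

truth = iv.IVIMParameters(f=0.04, D=0.7e-3, Dstar=17e-3)
scheme = iv.AcquisitionScheme.default()
noise = iv.NoiseModel.constant_snr(150, scheme)
rng = np.random.default_rng(1)

curve = iv.simulate_noisy_curve(truth, scheme, noise, rng)
result = iv.fit_ivim(curve)
p = result.params

print("            truth      fitted")
print(f"f    [%]    {truth.f*100:6.2f}    {p.f*100:6.2f}")
print(f"D*   [e-3]  {truth.Dstar*1e3:6.2f}    {p.Dstar*1e3:6.2f}")
print(f"D    [e-3]  {truth.D*1e3:6.3f}    {p.D*1e3:6.3f}")
print(f"fD*  [e-3]  {truth.fDstar*1e3:6.3f}    {p.fDstar*1e3:6.3f}")
print(f"\nconverged={result.converged}  valid={result.valid}  "
      f"weakly_identified={result.weakly_identified}  "
      f"residual_ss={result.residual_ss:.2e}")
# f and fD* are recovered well at this SNR; D* scatters more because it is
# constrained by only the few low-b points where the vascular signal lives.
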