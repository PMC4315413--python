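"""Monte-Carlo fit quality as a function of SNR (desk-scale replicate count).

Gaussian noise with standard deviation 1/SNR (in normalized signal units) is
added at every b-value to the gray-matter baseline curve; the segmented fit
runs on each replicate and the mean/SD of the fitted parameters is tabulated
per SNR.  Fits that hit a bound or fail to converge are excluded and counted.
"""

import ivimfun as iv

sweep = iv.run_snr_sweep(snr_values=[10, 50, 100, 200, 400],
                         n_replicates=300, seed=7)

truth = {"f": 0.04, "Dstar": 17e-3, "fDstar": 0.68e-3, "D": 0.7e-3}
print("SNR    param    mean(fit)   SD(fit)    truth     n_valid")
for _, row in sweep.table.iterrows():
    want = truth[row.parameter]
    print(f"{row.condition:5.0f}  {row.parameter:7s}  {row['mean']:.3e}  "
          f"{row.sd:.2e}  {want:.2e}  {row.n_valid:5d}")

# The perfusion parameters (f, D*, fD*) are strongly biased and dispersed at
# SNR 10 and tighten as SNR grows; the tissue D is accurate at every SNR
# because it comes from the high-b log-linear stage.  Note that the *mean*
# fitted D* converges slowly: its sampling distribution is right-skewed, so
# the mean sits above the (unbiased) median at moderate SNR.
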