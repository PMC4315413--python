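"""Generate a synthetic block-design study and run the full group analysis.

A digital phantom (four tissue regions in a circular head) is imaged across
alternating stimulation/baseline blocks for several subjects with realistic
b-dependent noise; the pipeline rebuilds the ROIs from the activation t-map,
fits every ROI-averaged block curve, and reports the group table with
percent variations and one-tailed paired t-tests.
"""

import ivimfun as iv

spec = iv.PhantomSpec(
    shape=(48, 48), brain_radius=20, gm_ribbon_width=5, visual_extent=9,
    n_subjects=6, blocks_per_condition=3, seed=42,
)
study = iv.simulate_study(spec)
result = iv.analyze_study(study, direction="increase")

cols = ["roi", "parameter", "baseline_mean", "stimulation_mean",
        "variation_pct", "p_value"]
print(result.summary[cols].round(3).to_string(index=False))

gm = result.summary[(result.summary.roi == "visual_gm")
                    & (result.summary.parameter == "fDstar")].iloc[0]
print(f"\nactivated gray matter flow parameter fD*: "
      f"{gm.baseline_mean:.2f} -> {gm.stimulation_mean:.2f} (1e-3 mm2/s), "
      f"+{gm.variation_pct:.0f}% (one-tailed paired p = {gm.p_value:.3f})")
print("The visual ROIs show a perfusion increase under stimulation; the")
print("non-visual ROIs, generated with their own condition truths, do not")
print("show a comparable activated-flow effect. Units: f in %, D/D*/fD* in")
print("1e-3 mm2/s. The perfusion-unit twin is in result.perfusion_summary.")
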