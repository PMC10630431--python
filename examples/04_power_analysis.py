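"""How rare can a niche be and still be found?  (reduced-size power scan)

Simulates tissues in which one niche's prevalence is dialled down,
samples sites worth one or six images of tissue, refits niches, and
calls the rare niche "captured" when its composition is recovered with
RMSE below the threshold.  Full-size scans use 25+ replicates per
prevalence; this demo runs 4 to stay fast.
"""

from nichescape import capture_threshold, power_curve

curve = power_curve(
    f_values=[0.06, 0.10, 0.16, 0.25],
    n_images_values=(1, 6),
    reps=4,
    seed=0,
)
print(curve[["f", "n_images", "prevalence", "capture_prob"]].to_string(index=False))

thr = capture_threshold(curve, min_prob=0.5)
for ni, v in thr.items():
    print(f"{ni} image(s): smallest reliably captured prevalence ~ {100 * v:.1f}% of tissue area")
# capture scales with prevalence x data size: six images push the
# detectable prevalence several-fold lower than one image
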