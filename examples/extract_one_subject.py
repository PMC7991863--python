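"""Generate one synthetic subject and extract its feature panel.

The phantom ROI pixels are drawn from a two-component Gaussian mixture
matched to four target moments (mean 336.56, SD 31.26, skewness -2.50,
Pearson kurtosis 13.80 — a strongly left-skewed, heavy-tailed gray-level
distribution typical of a T1 corpus-callosum ROI). The printed panel
shows how closely a single ~640-pixel ROI recovers those targets.
"""

from histofeat import (
    DistributionSpec,
    SubjectSpec,
    extract_features,
    generate_subject,
)

spec = SubjectSpec(
    subject_id="demo001",
    group_label="control",
    distribution=DistributionSpec(
        family="two_component_mixture",
        target_mean=336.56,
        target_sd=31.26,
        target_skewness=-2.50,
        target_kurtosis=13.80,
    ),
    roi_area_cm2=5.64,          # target physical ROI area
    grid_size=(256, 256),       # 240 mm field of view at 256 x 256
    pixel_spacing_mm=(0.9375, 0.9375),
)

image, mask = generate_subject(spec, seed=1)
features = extract_features(image, mask)

print(f"ROI pixels: {mask.pixel_count}")
for name, value in features.as_dict().items():
    print(f"{name:>16s}: {value:10.4f}")
print(
    "\nmean/sd/skewness/kurtosis should sit near the targets "
    "(336.56 / 31.26 / -2.50 / 13.80) up to sampling noise at ~640 pixels; "
    "area_cm2 is within one pixel of 5.64."
)
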