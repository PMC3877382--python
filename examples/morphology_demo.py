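"""Mitochondrial morphometry: segment a synthetic field, measure shapes.

Renders ellipse-like mitochondria with known sizes, segments them by Otsu
threshold + connected components, excludes touching/border objects, and
prints the five shape metrics (length, width, circularity, aspect ratio,
roundness) as cohort mean ± SEM.
"""

import mitodyn as md
from mitodyn import morphology

for name, printed in (("wt_len", 1.96), ("a53t_len", 1.32)):
    preset = md.morphology_preset(name, seed=1)
    image, truth = md.simulate_morphology_image(preset)
    labels = morphology.segment_mitochondria(image, preset.pixel_size)
    records = morphology.filter_isolated(
        morphology.shape_descriptors(labels, preset.pixel_size, truth))
    summary = morphology.summarize_morphology(records)
    print(f"\n{name} ({len(records)} isolated objects; condition mean "
          f"length {printed} μm):")
    print(summary.to_string(index=False,
                            formatters={"mean": "{:.3f}".format,
                                        "sem": "{:.3f}".format}))

print("\nLength (major axis) separates the conditions; circularity, roundness")
print("and aspect ratio do not — mitochondria shorten without changing shape.")
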