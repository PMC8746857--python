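"""Simulate one olive-oil proton spectrum and walk the processing chain.

Builds the canonical olive triglyceride composition, renders its FID on
the emulated 400 MHz instrument, runs apodization -> FT -> automatic
phasing -> TMS referencing -> baseline correction -> omega-3
normalisation, and prints the landmark peak heights.
"""

import numpy as np

import oilscreen as osn

olive = osn.make_oil("olive")
print("olive composition (molar chain fractions):")
for acid, f in sorted(olive.fractions.items(), key=lambda kv: -kv[1]):
    print(f"  {acid:10s} {f:.3f}")

spec = osn.render_spectrum(olive, rng=np.random.default_rng(0))

print("\nprocessing history:")
for line in spec.meta["history"]:
    print(" ", line)

print("\nlandmark intensities (normalised to the omega-3 methyl peak):")
for label, lo, hi in [("omega-3 methyl (0.977 ppm)", 0.95, 1.00),
                      ("other methyls (0.881 ppm)", 0.85, 0.92),
                      ("bis-allylic CH2 (2.78 ppm)", 2.70, 2.86),
                      ("olefinic CH (5.35 ppm)", 5.25, 5.45)]:
    h = spec.window(lo, hi).intensity.max()
    print(f"  {label:28s} height {h:9.2f}")

print("""
The omega-3 methyl reference is defined as height 1; olive oil's low
alpha-linolenic content makes every other signal appear large on this
scale.  A seed oil richer in omega-3 (e.g. hempseed) would show far
smaller relative heights - the contrast the authenticity screen uses.""")
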