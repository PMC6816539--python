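"""Sample random conductivity phantoms from both families and rasterize one.

The thoracic family includes organs with fixed probabilities and jittered
boundaries; the generic family draws 1-3 random non-overlapping ellipses.
"""
import numpy as np

from dbarnet import (ACT4Rules, KIT4Rules, ImageGrid, rasterize,
                     sample_act4_phantom, sample_kit4_phantom)

rng = np.random.default_rng(42)

thorax = sample_act4_phantom(ACT4Rules(), rng)
print(f"thoracic phantom: {len(thorax.inclusions)} organs, "
      f"background {thorax.background_sigma:.3f} S/m")
for inc in thorax.inclusions:
    tag = " (injured)" if inc.split else ""
    print(f"  {inc.label:10s} sigma={inc.sigma:.3f} S/m{tag}")

generic = sample_kit4_phantom(KIT4Rules(), rng)
print(f"\ngeneric phantom: {len(generic.inclusions)} ellipses, "
      f"background {generic.background_sigma:.3f} S/m")

img = rasterize(generic, ImageGrid(64))
print(f"rasterized 64x64 image: values in [{img.values.min():.3f}, "
      f"{img.values.max():.3f}] S/m")
# The image is piecewise constant: background everywhere outside the
# ellipses, each inclusion's conductivity inside (split regions respected).
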