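"""Render a super-resolution image and measure a structure width.

Builds a synthetic 100 nm-wide line of localizations (a stand-in for a
finger-like mitochondrial structure), renders it at 10 nm bins, and measures
its apparent width from a perpendicular line profile — the analysis used to
demonstrate resolution below the ~250 nm diffraction limit.
"""

import numpy as np
import pandas as pd

from snsmil import RenderSpec, line_profile, render

rng = np.random.default_rng(3)
n = 5000
locs = pd.DataFrame({
    "frame": 0,
    "x_nm": rng.normal(1000.0, 100.0 / 2.355, n),  # 100 nm FWHM line
    "y_nm": rng.uniform(200.0, 1800.0, n),
})

spec = RenderSpec(bin_size_nm=10.0, mode="histogram")
img = render(locs, spec, fov_nm=(2000.0, 2000.0))
print(f"rendered {img.shape[1]}x{img.shape[0]} px image "
      f"({spec.bin_size_nm:g} nm bins), total mass {img.sum():.0f}")

centers, prof = line_profile(img, ((1000, 200), (1000, 1800)),
                             width_nm=600.0, bin_size_nm=10.0)
above = centers[prof >= 0.5]
print(f"profile FWHM: {above.max() - above.min():.0f} nm (simulated width 100 nm)")
print("\nThe localization-based image resolves a structure far below the")
print("diffraction limit; the profile is normalized to its maximum.")
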