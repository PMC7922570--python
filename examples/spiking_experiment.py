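"""Emulate the spiking experiment that anchors the band library.

Milk is spiked with increasing amounts of one minor component; band
centers are the second-derivative minima whose absorbance grows
monotonically with the added concentration, and the variance spectrum
highlights the most concentration-responsive wavenumbers.
"""

import numpy as np

from milkmir import second_derivative_band_centers, variance_spectrum
from milkmir.bands import load_band_library
from milkmir.synthetic import simulate_spiking_series

library = load_band_library()

for molecule in ("bhb", "acetone"):
    spectra, meta = simulate_spiking_series(molecule, [0.0, 0.1, 0.2, 0.4], seed=3)
    centers = [c for c, _ in second_derivative_band_centers(
        spectra, meta["concentration"])]
    vs = variance_spectrum(spectra)
    vmax = vs.grid.points[np.argmax(vs.values)]
    reference = library.centers(molecule, "milk")
    print(f"{molecule}: reference milk bands {reference}")
    print(f"  increasing band centers found: {[round(c, 1) for c in centers]}")
    matched = [ref for ref in reference
               if any(abs(c - ref) <= spectra.grid.spacing for c in centers)]
    print(f"  matched within one grid spacing: {matched}")
    print(f"  variance spectrum maximal at {vmax:.1f} cm^-1\n")

print("Each molecule's strongest reference bands reappear as growing "
      "second-derivative minima; side lobes of strong bands may add extra "
      "centers, which is why assignment uses a ±5 cm^-1 tolerance.")
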