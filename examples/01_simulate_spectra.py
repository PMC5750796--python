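"""Generate synthetic two-class FTIR tissue spectra and inspect a band contrast.

Builds a balanced cancer/colitis dataset on a 1000-4000 cm^-1 axis and
prints the class-mean absorbance at the 1743 cm^-1 lipid C=O band, which
is strongly reduced in the cancer class.
"""

import numpy as np

from ewhk import GeneratorConfig, generate

cfg = GeneratorConfig(seed=1, n_per_class=50)
ds = generate(cfg)
print(f"dataset: {ds.n_samples} spectra x {ds.n_features} wavenumbers, "
      f"classes {ds.classes}")

col = np.argmin(np.abs(ds.wavenumbers - 1743))
for label in ds.classes:
    mean = ds.absorbance[ds.labels == label, col].mean()
    print(f"mean absorbance at 1743 cm^-1, {label:8s}: {mean:.3f}")
# The colitis mean is clearly higher: the generator encodes the loss of
# lipid bands in malignant tissue.
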