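"""Bi-modal evolved spectra versus the uni-modal random-matrix null.

Evolves an omnivorous web, pools the community-matrix eigenvalues of
recorded webs at one species richness, and contrasts the real-part
distribution (scaled to start at -1) with a connectivity-matched random
ensemble of the same size.
"""

import numpy as np

from evospectra import (
    AssemblyConfig,
    RandomEnsembleSpec,
    connectivity,
    ensemble_spectrum,
    evolve,
    purely_real_fraction,
    real_part_distribution,
)
from evospectra.spectra import spectrum_set_from_history

RICHNESS = 5

history = evolve(AssemblyConfig(mode="omnivorous", beta=0.75, attempts=4000, seed=3))
evolved = spectrum_set_from_history(history).eigenvalues_by_richness[RICHNESS]

spec = RandomEnsembleSpec(size=RICHNESS, samples=2000, seed=3)
random_eigs = ensemble_spectrum(spec).eigenvalues_by_richness[RICHNESS]

print(f"richness {RICHNESS}: {evolved.size} evolved eigenvalues, "
      f"p(N) = {connectivity(RICHNESS):.3f}")
print(f"purely real fraction, evolved: {purely_real_fraction(evolved):.3f}")
print(f"purely real fraction, random : {purely_real_fraction(random_eigs):.3f}")

for label, eigs in (("evolved", evolved), ("random", random_eigs)):
    edges, mass = real_part_distribution(eigs, bins=10)
    peak = int(np.argmax(mass))
    print(f"{label}: real-part histogram peak in bin {peak} "
          f"[{edges[peak]:.2f}, {edges[peak + 1]:.2f}] of {mass.size}")

# The evolved distribution piles up just below zero with a secondary
# shoulder near -1 (bi-modal); the random ensemble, centred on its
# diagonal -1, peaks in the interior of its support (uni-modal).
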