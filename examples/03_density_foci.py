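"""Peritumoral density maps and L-TAM foci on clustered vs dispersed slides.

Builds a 500-um peritumoral band around a circular tumor contour, drops
Thomas-clustered L-TAM centroids on one slide and a matched homogeneous
Poisson pattern on another, and compares the total area of high-density foci
(>= 100 cells within 200 um).
"""

import numpy as np

from tammorph import GeneratorConfig, compare_foci, density_map, detect_foci
from tammorph.simulate import generate_spatial_patterns

cfg = GeneratorConfig()
early, favorable = [], []
for seed in range(6):
    rng = np.random.default_rng(seed)
    geom, ltam, _ = generate_spatial_patterns(cfg, "early", rng)
    foci = detect_foci(ltam, geom)  # 200-um radius, threshold 100, 20-um pixels
    early.append(foci.total_foci_area)
    dmap = density_map(ltam, geom)  # display map: counts within 500 um
    print(f"clustered slide {seed}: {len(ltam)} L-TAMs, peak density "
          f"{dmap.counts.max()} cells/500um, {foci.n_foci} foci, "
          f"total {foci.total_foci_area / 1e3:.0f} x10^3 um^2")
    geom, ltam, _ = generate_spatial_patterns(cfg, "favorable", rng)
    favorable.append(detect_foci(ltam, geom).total_foci_area)

u, p = compare_foci(early, favorable)
print(f"\nclustered vs dispersed total foci area: U={u:.0f}, exact p={p:.4f}")
# Clustered (early-recurrence-like) slides form large supra-threshold foci;
# dispersed slides at the same overall density form none, so the exact 6-vs-6
# Mann-Whitney comparison is decisive.
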