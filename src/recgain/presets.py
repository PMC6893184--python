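"""Published per-chromosome genetic lengths and interference parameters.

Genetic lengths (cM) of the two study species under normal recombination and
under the two engineered increases.  The two ways of increasing recombination
(global multiplicative "HyperRec" scaling and additive pericentromere-warming
"boosted" recombination) are calibrated to the same per-chromosome target
length, so a single "increased" column serves both.  The gamma-model
interference shapes (nu) are available for the B. rapa diploid (normal
recombination) and allotriploid (boosted recombination) karyotypes only.
"""

from __future__ import annotations

# O. sativa: 12 chromosomes, wild type vs increased recombination.
OSATIVA_CHROMS = tuple(f"chr{i:02d}" for i in range(1, 13))
OSATIVA_GL_NORMAL = (
    210.27, 174.83, 156.30, 132.72, 143.97, 172.68,
    144.15, 128.42, 120.45, 100.87, 137.74, 136.14,
)
OSATIVA_GL_INCREASED = (
    650.68, 504.69, 482.42, 468.98, 435.66, 479.01,
    429.28, 424.03, 496.54, 372.00, 472.26, 484.32,
)

# B. rapa: 10 chromosomes, diploid vs increased recombination.
BRAPA_CHROMS = tuple(f"A{i:02d}" for i in range(1, 11))
BRAPA_GL_NORMAL = (92.9, 78.0, 102.9, 56.2, 95.4, 105.7, 74.1, 56.8, 103.9, 55.8)
BRAPA_GL_INCREASED = (265.2, 260.7, 396.3, 206.5, 263.3, 300.9, 318.3, 225.8, 394.7, 143.1)

# Gamma-model interference shape nu per B. rapa chromosome.
BRAPA_NU_DIPLOID = (6.97, 6.139, 7.207, 18.576, 12.934, 8.814, 13.001, 12.185, 4.895, 63.778)
BRAPA_NU_ALLOTRIPLOID = (1.887, 1.479, 2.392, 1.946, 2.263, 3.084, 1.64, 2.036, 2.418, 2.362)
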