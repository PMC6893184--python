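# recgain

Forward-in-time simulation of recurrent selection in biparental plant
populations under engineered meiotic recombination landscapes.

Crossovers are rare and unevenly placed: in most crops the pericentromeric
half of a chromosome is almost devoid of them, which traps allelic variation
in large linkage blocks (the Hill–Robertson effect) and limits long-term
response to selection.  Two experimental routes can raise recombination:
knocking out anti-crossover genes (**HyperRec**) multiplies the whole
landscape by a constant, preserving its shape; crossing to change ploidy
(allotriploid hybrids, **boosted** recombination) adds a constant rate
everywhere, which disproportionately warms the cold pericentromeres.
`recgain` quantifies what either intervention is worth to a breeder: it
simulates 20 generations of phenotypic or RR-BLUP genomic selection on a
biparental cross and reports the *efficiency* of modified recombination —
the ratio of cumulative genetic gains, gain(modified)/gain(normal), over
paired stochastic replicates.

The package is aimed at quantitative geneticists and breeding-program
modelers.  It ships presets for a *Brassica rapa*-like genome
(10 chromosomes, 821.7 → 2774.8 cM) and an *Oryza sativa*-like genome
(12 chromosomes, 1758.54 → 5699.87 cM), a synthetic-genome generator with
cold pericentromeres and realistic gene-density profiles, and readers for
user-supplied marker tables (TSV Marey maps) and gene annotations (GFF3).

## Model in brief

* **Genome** — per-chromosome monotone Marey maps (physical Mb → genetic
  cM).  HyperRec: genetic positions scaled by `GL_target/GL`.  Boosted:
  local rate + `(GL_target − GL)/PL` cM/Mb everywhere.  Both hit the same
  per-chromosome target length.
* **Meiosis** — crossovers in genetic space, 1 expected per 100 cM:
  Poisson/uniform (Haldane) or a stationary gamma-renewal process with
  interference shape ν ≥ 1.
* **Trait** — purely additive; QTL sampled from gene positions, amplitudes
  a ~ Gamma(k = 0.4, θ = 1.58), allelic effects ±a/2, optional
  coupling/repulsion of founder linkage phase with
  P = ½(1 − e^(−Δx/L)), L = 5 cM.
* **Selection** — 250 individuals, best 5 kept (2%), random mating (Fn
  scheme) or alternating doubled-haploid panels (DH scheme); criterion is
  the phenotype (h² calibrated on the F2) or GEBV = β + Z·u from RR-BLUP
  (`Y = Xβ + Zu + e`, REML via spectral decomposition), recalibrated every
  fourth generation by default.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Run five paired replicates of the default B. rapa design (Fn scheme, genomic
selection, 200 QTL/chromosome, h² = 0.5) under the normal and boosted
landscapes:

```python
import numpy as np
from recgain import ExperimentConfig, run_replicates, summarize_pairs

cfg = ExperimentConfig(
    species="brapa",
    scenarios=("normal", "boosted"),
    n_replicates=5,
    base_seed=42,
    markers_per_chrom=200,
)
df = run_replicates(cfg)
print(
    summarize_pairs(df)
    .query("generation in (10, 20)")
    .round(2)
    .to_string(index=False)
)
```

```
 scenario_pair  generation  mean_gain_normal  mean_gain_modified  gain_ratio  ci_normal  ci_modified  n_replicates
boosted/normal          10            201.00              255.81        1.27      35.45        20.56             5
boosted/normal          20            215.31              326.28        1.52      36.57        22.48             5
```

Reading: by generation 20 the normal landscape has gained ~215 trait units
(sums of QTL effects) over the F2 mean, the boosted landscape ~326 from the
same founders and trait architectures, and the advantage widens between
g = 10 and g = 20 as the normal landscape exhausts its variance first.  At
five replicates the 95% confidence half-widths (`ci_*`) are wide and the
ratio is noisy — the bundled experiments use 100–1000 replicates, where the
same design averages close to a ratio of 1.3.

The same experiment from the shell:

```bash
recgain simulate --config config.yaml --replicates 5 --seed 42 --out out/
recgain landscape --preset brapa --out landscapes/   # inspect the three maps
recgain summarize --in out/ --out summary.csv
```

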