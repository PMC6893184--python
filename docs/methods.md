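# Methods

## Problem and model

`recgain` asks a quantitative-genetics question: if a breeder could engineer
more meiotic crossovers, how much extra genetic gain would a recurrent
selection program harvest, and does it matter *where* on the chromosomes the
extra recombination lands?  Two experimentally motivated interventions are
contrasted against a species' normal recombination landscape:

* **HyperRec** (anti-crossover-gene knockouts): the local recombination rate
  is multiplied everywhere by a constant `GL_target / GL_normal`, so the
  Marey-map shape is preserved — pericentromeric cold regions stay cold.
* **Boosted** recombination (allotriploid hybrids): a spatially constant
  rate `(GL_target − GL_normal) / PL` (cM/Mb) is added everywhere, which
  proportionally warms the cold regions most.

Both transforms are calibrated per chromosome to the same target genetic
length, so a paired comparison isolates the spatial redistribution of
crossovers from the total increase.

The simulated program is a biparental cross: two fully homozygous founders
(g = 0), their F1 (g = 1), and from g = 2 a population of 250 under
truncation selection.  Two schemes are implemented: the **Fn scheme**
(selfed F2, then each generation the best 5 of 250 are selected and randomly
mated) and the **DH scheme** (alternating doubled-haploid panels, where
selection happens, and heterozygous crossing generations; 20 generations =
10 cycles).  Selection acts on the phenotype or, for genomic selection, on
GEBV = β + Z·u from an RR-BLUP model recalibrated on a configurable
schedule ({2}, {2,6,10,14,18} or {2,4,…,20}).

The trait is purely additive: G sums the two allelic effects (±a/2) over
all QTL.  Amplitudes are Gamma(k = 0.4, θ = 1.58) — an L-shaped
distribution with unit variance of the amplitude — and founder P1 carries a
random sign per QTL, P2 the opposite allele.  Environmental noise is
N(0, V_E) with V_E set once from the g = 2 genetic variance to reach the
configured heritability (default h² = 0.5) and then held fixed.

## Meiosis

Crossovers are generated directly in genetic space at the gamete scale: one
expected crossover per 100 cM.  Without interference the count is
Poisson(GL/100) with uniform positions (Haldane).  With interference a
stationary gamma-renewal process is used: inter-crossover distances are
Gamma(shape ν ≥ 1, mean 100 cM), with the first event drawn from the
equilibrium residual distribution (`U · Gamma(ν + 1)`, the
inspection-paradox construction).  Stationarity matters: it keeps crossover
density uniform in cM and the expected count at GL/100 for every ν, so the
genetic-length contract of the landscape tables is honored.  ν = 1 reduces
exactly to Haldane.  No obligate crossover, no four-strand bookkeeping and
no chromatid interference are modeled; ν is an effective gamete-scale
interference parameter.

The selection engine does not materialize segment mosaics.  Populations are
arrays of founder origins at a fixed set of loci (the union of QTL and
neutral-marker genetic positions); the origin of a locus in a gamete depends
only on the parity of the crossover count below it, which is exact for any
crossover process and fully vectorizable across a population.  The
segment-based `Gamete`/`Individual` API is retained for inspection and is
cross-checked against the parity engine in the test suite.

## Synthetic genomes

The real landscapes and gene annotations behind the published tables are
third-party supplements; the package regenerates inputs with the same
summary structure so every experiment is self-contained:

* per-chromosome normal Marey maps with the published total genetic lengths
  (10 B. rapa-like chromosomes totalling 821.7 cM, 12 O. sativa-like
  chromosomes totalling 1758.54 cM) and a pericentromeric block covering
  40% of the physical span recombining at 2% of the chromosome-average
  rate.  Physical span defaults to 40 Mb/chromosome; only rate *ratios*
  matter downstream because simulation operates in genetic coordinates;
* engineered landscapes derived with the two transforms above, hitting the
  published per-chromosome increased lengths (2774.8 cM total for
  B. rapa; 5699.87 cM for O. sativa — the sum of the published
  per-chromosome entries, which the published total line misprints);
* gene positions drawn from a two-level density, reduced to 30% inside the
  pericentromere (3000 genes/chromosome by default);
* per-replicate QTL sampled uniformly among genes without replacement (two
  QTL at one gene would be a single locus), with genetic positions obtained
  per scenario through each landscape's map.

What the generator does **not** emulate: fine-scale rate heterogeneity
(hotspots), chromosome-specific pericentromere geometry, telomeric rate
gradients, or transposable elements.  Passing tests therefore demonstrate
the behavior of the selection machinery on landscapes with the published
coarse structure, not on any particular measured map; users with real
marker tables can load them through the TSV reader (`read_marey_tsv`) and
GFF3 gene reader instead.

## Founder linkage phase (coupling / repulsion)

Walking along a chromosome, the probability attached to each adjacent QTL
pair is P = ½(1 − e^(−Δx/L)) with L = 5 cM.  Under coupling P is the
probability the founder sign *changes*; under repulsion that it *stays*.
Δx is each scenario's own genetic distance: linkage phase interacts with the
landscape, so the same physical architecture is more weakly coupled under an
engineered landscape that spreads the QTL apart.  The per-pair uniform draws
and per-chromosome initial signs are shared across scenarios, keeping the
paired-replicate coupling between scenarios maximal; under the default
random phase the sign vectors are bit-identical across scenarios.  This
per-scenario phase assignment is what reproduces the published coupling
(≈0.8) and repulsion (≈1.38) efficiency ratios; assigning signs once from
normal-map distances and reusing them yields qualitatively different values
(≈1.0 and ≈1.2 at g = 20).

## RR-BLUP

`Y = Xβ + Zu + e` with X a column of ones and Z the N×M marker matrix coded
−1/0/+1 (homozygous P1 / heterozygous / homozygous P2) on 1000 equally
spaced neutral markers per chromosome (spacing GL/999 in each scenario's
genetic length).  δ = Ve/Vu is estimated by REML through the spectral
decomposition of the projected kernel T′ZZ′T (T an orthonormal basis of the
intercept's complement), a bounded 1-D optimization over log δ (tolerance
1e−8); β and u then solve the mixed-model equations at the REML ratio.
Monomorphic marker columns are permitted and shrink to zero.  After
fixation with h² = 1 the phenotype is constant and unfittable; the engine
keeps the previous model (selection is pure drift from then on).

## Numerical and design choices

* Maps are monotone by construction: marker genetic positions are
  isotonically projected, then interpolated with a monotone (PCHIP) cubic;
  local rates are finite differences on a 0.1 Mb grid, which makes the
  additive transform exact and auditable.  Genetic positions are anchored
  at 0 cM on the first mapped marker; queries outside the mapped physical
  range are rejected.
* Intervals are half-open [start, end); a locus at a crossover position
  belongs to the segment that starts there.  Crossover positions are
  continuous, so ties have measure zero.
* Truncation-selection ties are broken uniformly at random.
* Random mating draws an ordered pair of *distinct* parents per offspring
  (no selfing among the selected; a documented switch re-enables it).
* Per-replicate and per-scenario RNG streams are spawned from the base seed
  (`SeedSequence([seed, replicate, stream])`), so runs are bit-reproducible
  and trait architectures are shared across the scenarios of a replicate.
* Reduced problem sizes: the bundled acceptance script and heavy tests
  use 100 paired replicates (the reference design used 1000) and thin the
  neutral markers to 200/chromosome for GEBV computation; both choices
  leave the mean gain ratios essentially unchanged while keeping a full
  battery of experiments inside a coffee break.

## Known limitations

* Single trait, pure additivity: no dominance, epistasis,
  genotype–environment interaction or multi-trait economic weighting.
* Interference uses published two-pathway ν estimates inside a
  single-pathway model, which overstates interference strength; the
  interference experiment should be read as a bound.
* The B. rapa interference parameters exist only for the diploid (normal)
  and allotriploid (boosted) karyotypes, so interference runs are
  restricted to that pair.
* Gain ratios at 100 replicates carry Monte-Carlo error of roughly ±0.02–0.04
  (95% CI at 100 replicates); single replicates are far noisier.
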