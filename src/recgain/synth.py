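"""Synthetic genomes, gene positions and quantitative-trait architectures.

The real study read its recombination landscapes and gene annotations from
external supplements that are not redistributable.  This module generates
stand-ins with the same published summary structure: per-chromosome normal
Marey maps whose total genetic lengths match the published tables, a cold
pericentromeric block with strongly reduced crossover rate, and gene physical
positions whose density drops inside the pericentromere.  The engineered
landscapes are then derived with the same two transforms used downstream
(:func:`recgain.genome.make_hyperrec`, :func:`recgain.genome.make_boosted`).

A :class:`TraitModel` holds the QTL architecture of one replicate: physical
positions sampled among genes, gamma-distributed amplitudes, and founder
allele signs (optionally in coupling or repulsion along each chromosome).
The same physical positions, amplitudes and signs are shared by all three
landscape scenarios of a replicate; only the genetic positions differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import presets
from .errors import (
    InsufficientGenesError,
    InvalidCountError,
    UnsortedInputError,
)
from .genome import (
    ChromosomeMap,
    GenomeSpec,
    RecombinationLandscape,
    fit_map,
    make_boosted,
    make_hyperrec,
    physical_to_genetic,
)

__all__ = [
    "SyntheticGenomeConfig",
    "SyntheticGenome",
    "TraitModel",
    "gen_landscape",
    "gen_genome",
    "gen_gene_positions",
    "sample_qtl",
    "draw_amplitudes",
    "assign_phase",
    "build_trait",
    "read_gff_genes",
]

SCENARIOS = ("normal", "hyperrec", "boosted")


@dataclass(frozen=True)
class SyntheticGenomeConfig:
    """Recipe for a synthetic species genome.

    ``GL_normal``/``GL_increased`` are per-chromosome genetic lengths (cM);
    defaults come from the published per-species tables.  The pericentromere
    occupies ``peri_width`` of the physical span around ``peri_center`` and
    recombines at ``cold_rate_frac`` of the chromosome-average rate; gene
    density inside it is ``gene_density_cold_frac`` of the outside density.
    """

    chrom_ids: tuple[str, ...]
    GL_normal: tuple[float, ...]
    GL_increased: tuple[float, ...]
    PL: tuple[float, ...] = ()  # Mb; default 40 per chromosome
    peri_center: float = 0.5  # fraction of physical span
    peri_width: float = 0.4
    cold_rate_frac: float = 0.02
    gene_density_cold_frac: float = 0.3
    genes_per_chrom: int = 3000
    nu_normal: tuple[float, ...] | None = None
    nu_boosted: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        n = len(self.chrom_ids)
        if len(self.GL_normal) != n or len(self.GL_increased) != n:
            raise InvalidCountError("GL arrays must match the number of chromosomes")
        if not self.PL:
            object.__setattr__(self, "PL", tuple(40.0 for _ in range(n)))
        if not 0 < self.peri_width < 1:
            raise InvalidCountError("peri_width must be in (0, 1)")
        if not 0 <= self.cold_rate_frac <= 1:
            raise InvalidCountError("cold_rate_frac must be in [0, 1]")
        for gn, gi in zip(self.GL_normal, self.GL_increased):
            if gi <= gn:
                raise InvalidCountError("GL_increased must exceed GL_normal everywhere")

    @classmethod
    def brapa(cls, **over) -> "SyntheticGenomeConfig":
        """B. rapa-like genome: 10 chromosomes, published lengths and nu values."""
        kw = dict(
            chrom_ids=presets.BRAPA_CHROMS,
            GL_normal=presets.BRAPA_GL_NORMAL,
            GL_increased=presets.BRAPA_GL_INCREASED,
            nu_normal=presets.BRAPA_NU_DIPLOID,
            nu_boosted=presets.BRAPA_NU_ALLOTRIPLOID,
        )
        kw.update(over)
        return cls(**kw)

    @classmethod
    def osativa(cls, **over) -> "SyntheticGenomeConfig":
        """O. sativa-like genome: 12 chromosomes, published lengths."""
        kw = dict(
            chrom_ids=presets.OSATIVA_CHROMS,
            GL_normal=presets.OSATIVA_GL_NORMAL,
            GL_increased=presets.OSATIVA_GL_INCREASED,
        )
        kw.update(over)
        return cls(**kw)


def _peri_bounds(config: SyntheticGenomeConfig, c: int) -> tuple[float, float]:
    pl = config.PL[c]
    half = 0.5 * config.peri_width * pl
    center = config.peri_center * pl
    return max(0.0, center - half), min(pl, center + half)


def _normal_map(config: SyntheticGenomeConfig, c: int, n_pts: int = 25) -> ChromosomeMap:
    """Piecewise cold/warm Marey map with exact total genetic length."""
    gl, pl = config.GL_normal[c], config.PL[c]
    lo, hi = _peri_bounds(config, c)
    w_cold = hi - lo
    rate_cold = config.cold_rate_frac * gl / pl
    rate_warm = (gl - rate_cold * w_cold) / (pl - w_cold)
    xs, gs = [], []
    pos = 0.0
    gpos = 0.0
    for a, b, r in ((0.0, lo, rate_warm), (lo, hi, rate_cold), (hi, pl, rate_warm)):
        if b <= a:
            continue
        seg_x = np.linspace(a, b, n_pts)
        seg_g = gpos + r * (seg_x - a)
        if xs:
            seg_x, seg_g = seg_x[1:], seg_g[1:]
        xs.append(seg_x)
        gs.append(seg_g)
        gpos += r * (b - a)
    markers = np.column_stack([np.concatenate(xs), np.concatenate(gs)])
    return fit_map(markers, chrom_id=config.chrom_ids[c])


def gen_landscape(config: SyntheticGenomeConfig) -> GenomeSpec:
    """Build the three landscape scenarios from one synthetic-genome recipe."""
    normal, hyper, boost = {}, {}, {}
    for c, cid in enumerate(config.chrom_ids):
        nm = _normal_map(config, c)
        normal[cid] = nm
        hyper[cid] = make_hyperrec(nm, config.GL_increased[c])
        boost[cid] = make_boosted(nm, config.GL_increased[c])
    nu_n = dict(zip(config.chrom_ids, config.nu_normal)) if config.nu_normal else None
    nu_b = dict(zip(config.chrom_ids, config.nu_boosted)) if config.nu_boosted else None
    return GenomeSpec(
        chrom_ids=config.chrom_ids,
        landscapes={
            "normal": RecombinationLandscape("normal", normal, nu_n),
            "hyperrec": RecombinationLandscape("hyperrec", hyper, None),
            "boosted": RecombinationLandscape("boosted", boost, nu_b),
        },
    )


def gen_gene_positions(
    config: SyntheticGenomeConfig,
    genes_per_chrom: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Sample gene physical positions (Mb), sparser inside the pericentromere.

    The density is a two-level mixture: relative density 1 outside the
    pericentromere and ``gene_density_cold_frac`` inside it.
    """
    n = genes_per_chrom if genes_per_chrom is not None else config.genes_per_chrom
    if n < 1:
        raise InvalidCountError("genes_per_chrom must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    out = []
    d = config.gene_density_cold_frac
    for c in range(len(config.chrom_ids)):
        pl = config.PL[c]
        lo, hi = _peri_bounds(config, c)
        w = (hi - lo) / pl
        p_in = d * w / (d * w + (1 - w)) if (d * w + (1 - w)) > 0 else 0.0
        inside = rng.random(n) < p_in
        pos = np.where(
            inside,
            rng.uniform(lo, hi, n),
            _uniform_outside(rng, n, lo, hi, pl),
        )
        out.append(np.sort(pos))
    return out


def _uniform_outside(rng, n, lo, hi, pl):
    """Uniform draws on [0, lo) U (hi, pl]."""
    left = lo
    right = pl - hi
    u = rng.uniform(0.0, left + right, n)
    return np.where(u < left, u, u - left + hi)


@dataclass(frozen=True)
class SyntheticGenome:
    """A generated species: landscapes plus gene physical positions."""

    spec: GenomeSpec
    genes: tuple[np.ndarray, ...]  # per-chromosome Mb positions
    config: SyntheticGenomeConfig


def gen_genome(config: SyntheticGenomeConfig) -> SyntheticGenome:
    rng = np.random.default_rng(config.seed)
    spec = gen_landscape(config)
    genes = tuple(gen_gene_positions(config, rng=rng))
    return SyntheticGenome(spec=spec, genes=genes, config=config)


def sample_qtl(
    gene_positions: Sequence[np.ndarray],
    n_qtl_per_chrom: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Draw QTL physical positions uniformly among genes, without replacement."""
    out = []
    for c, genes in enumerate(gene_positions):
        if n_qtl_per_chrom > len(genes):
            raise InsufficientGenesError(
                f"chromosome {c}: {n_qtl_per_chrom} QTL requested, {len(genes)} genes"
            )
        out.append(np.sort(rng.choice(genes, size=n_qtl_per_chrom, replace=False)))
    return out


def draw_amplitudes(
    n: int,
    k: float = 0.4,
    theta: float = 1.58,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """QTL amplitudes ~ Gamma(shape k, scale theta); k=0.4, theta=1.58 gives
    an L-shaped distribution with unit variance of the amplitude."""
    if n < 1:
        raise InvalidCountError("need n >= 1 amplitudes")
    rng = rng if rng is not None else np.random.default_rng()
    return rng.gamma(k, theta, n)


def _signs_from_uniforms(
    pos: np.ndarray, mode: str, L: float, first: int, u: np.ndarray
) -> np.ndarray:
    """Phase walk along one chromosome from pre-drawn uniforms.

    ``P = (1/2)(1 - exp(-dx/L))`` per adjacent pair; under ``coupling`` the
    sign changes when ``u < P``, under ``repulsion`` it stays when ``u < P``.
    """
    pos = np.asarray(pos, dtype=float)
    m = len(pos)
    s = np.empty(m, dtype=np.int8)
    if m == 0:
        return s
    s[0] = first
    if m == 1:
        return s
    dx = np.diff(pos)
    if np.any(dx < 0):
        raise UnsortedInputError("QTL genetic positions must be sorted")
    p = 0.5 * (1.0 - np.exp(-dx / L))
    p_change = p if mode == "coupling" else 1.0 - p
    flips = u < p_change
    s[1:] = first * np.cumprod(np.where(flips, -1, 1))
    return s


def assign_phase(
    qtl_genetic: Sequence[np.ndarray],
    mode: str = "random",
    L: float = 5.0,
    rng: np.random.Generator | None = None,
) -> list[np.ndarray]:
    """Assign founder-P1 allele signs along each chromosome.

    Walking along a chromosome, the probability attached to each adjacent
    QTL pair is ``P = (1/2) (1 - exp(-dx/L))`` with ``dx`` the genetic
    distance.  Under ``coupling`` P is the probability the sign *changes*;
    under ``repulsion`` the probability it *stays*; ``random`` assigns
    independent uniform signs.
    """
    if mode not in ("random", "coupling", "repulsion"):
        raise InvalidCountError(f"unknown phase mode {mode!r}")
    rng = rng if rng is not None else np.random.default_rng()
    signs = []
    for pos in qtl_genetic:
        m = len(np.asarray(pos))
        if mode == "random":
            signs.append(rng.choice(np.array([-1, 1], dtype=np.int8), size=m))
            continue
        first = int(rng.choice([-1, 1]))
        u = rng.random(max(m - 1, 0))
        signs.append(_signs_from_uniforms(pos, mode, L, first, u))
    return signs


@dataclass(frozen=True)
class TraitModel:
    """QTL architecture of one replicate.

    Physical positions and amplitudes are shared by all landscape scenarios;
    genetic positions are scenario-specific.  Allelic effects are ``+-a/2``:
    founder P1 carries ``sign_p1 * a/2`` at each QTL and P2 the opposite
    allele.  Under random phase the signs are identical across scenarios;
    under coupling/repulsion the phase walk depends on genetic distances and
    the signs are therefore keyed by scenario (sharing the underlying random
    draws, so scenarios differ only where their linkage differs).
    """

    qtl_physical: tuple[np.ndarray, ...]  # per chromosome, Mb, sorted
    amplitude: tuple[np.ndarray, ...]  # per chromosome, > 0
    sign_p1: Mapping[str, tuple[np.ndarray, ...]]  # scenario -> per chromosome +-1
    qtl_genetic: Mapping[str, tuple[np.ndarray, ...]]  # scenario -> per chromosome cM

    @property
    def n_qtl(self) -> int:
        return int(sum(len(a) for a in self.amplitude))

    def effects_p1(self, scenario: str = "normal") -> np.ndarray:
        """Concatenated P1 allelic effects (sign * a / 2), chromosome order."""
        return np.concatenate(
            [s * a / 2.0 for s, a in zip(self.sign_p1[scenario], self.amplitude)]
        )

    def gain_ceiling(self) -> float:
        """Maximum attainable mean genotypic value: sum of QTL amplitudes."""
        return float(sum(a.sum() for a in self.amplitude))


def build_trait(
    genome: SyntheticGenome,
    n_qtl_per_chrom: int,
    rng: np.random.Generator,
    phase_mode: str = "random",
    L: float = 5.0,
    k: float = 0.4,
    theta: float = 1.58,
) -> TraitModel:
    """Sample one replicate's QTL architecture from a synthetic genome.

    Under random phase one sign vector is drawn and shared by all scenarios.
    Under coupling/repulsion the phase walk is driven by each scenario's own
    genetic distances; the per-pair uniforms and per-chromosome first signs
    are shared across scenarios, so the sign vectors coincide wherever the
    linkage does.
    """
    if phase_mode not in ("random", "coupling", "repulsion"):
        raise InvalidCountError(f"unknown phase mode {phase_mode!r}")
    qtl_phys = sample_qtl(genome.genes, n_qtl_per_chrom, rng)
    amps = tuple(draw_amplitudes(len(q), k, theta, rng) for q in qtl_phys)
    scenarios = tuple(genome.spec.landscapes)
    qtl_gen = {
        scen: tuple(
            np.asarray(physical_to_genetic(lsc.maps[cid], q))
            for cid, q in zip(genome.spec.chrom_ids, qtl_phys)
        )
        for scen, lsc in genome.spec.landscapes.items()
    }
    if phase_mode == "random":
        shared = tuple(assign_phase(qtl_gen["normal"], "random", L, rng))
        signs = {scen: shared for scen in scenarios}
    else:
        firsts = [int(rng.choice([-1, 1])) for _ in qtl_phys]
        us = [rng.random(max(len(q) - 1, 0)) for q in qtl_phys]
        signs = {
            scen: tuple(
                _signs_from_uniforms(qtl_gen[scen][c], phase_mode, L, firsts[c], us[c])
                for c in range(len(qtl_phys))
            )
            for scen in scenarios
        }
    return TraitModel(
        qtl_physical=tuple(qtl_phys),
        amplitude=amps,
        sign_p1=signs,
        qtl_genetic=qtl_gen,
    )


def read_gff_genes(path) -> dict[str, np.ndarray]:
    """Gene physical positions (Mb) per chromosome from a GFF3 annotation.

    Uses gene start coordinates; 1-based inclusive GFF starts are converted
    to the internal 0-based Mb convention.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out: dict[str, list[float]] = {}
    for gene in db.features_of_type("gene"):
        out.setdefault(gene.seqid, []).append((gene.start - 1) / 1e6)
    return {k: np.sort(np.asarray(v)) for k, v in out.items()}
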