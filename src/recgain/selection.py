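"""Recurrent-selection schemes over a biparental population.

The engine follows the standard design: two inbred founders P1/P2 (g = 0)
are crossed to an F1 (g = 1); the F1 is selfed to 250 F2 individuals (Fn
scheme) or turned into 250 doubled haploids (DH scheme) at g = 2, the first
generation under selection.  Each subsequent generation keeps the best
``n_selected`` individuals by truncation on a breeding value — the phenotype
(phenotypic selection) or the genomic estimated breeding value from an
RR-BLUP model (genomic selection) — and mates them at random (ordered pairs
of distinct parents) to restore the population size.  Environmental variance
is calibrated once, on the g = 2 genetic variance, to reach the configured
heritability, and held fixed afterwards.

Populations are stored as founder-origin arrays of shape
``(n_individuals, 2, n_loci)`` over the union of QTL and neutral-marker
genetic positions (see :class:`LociLayout`); meioses use the exact
locus-parity construction of :func:`recgain.meiosis.meiosis_batch`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateTraitError,
    InvalidCountError,
    PanelMismatchError,
)
from .genome import RecombinationLandscape, place_neutral_markers
from .meiosis import Individual, meiosis_batch
from .rrblup import MarkerRidge
from .synth import TraitModel

__all__ = [
    "SchemeConfig",
    "TraitState",
    "GSModel",
    "LociLayout",
    "Trajectory",
    "genotypic_value",
    "calibrate_VE",
    "phenotype",
    "genotype_matrix",
    "fit_rrblup",
    "gebv",
    "truncation_select",
    "run_fn_scheme",
    "run_dh_scheme",
    "run_scheme",
]

RECALIBRATION_SCHEDULES = {
    "F2_only": (2,),
    "every_4": (2, 6, 10, 14, 18),
    "every_2": tuple(range(2, 21, 2)),
}


@dataclass(frozen=True)
class SchemeConfig:
    """Parameters of one selection program."""

    scheme: str = "Fn"  # Fn | DH
    pop_size: int = 250
    n_selected: int = 5  # 2% of 250
    n_generations: int = 20
    selection_mode: str = "genomic"  # genomic | phenotypic
    h2: float = 0.5
    recalibration: str = "every_4"  # F2_only | every_2 | every_4
    scenario: str = "normal"
    interference: bool = False
    markers_per_chrom: int = 1000
    allow_selfing: bool = False  # random mating among the selected

    def __post_init__(self):
        if self.scheme not in ("Fn", "DH"):
            raise InvalidCountError(f"unknown scheme {self.scheme!r}")
        if self.selection_mode not in ("genomic", "phenotypic"):
            raise InvalidCountError(f"unknown selection mode {self.selection_mode!r}")
        if self.recalibration not in RECALIBRATION_SCHEDULES:
            raise InvalidCountError(f"unknown recalibration {self.recalibration!r}")
        if not 0 < self.h2 <= 1:
            raise InvalidCountError("h2 must be in (0, 1]")
        if self.n_selected > self.pop_size:
            raise InvalidCountError("cannot select more individuals than exist")
        if self.n_generations < 2:
            raise InvalidCountError("need at least 2 generations")


@dataclass(frozen=True)
class TraitState:
    """Fixed environmental variance implied by the g = 2 genetic variance."""

    V_E: float
    V_G_F2: float
    h2: float


@dataclass(frozen=True)
class GSModel:
    """Trained genomic-selection model: intercept and marker effects."""

    beta: float
    u: np.ndarray
    trained_at: int  # generation index


@dataclass(frozen=True)
class LociLayout:
    """Locus bookkeeping for one (landscape scenario, trait) pair.

    Loci are the per-chromosome sorted union of QTL genetic positions and
    equally spaced neutral markers; ``qtl_cols``/``marker_cols`` map trait
    and marker order onto the concatenated locus axis.
    """

    chrom_pos: tuple[np.ndarray, ...]  # sorted cM per chromosome
    GL: tuple[float, ...]
    nu: tuple[float, ...] | None
    qtl_cols: np.ndarray  # concatenated-locus index of each QTL (trait order)
    marker_cols: np.ndarray  # concatenated-locus index of each neutral marker
    effects_p1: np.ndarray  # P1 allelic effect per QTL (sign * a / 2)

    @property
    def n_loci(self) -> int:
        return int(sum(len(p) for p in self.chrom_pos))

    @classmethod
    def build(
        cls,
        landscape: RecombinationLandscape,
        trait: TraitModel,
        markers_per_chrom: int = 1000,
        interference: bool = False,
    ) -> "LociLayout":
        scen = landscape.scenario
        chrom_pos, qtl_cols, marker_cols = [], [], []
        GLs, nus = [], []
        offset = 0
        for c, (cid, cmap) in enumerate(landscape.maps.items()):
            qg = np.asarray(trait.qtl_genetic[scen][c], dtype=float)
            mg = place_neutral_markers(cmap.GL, markers_per_chrom)
            pos = np.concatenate([qg, mg])
            order = np.argsort(pos, kind="stable")
            inv = np.empty_like(order)
            inv[order] = np.arange(len(pos))
            chrom_pos.append(pos[order])
            qtl_cols.append(inv[: len(qg)] + offset)
            marker_cols.append(inv[len(qg) :] + offset)
            GLs.append(cmap.GL)
            if interference:
                if landscape.nu is None:
                    raise InvalidCountError(
                        f"landscape {scen!r} has no interference parameters"
                    )
                nus.append(landscape.nu[cid])
            offset += len(pos)
        return cls(
            chrom_pos=tuple(chrom_pos),
            GL=tuple(GLs),
            nu=tuple(nus) if interference else None,
            qtl_cols=np.concatenate(qtl_cols),
            marker_cols=np.concatenate(marker_cols),
            effects_p1=trait.effects_p1(scen),
        )


@dataclass
class Trajectory:
    """Per-generation population summaries of one run."""

    scenario: str
    scheme: str
    generations: np.ndarray  # 2..n_generations
    mean_G: np.ndarray
    var_G: np.ndarray
    n_fixed_qtl: np.ndarray
    gs_trained: np.ndarray  # bool per generation
    replicate: int = 0
    seed: int | None = None

    def gain(self, g: int) -> float:
        """Cumulative genetic gain: mean G at generation g minus at g = 2."""
        if g < 2 or g > int(self.generations[-1]):
            raise InvalidCountError(f"generation {g} outside trajectory range")
        i = int(np.searchsorted(self.generations, g))
        return float(self.mean_G[i] - self.mean_G[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": self.replicate,
                "seed": self.seed if self.seed is not None else -1,
                "scenario": self.scenario,
                "scheme": self.scheme,
                "generation": self.generations,
                "mean_G": self.mean_G,
                "var_G": self.var_G,
                "gain": self.mean_G - self.mean_G[0],
                "n_fixed_qtl": self.n_fixed_qtl,
                "gs_trained": self.gs_trained.astype(int),
            }
        )


# ---------------------------------------------------------------------------
# quantitative genetics primitives

def genotypic_value(ind: Individual, trait: TraitModel, scenario: str = "normal") -> float:
    """Additive genotypic value: sum of the two carried allelic effects per QTL."""
    total = 0.0
    for c, qg in enumerate(trait.qtl_genetic[scenario]):
        e = trait.sign_p1[scenario][c] * trait.amplitude[c] / 2.0
        d = ind.dosage_at(c, qg)  # count of P2 alleles
        total += float(np.sum(e * (2.0 - 2.0 * d)))
    return total


def _values_from_origins(origins: np.ndarray, layout: LociLayout) -> np.ndarray:
    """Genotypic values of a population array (n, 2, L)."""
    d = origins[:, 0, layout.qtl_cols].astype(np.float64) + origins[
        :, 1, layout.qtl_cols
    ].astype(np.float64)
    return 2.0 * layout.effects_p1.sum() - 2.0 * d @ layout.effects_p1


def calibrate_VE(f2_values: np.ndarray, h2: float) -> TraitState:
    """Environmental variance giving heritability ``h2`` at g = 2, then fixed."""
    f2_values = np.asarray(f2_values, dtype=float)
    if f2_values.size < 2:
        raise DegenerateTraitError("need at least 2 genotypic values")
    if not 0 < h2 <= 1:
        raise InvalidCountError("h2 must be in (0, 1]")
    vg = float(np.var(f2_values, ddof=1))
    if vg == 0 and h2 < 1:
        raise DegenerateTraitError("zero genetic variance with h2 < 1")
    return TraitState(V_E=vg * (1.0 - h2) / h2, V_G_F2=vg, h2=h2)


def phenotype(
    values: np.ndarray, state: TraitState, rng: np.random.Generator
) -> np.ndarray:
    """Phenotypes: genotypic values plus N(0, V_E) environmental noise."""
    values = np.asarray(values, dtype=float)
    if state.V_E == 0:
        return values.copy()
    return values + rng.normal(0.0, np.sqrt(state.V_E), values.shape)


def genotype_matrix(origins: np.ndarray, layout: LociLayout) -> np.ndarray:
    """Marker matrix coded -1 (hom. P1) / 0 (het.) / +1 (hom. P2)."""
    d = origins[:, 0, layout.marker_cols].astype(np.int8) + origins[
        :, 1, layout.marker_cols
    ].astype(np.int8)
    return d - 1


def fit_rrblup(Y: np.ndarray, Z: np.ndarray, trained_at: int = 0) -> GSModel:
    """REML RR-BLUP fit wrapped into a :class:`GSModel`."""
    res = MarkerRidge(Y, Z).fit()
    return GSModel(beta=res.beta, u=res.u, trained_at=trained_at)


def gebv(Z: np.ndarray, model: GSModel) -> np.ndarray:
    """Genomic estimated breeding values ``beta + Z @ u``."""
    Z = np.asarray(Z)
    if Z.shape[1] != len(model.u):
        raise PanelMismatchError(
            f"genotype matrix has {Z.shape[1]} markers, model expects {len(model.u)}"
        )
    return model.beta + Z.astype(float) @ model.u


def truncation_select(
    values: np.ndarray, n_keep: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of the ``n_keep`` largest values; ties broken uniformly at random."""
    values = np.asarray(values, dtype=float)
    if n_keep > len(values):
        raise InvalidCountError("n_keep exceeds the number of candidates")
    order = np.lexsort((rng.random(len(values)), values))
    return order[len(values) - n_keep :]


# ---------------------------------------------------------------------------
# scheme runners

def _mating_pairs(
    n_off: int, n_parents: int, rng: np.random.Generator, allow_selfing: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Ordered parent pairs for each offspring, distinct unless selfing allowed."""
    a = rng.integers(0, n_parents, n_off)
    if allow_selfing or n_parents == 1:
        b = rng.integers(0, n_parents, n_off)
    else:
        b = (a + 1 + rng.integers(0, n_parents - 1, n_off)) % n_parents
    return a, b


def _f1_origins(n_loci: int) -> np.ndarray:
    f1 = np.zeros((1, 2, n_loci), dtype=np.uint8)
    f1[0, 1, :] = 1
    return f1


def _n_fixed(origins: np.ndarray, layout: LociLayout) -> int:
    q = origins[:, :, layout.qtl_cols]
    col_sum = q.sum(axis=(0, 1))
    n_alleles = 2 * origins.shape[0]
    return int(np.sum((col_sum == 0) | (col_sum == n_alleles)))


class _Recorder:
    def __init__(self, layout: LociLayout):
        self.layout = layout
        self.gens, self.mean, self.var, self.fixed, self.trained = [], [], [], [], []

    def add(self, g: int, origins: np.ndarray, values: np.ndarray, trained: bool):
        self.gens.append(g)
        self.mean.append(float(values.mean()))
        # an absorbed (all-identical) population has exactly zero variance
        v = 0.0 if np.ptp(values) == 0 else float(np.var(values, ddof=1))
        self.var.append(v)
        self.fixed.append(_n_fixed(origins, self.layout))
        self.trained.append(trained)

    def finish(self, config: SchemeConfig, replicate: int, seed) -> Trajectory:
        return Trajectory(
            scenario=config.scenario,
            scheme=config.scheme,
            generations=np.asarray(self.gens),
            mean_G=np.asarray(self.mean),
            var_G=np.asarray(self.var),
            n_fixed_qtl=np.asarray(self.fixed),
            gs_trained=np.asarray(self.trained, dtype=bool),
            replicate=replicate,
            seed=seed,
        )


def _maybe_train(
    config: SchemeConfig,
    g: int,
    values: np.ndarray,
    origins: np.ndarray,
    layout: LociLayout,
    state: TraitState,
    model: GSModel | None,
    rng: np.random.Generator,
) -> tuple[GSModel | None, bool]:
    """Refit the GS model at scheduled training generations.

    After fixation with h2 = 1 the phenotypes are constant and the model is
    unfittable; the previous model is kept (selection is pure drift then).
    """
    if config.selection_mode != "genomic":
        return model, False
    if g not in RECALIBRATION_SCHEDULES[config.recalibration]:
        return model, False
    y = phenotype(values, state, rng)
    if np.ptp(y) == 0:
        return model, False
    Z = genotype_matrix(origins, layout)
    return fit_rrblup(y, Z, trained_at=g), True


def _criterion(
    config: SchemeConfig,
    values: np.ndarray,
    origins: np.ndarray,
    layout: LociLayout,
    state: TraitState,
    model: GSModel | None,
    rng: np.random.Generator,
) -> np.ndarray:
    if config.selection_mode == "phenotypic":
        return phenotype(values, state, rng)
    assert model is not None
    return gebv(genotype_matrix(origins, layout), model)


def run_fn_scheme(
    config: SchemeConfig,
    landscape: RecombinationLandscape,
    trait: TraitModel,
    rng: np.random.Generator,
    replicate: int = 0,
    seed=None,
) -> Trajectory:
    """Recurrent selection on heterozygous populations (selfed-F2 start)."""
    layout = LociLayout.build(
        landscape, trait, config.markers_per_chrom, config.interference
    )
    L = layout.n_loci
    n = config.pop_size
    f1 = _f1_origins(L)
    idx0 = np.zeros(n, dtype=np.intp)
    # F2 by selfing: two independent meioses of the F1 per individual
    origins = np.stack(
        [
            meiosis_batch(f1[idx0], layout.chrom_pos, layout.GL, layout.nu, rng),
            meiosis_batch(f1[idx0], layout.chrom_pos, layout.GL, layout.nu, rng),
        ],
        axis=1,
    )
    values = _values_from_origins(origins, layout)
    state = calibrate_VE(values, config.h2)
    rec = _Recorder(layout)
    model, trained = _maybe_train(config, 2, values, origins, layout, state, None, rng)
    rec.add(2, origins, values, trained)
    for g in range(2, config.n_generations):
        crit = _criterion(config, values, origins, layout, state, model, rng)
        sel = truncation_select(crit, config.n_selected, rng)
        a, b = _mating_pairs(n, len(sel), rng, config.allow_selfing)
        origins = np.stack(
            [
                meiosis_batch(origins[sel[a]], layout.chrom_pos, layout.GL, layout.nu, rng),
                meiosis_batch(origins[sel[b]], layout.chrom_pos, layout.GL, layout.nu, rng),
            ],
            axis=1,
        )
        values = _values_from_origins(origins, layout)
        model, trained = _maybe_train(
            config, g + 1, values, origins, layout, state, model, rng
        )
        rec.add(g + 1, origins, values, trained)
    return rec.finish(config, replicate, seed)


def run_dh_scheme(
    config: SchemeConfig,
    landscape: RecombinationLandscape,
    trait: TraitModel,
    rng: np.random.Generator,
    replicate: int = 0,
    seed=None,
) -> Trajectory:
    """Recurrent selection alternating doubled-haploid panels and crosses.

    Even generations are fully homozygous DH panels where selection and GS
    training happen; odd generations are the heterozygous crosses of the
    selected DHs, each contributing exactly one DH to the next panel.
    """
    layout = LociLayout.build(
        landscape, trait, config.markers_per_chrom, config.interference
    )
    n = config.pop_size
    f1 = _f1_origins(layout.n_loci)
    idx0 = np.zeros(n, dtype=np.intp)
    gam = meiosis_batch(f1[idx0], layout.chrom_pos, layout.GL, layout.nu, rng)
    origins = np.stack([gam, gam], axis=1)  # DH panel at g = 2
    values = _values_from_origins(origins, layout)
    state = calibrate_VE(values, config.h2)
    rec = _Recorder(layout)
    model, trained = _maybe_train(config, 2, values, origins, layout, state, None, rng)
    rec.add(2, origins, values, trained)
    g = 2
    while g + 2 <= config.n_generations:
        crit = _criterion(config, values, origins, layout, state, model, rng)
        sel = truncation_select(crit, config.n_selected, rng)
        a, b = _mating_pairs(n, len(sel), rng, config.allow_selfing)
        hets = np.stack(
            [
                meiosis_batch(origins[sel[a]], layout.chrom_pos, layout.GL, layout.nu, rng),
                meiosis_batch(origins[sel[b]], layout.chrom_pos, layout.GL, layout.nu, rng),
            ],
            axis=1,
        )
        het_values = _values_from_origins(hets, layout)
        rec.add(g + 1, hets, het_values, False)
        gam = meiosis_batch(hets, layout.chrom_pos, layout.GL, layout.nu, rng)
        origins = np.stack([gam, gam], axis=1)
        values = _values_from_origins(origins, layout)
        g += 2
        model, trained = _maybe_train(
            config, g, values, origins, layout, state, model, rng
        )
        rec.add(g, origins, values, trained)
    return rec.finish(config, replicate, seed)


def run_scheme(
    config: SchemeConfig,
    landscape: RecombinationLandscape,
    trait: TraitModel,
    rng: np.random.Generator,
    replicate: int = 0,
    seed=None,
) -> Trajectory:
    runner = run_fn_scheme if config.scheme == "Fn" else run_dh_scheme
    return runner(config, landscape, trait, rng, replicate, seed)
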