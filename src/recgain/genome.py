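"""Genetic maps, recombination landscapes and landscape-engineering transforms.

A :class:`ChromosomeMap` is a monotone Marey map: a non-decreasing function
from physical position (Mb) to genetic position (cM), anchored at 0 cM on the
first mapped marker.  Two transforms derive engineered landscapes from a
normal one:

* :func:`make_hyperrec` multiplies the local recombination rate everywhere by
  a constant (``GL_target / GL``), preserving the landscape shape — cold
  pericentromeric regions stay cold;
* :func:`make_boosted` adds a spatially constant rate
  ``(GL_target - GL) / PL`` (cM/Mb) everywhere, warming cold regions.

Both reach the same per-chromosome target length so the genome-wide increase
is identical and only its spatial distribution differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from sklearn.isotonic import IsotonicRegression

from .errors import (
    InconsistentMapError,
    InvalidCountError,
    InvalidMapError,
    InvalidTargetError,
    OutOfRangeError,
)

__all__ = [
    "ChromosomeMap",
    "RecombinationLandscape",
    "GenomeSpec",
    "fit_map",
    "physical_to_genetic",
    "make_boosted",
    "make_hyperrec",
    "place_neutral_markers",
    "rate_on_grid",
    "read_marey_tsv",
    "write_landscape_tsv",
]

#: maximum monotonicity violation (cM) absorbed as noise by fit_map
MONOTONE_TOL = 3.0


@dataclass(frozen=True)
class ChromosomeMap:
    """Monotone physical (Mb) -> genetic (cM) map for one chromosome."""

    chrom_id: str
    physical: np.ndarray  # Mb, strictly increasing
    genetic: np.ndarray  # cM, non-decreasing, genetic[0] == 0
    _interp: PchipInterpolator = field(repr=False, compare=False)

    @property
    def GL(self) -> float:
        """Total genetic length (cM)."""
        return float(self.genetic[-1])

    @property
    def PL(self) -> float:
        """Mapped physical span (Mb)."""
        return float(self.physical[-1] - self.physical[0])

    def __call__(self, x):
        return physical_to_genetic(self, x)


def _build(chrom_id: str, physical: np.ndarray, genetic: np.ndarray) -> ChromosomeMap:
    interp = PchipInterpolator(physical, genetic)
    return ChromosomeMap(chrom_id, physical, genetic, interp)


@dataclass(frozen=True)
class _RampedInterp:
    """Base interpolant plus a linear ramp ``slope * (x - x0)``.

    Refitting a monotone cubic through ramped points would not commute with
    the ramp near curvature changes; composing functionally keeps the added
    recombination rate exactly constant everywhere.
    """

    base: object
    slope: float
    x0: float

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        return self.base(x) + self.slope * (x - self.x0)


def fit_map(
    markers: Iterable[tuple[float, float]] | np.ndarray,
    chrom_id: str = "chr",
    monotone_tol: float = MONOTONE_TOL,
) -> ChromosomeMap:
    """Fit a monotone Marey map from ``(physical Mb, genetic cM)`` markers.

    Noise in the genetic positions is removed by isotonic projection; the
    projected points are interpolated with a monotone (PCHIP) cubic.  Genetic
    positions are re-anchored so the first mapped marker sits at 0 cM.

    Raises
    ------
    InvalidMapError
        Fewer than 3 markers, or physical positions not strictly increasing.
    InconsistentMapError
        Genetic positions decrease by more than ``monotone_tol`` cM, or the
        fitted map has zero total length.
    """
    arr = np.asarray(list(markers) if not isinstance(markers, np.ndarray) else markers, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise InvalidMapError("need at least 3 (physical, genetic) markers")
    phys, gen = arr[:, 0], arr[:, 1]
    if np.any(np.diff(phys) <= 0):
        raise InvalidMapError("physical positions must be strictly increasing")
    iso = IsotonicRegression(increasing=True).fit_transform(phys, gen)
    if np.max(np.abs(iso - gen)) > monotone_tol:
        raise InconsistentMapError(
            "genetic positions decrease beyond the smoothing tolerance "
            f"({monotone_tol} cM)"
        )
    gen_fit = iso - iso[0]
    if gen_fit[-1] <= 0:
        raise InconsistentMapError("fitted map has zero genetic length")
    return _build(chrom_id, phys.copy(), gen_fit)


def physical_to_genetic(cmap: ChromosomeMap, x) -> np.ndarray | float:
    """Genetic position (cM) of physical position(s) ``x`` (Mb)."""
    xa = np.asarray(x, dtype=float)
    lo, hi = cmap.physical[0], cmap.physical[-1]
    if np.any(xa < lo) or np.any(xa > hi):
        raise OutOfRangeError(
            f"{cmap.chrom_id}: position outside mapped range [{lo}, {hi}] Mb"
        )
    out = cmap._interp(xa)
    return float(out) if np.isscalar(x) else out


def make_boosted(cmap: ChromosomeMap, GL_target: float) -> ChromosomeMap:
    """Additive landscape transform: rate + (GL_target - GL)/PL everywhere."""
    if GL_target <= cmap.GL:
        raise InvalidTargetError("GL_target must exceed the current genetic length")
    const = (GL_target - cmap.GL) / cmap.PL  # cM/Mb
    gen = cmap.genetic + const * (cmap.physical - cmap.physical[0])
    interp = _RampedInterp(cmap._interp, const, float(cmap.physical[0]))
    return ChromosomeMap(cmap.chrom_id, cmap.physical, gen, interp)


def make_hyperrec(cmap: ChromosomeMap, GL_target: float) -> ChromosomeMap:
    """Multiplicative landscape transform: genetic positions scaled by GL_target/GL."""
    if GL_target <= cmap.GL:
        raise InvalidTargetError("GL_target must exceed the current genetic length")
    gen = cmap.genetic * (GL_target / cmap.GL)
    return _build(cmap.chrom_id, cmap.physical, gen)


def place_neutral_markers(GL: float, n: int = 1000) -> np.ndarray:
    """``n`` equally spaced genetic positions covering [0, GL] cM."""
    if n < 2:
        raise InvalidCountError("need at least 2 neutral markers")
    if GL <= 0:
        raise InvalidMapError("GL must be positive")
    return np.linspace(0.0, GL, n)


def rate_on_grid(cmap: ChromosomeMap, step: float = 0.1):
    """Local recombination rate (cM/Mb) by finite differences on a fixed grid.

    Returns ``(grid_Mb, genetic_cM, rate_cM_per_Mb)``; the rate array has one
    fewer entry than the grid (midpoint rates of consecutive grid cells).
    """
    grid = np.arange(cmap.physical[0], cmap.physical[-1] + step / 2, step)
    grid[-1] = cmap.physical[-1]
    gen = physical_to_genetic(cmap, grid)
    rate = np.diff(gen) / np.diff(grid)
    return grid, gen, rate


@dataclass(frozen=True)
class RecombinationLandscape:
    """One scenario's set of chromosome maps plus optional interference shapes."""

    scenario: str  # normal | hyperrec | boosted
    maps: Mapping[str, ChromosomeMap]
    nu: Mapping[str, float] | None = None  # gamma interference shape per chromosome

    def __post_init__(self):
        if self.nu is not None:
            if set(self.nu) != set(self.maps):
                raise InvalidMapError("nu must cover exactly the mapped chromosomes")
            if any(v < 1 for v in self.nu.values()):
                raise InvalidMapError("interference shape nu must be >= 1")

    @property
    def chrom_ids(self) -> tuple[str, ...]:
        return tuple(self.maps)

    def total_GL(self) -> float:
        return sum(m.GL for m in self.maps.values())


@dataclass(frozen=True)
class GenomeSpec:
    """The three landscape scenarios of one species."""

    chrom_ids: tuple[str, ...]
    landscapes: Mapping[str, RecombinationLandscape]

    def __post_init__(self):
        for scen, lsc in self.landscapes.items():
            if tuple(lsc.maps) != tuple(self.chrom_ids):
                raise InvalidMapError(f"landscape {scen!r} does not cover all chromosomes")
        if {"hyperrec", "boosted"} <= set(self.landscapes):
            for cid in self.chrom_ids:
                g1 = self.landscapes["hyperrec"].maps[cid].GL
                g2 = self.landscapes["boosted"].maps[cid].GL
                if abs(g1 - g2) > 1e-6:
                    raise InvalidMapError(
                        f"{cid}: hyperrec and boosted total lengths differ ({g1} vs {g2})"
                    )

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_ids)


def read_marey_tsv(path) -> dict[str, ChromosomeMap]:
    """Read a marker table (columns chrom, physical_Mb, genetic_cM) into fitted maps."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "physical_Mb", "genetic_cM"}
    if not required <= set(df.columns):
        raise InvalidMapError(f"marker TSV needs columns {sorted(required)}")
    maps = {}
    for cid, sub in df.groupby("chrom", sort=False):
        sub = sub.sort_values("physical_Mb")
        maps[str(cid)] = fit_map(
            np.column_stack([sub["physical_Mb"], sub["genetic_cM"]]), chrom_id=str(cid)
        )
    return maps


def write_landscape_tsv(landscape: RecombinationLandscape, path, step: float = 0.1) -> None:
    """Dump grid positions and local rates of every chromosome for inspection."""
    frames = []
    for cid, cmap in landscape.maps.items():
        grid, gen, rate = rate_on_grid(cmap, step)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": cid,
                    "grid_Mb": grid[:-1],
                    "genetic_cM": gen[:-1],
                    "rate_cM_per_Mb": rate,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
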