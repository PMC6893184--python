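"""Crossover formation and gamete/individual construction.

Crossovers are simulated directly in genetic space at the gamete scale: the
expected number per chromosome and meiosis is GL/100, i.e. one crossover per
100 cM.  Two models are available:

* Haldane (no interference): Poisson count, uniform positions;
* single-pathway gamma renewal: inter-crossover distances are gamma with
  shape ``nu`` (>= 1) and mean 100 cM.  The first event is drawn from the
  equilibrium residual distribution so the process is stationary; crossover
  density is then uniform along the chromosome and the expected count stays
  GL/100 for every ``nu``.  ``nu = 1`` reduces exactly to Haldane.

Two representations coexist.  The segment representation
(:class:`Gamete`/:class:`Individual`) stores founder-origin mosaics as
breakpoint lists and is convenient for inspection.  The batch functions at
the bottom operate on founder-origin arrays indexed by a fixed set of locus
positions and are what the selection engine uses; they are exact at the loci
(the origin of a locus depends only on the parity of the crossover count
below it) and fully vectorized across a population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import InvalidInterferenceError
from .genome import RecombinationLandscape

__all__ = [
    "Gamete",
    "Individual",
    "draw_crossovers_haldane",
    "draw_crossovers_gamma",
    "make_gamete",
    "cross",
    "self_",
    "make_dh",
    "founder",
    "batch_crossovers",
    "meiosis_batch",
]


# ---------------------------------------------------------------------------
# crossover draws

def draw_crossovers_haldane(GL: float, rng: np.random.Generator) -> np.ndarray:
    """Sorted crossover positions on [0, GL] under the Haldane model."""
    if GL <= 0:
        return np.empty(0)
    n = rng.poisson(GL / 100.0)
    return np.sort(rng.uniform(0.0, GL, n))


def draw_crossovers_gamma(GL: float, nu: float, rng: np.random.Generator) -> np.ndarray:
    """Sorted crossover positions under the stationary gamma-renewal model.

    Inter-arrival distances ~ Gamma(shape nu, mean 100 cM); the first event
    uses the inspection-paradox construction ``U * Gamma(nu + 1)`` so the
    renewal process is in equilibrium and the expected count is GL/100.
    """
    if nu < 1:
        raise InvalidInterferenceError("interference shape nu must be >= 1")
    if GL <= 0:
        return np.empty(0)
    scale = 100.0 / nu
    out = []
    x = rng.random() * rng.gamma(nu + 1.0, scale)
    while x < GL:
        out.append(x)
        x += rng.gamma(nu, scale)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# segment representation

@dataclass(frozen=True)
class Gamete:
    """Founder-origin mosaic: per chromosome, breakpoints (cM) and origins.

    ``origins[c]`` has one more entry than ``breakpoints[c]``; segment ``i``
    spans ``[breakpoints[i-1], breakpoints[i])`` with founder ``origins[i]``
    (0 = P1, 1 = P2).  Adjacent segments always differ in origin.
    """

    breakpoints: tuple[np.ndarray, ...]
    origins: tuple[np.ndarray, ...]

    @property
    def n_chrom(self) -> int:
        return len(self.breakpoints)

    def origin_at(self, c: int, pos) -> np.ndarray:
        """Founder origin (0/1) at genetic position(s) on chromosome ``c``.

        A position belongs to the half-open segment [start, end) containing it.
        """
        idx = np.searchsorted(self.breakpoints[c], np.asarray(pos, float), side="right")
        return self.origins[c][idx]


@dataclass
class Individual:
    """Two gametes on the same landscape scenario."""

    gamete_m: Gamete
    gamete_f: Gamete
    value: float | None = field(default=None, compare=False)  # cached genotypic value

    def dosage_at(self, c: int, pos) -> np.ndarray:
        """Count of P2 alleles (0/1/2) at genetic position(s)."""
        return self.gamete_m.origin_at(c, pos).astype(np.int8) + self.gamete_f.origin_at(
            c, pos
        ).astype(np.int8)


def founder(landscape: RecombinationLandscape, which: int) -> Individual:
    """Fully homozygous founder P1 (which=0) or P2 (which=1)."""
    n = len(landscape.maps)
    bp = tuple(np.empty(0) for _ in range(n))
    org = tuple(np.array([which], dtype=np.int8) for _ in range(n))
    g = Gamete(bp, org)
    return Individual(g, g)


def _compress(bp: np.ndarray, org: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge adjacent segments with equal origin."""
    if len(bp) == 0:
        return bp, org
    keep = org[1:] != org[:-1]
    return bp[keep], np.concatenate([org[:1], org[1:][keep]])


def make_gamete(
    parent: Individual,
    landscape: RecombinationLandscape,
    rng: np.random.Generator,
    interference: bool = False,
) -> Gamete:
    """One meiotic product of ``parent`` under the landscape's crossover model."""
    bps, orgs = [], []
    for c, (cid, cmap) in enumerate(landscape.maps.items()):
        if interference:
            if landscape.nu is None:
                raise InvalidInterferenceError(
                    f"landscape {landscape.scenario!r} carries no nu values"
                )
            xo = draw_crossovers_gamma(cmap.GL, landscape.nu[cid], rng)
        else:
            xo = draw_crossovers_haldane(cmap.GL, rng)
        start = int(rng.integers(0, 2))
        gm = (parent.gamete_m, parent.gamete_f)
        # candidate breakpoints: crossovers plus both parental mosaics' breakpoints
        cand = np.unique(
            np.concatenate([xo, gm[0].breakpoints[c], gm[1].breakpoints[c]])
        )
        # origin immediately at/after each candidate start (half-open segments)
        starts = np.concatenate([[0.0], cand])
        active = (start + np.searchsorted(xo, starts, side="right")) % 2
        org = np.empty(len(starts), dtype=np.int8)
        for s in (0, 1):
            sel = active == s
            if sel.any():
                org[sel] = gm[s].origin_at(c, starts[sel])
        bp, og = _compress(cand, org)
        bps.append(bp)
        orgs.append(og)
    return Gamete(tuple(bps), tuple(orgs))


def cross(
    p1: Individual,
    p2: Individual,
    landscape: RecombinationLandscape,
    rng: np.random.Generator,
    interference: bool = False,
) -> Individual:
    """Offspring of two parents, one independent meiosis each."""
    return Individual(
        make_gamete(p1, landscape, rng, interference),
        make_gamete(p2, landscape, rng, interference),
    )


def self_(
    p: Individual,
    landscape: RecombinationLandscape,
    rng: np.random.Generator,
    interference: bool = False,
) -> Individual:
    """Selfed offspring: two independent meioses of the same parent."""
    return cross(p, p, landscape, rng, interference)


def make_dh(
    p: Individual,
    landscape: RecombinationLandscape,
    rng: np.random.Generator,
    interference: bool = False,
) -> Individual:
    """Doubled haploid: one meiotic product duplicated into both gametes."""
    g = make_gamete(p, landscape, rng, interference)
    return Individual(g, g)


def write_breakpoints_tsv(gamete: Gamete, path, chrom_ids: Sequence[str] | None = None) -> None:
    """Debug dump: one row per segment with its start (cM) and founder origin."""
    import pandas as pd

    rows = []
    for c in range(gamete.n_chrom):
        cid = chrom_ids[c] if chrom_ids is not None else str(c)
        starts = np.concatenate([[0.0], gamete.breakpoints[c]])
        for s, o in zip(starts, gamete.origins[c]):
            rows.append({"chrom": cid, "segment_start_cM": s, "origin": f"P{o + 1}"})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# batched locus-parity engine

def batch_crossovers(
    n: int, GL: float, nu: float | None, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Crossover positions for ``n`` meioses on one chromosome, flat form.

    Returns ``(rows, xpos)``: meiosis index and position of every crossover.
    Positions within a meiosis are unordered (only counts below each locus
    matter downstream).  ``nu=None`` or 1 selects the Haldane model.
    """
    if GL <= 0:
        return np.empty(0, np.intp), np.empty(0)
    lam = GL / 100.0
    if nu is None or nu == 1:
        counts = rng.poisson(lam, n)
        rows = np.repeat(np.arange(n), counts)
        return rows, rng.uniform(0.0, GL, counts.sum())
    if nu < 1:
        raise InvalidInterferenceError("interference shape nu must be >= 1")
    scale = 100.0 / nu
    k = max(4, int(lam + 6.0 * math.sqrt(lam) + 8))
    first = rng.random(n) * rng.gamma(nu + 1.0, scale, n)
    pos = np.cumsum(
        np.concatenate([first[:, None], rng.gamma(nu, scale, (n, k - 1))], axis=1),
        axis=1,
    )
    while pos[:, -1].min() < GL:  # rare: extend unfinished renewal sequences
        ext = np.cumsum(rng.gamma(nu, scale, (n, k)), axis=1) + pos[:, -1:]
        pos = np.concatenate([pos, ext], axis=1)
    mask = pos < GL
    rows, _ = np.nonzero(mask)
    return rows, pos[mask]


def meiosis_batch(
    parent_origins: np.ndarray,
    loci: Sequence[np.ndarray],
    GL: Sequence[float],
    nu: Sequence[float] | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiotic product per parent, on a fixed locus grid.

    ``parent_origins`` has shape ``(n, 2, L)`` (meiosis, parental gamete,
    locus) with founder origins 0/1; ``loci`` lists the sorted genetic
    positions per chromosome (concatenated to length L).  The origin of a
    locus in the product is ``parent_origins[i, (start_i + m) % 2, l]`` where
    ``m`` is the number of crossovers below the locus — exact for any
    crossover process.
    """
    n = parent_origins.shape[0]
    out = np.empty((n, parent_origins.shape[2]), dtype=np.uint8)
    offset = 0
    rng_start = rng.integers(0, 2, size=(n, len(loci)))
    for c, pos in enumerate(loci):
        Lc = len(pos)
        rows, xpos = batch_crossovers(n, GL[c], None if nu is None else nu[c], rng)
        # uint8 wrap-around is harmless: only the crossover-count parity matters
        counts = np.zeros((n, Lc + 1), dtype=np.uint8)
        idx = np.searchsorted(pos, xpos, side="left")
        np.add.at(counts, (rows, idx), 1)
        counts &= 1
        parity = np.bitwise_xor.accumulate(counts[:, :-1], axis=1)
        parity ^= rng_start[:, c : c + 1].astype(np.uint8)
        sl = slice(offset, offset + Lc)
        g0 = parent_origins[:, 0, sl]
        g1 = parent_origins[:, 1, sl]
        out[:, sl] = np.where(parity == 0, g0, g1)
        offset += Lc
    return out
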