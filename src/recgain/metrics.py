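"""Across-replicate summary statistics: gains, gain ratios, confidence intervals."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InsufficientReplicatesError, InvalidCountError
from .selection import Trajectory

__all__ = [
    "genetic_gain",
    "gain_ratio",
    "aggregate",
    "summarize_pairs",
]


def genetic_gain(traj: Trajectory, g: int) -> float:
    """Cumulative genetic gain at generation ``g`` relative to g = 2."""
    return traj.gain(g)


def gain_ratio(gain_modified, gain_normal) -> float:
    """Efficiency of modified recombination: ratio of mean gains.

    The primary estimator is the ratio of across-replicate mean gains; pass
    arrays of per-replicate gains or two scalars.  A zero denominator yields
    NaN (undefined-ratio sentinel).
    """
    num = float(np.mean(gain_modified))
    den = float(np.mean(gain_normal))
    if den == 0:
        return float("nan")
    return num / den


def paired_ratios(gain_modified, gain_normal) -> np.ndarray:
    """Diagnostic per-replicate paired ratios (NaN where the normal gain is 0)."""
    num = np.asarray(gain_modified, dtype=float)
    den = np.asarray(gain_normal, dtype=float)
    out = np.full(num.shape, np.nan)
    ok = den != 0
    out[ok] = num[ok] / den[ok]
    return out


def aggregate(values: np.ndarray) -> tuple[float, float]:
    """Across-replicate mean and 95% CI half-width (1.96 sd / sqrt(n))."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise InsufficientReplicatesError("need at least 2 replicates")
    return float(values.mean()), float(1.96 * values.std(ddof=1) / np.sqrt(n))


def summarize_pairs(
    trajectories: pd.DataFrame, baseline: str = "normal"
) -> pd.DataFrame:
    """Per-generation paired summary of every scenario against the baseline.

    ``trajectories`` is the long frame written by the experiment runner
    (columns replicate, scenario, generation, gain, ...).  Returns one row
    per (scenario pair, generation) with mean gains, the gain ratio of the
    across-replicate means, and 95% CI half-widths.
    """
    if baseline not in set(trajectories["scenario"]):
        raise InvalidCountError(f"baseline scenario {baseline!r} not present")
    rows = []
    base = trajectories[trajectories["scenario"] == baseline]
    others = [s for s in trajectories["scenario"].unique() if s != baseline]
    for scen in others:
        mod = trajectories[trajectories["scenario"] == scen]
        for g, base_g in base.groupby("generation"):
            mod_g = mod[mod["generation"] == g]
            bg = base_g.sort_values("replicate")["gain"].to_numpy()
            mg = mod_g.sort_values("replicate")["gain"].to_numpy()
            mean_n, ci_n = aggregate(bg)
            mean_m, ci_m = aggregate(mg)
            rows.append(
                {
                    "scenario_pair": f"{scen}/{baseline}",
                    "generation": int(g),
                    "mean_gain_normal": mean_n,
                    "mean_gain_modified": mean_m,
                    "gain_ratio": gain_ratio(mg, bg),
                    "ci_normal": ci_n,
                    "ci_modified": ci_m,
                    "n_replicates": len(bg),
                }
            )
    return pd.DataFrame(rows)
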