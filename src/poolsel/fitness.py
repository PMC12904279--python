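"""Fitness and diversity statistics from strain-frequency estimates.

Relative strain fitness is log2(final frequency / initial frequency):
a fourfold increase scores +2, a fourfold decrease -2, and strains
estimated at frequency zero in a selected community receive a fixed
floor (default -8), below the smallest measurable reduction. Fitness
shifts subtract wild-type relative fitness from mutant-host relative
fitness and are the association response downstream.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import FitnessTable, ShiftTable

__all__ = [
    "relative_fitness",
    "fitness_table",
    "fitness_shift",
    "shannon_diversity",
    "absolute_fitness",
    "competitive_fitness",
]


def relative_fitness(final_freq, initial_freq, floor: float = -8.0):
    """log2(final/initial), with zero final frequencies floored.

    Vectorised over array-like inputs. ``initial_freq`` must be
    positive everywhere (a strain absent from the inoculum has no
    defined relative fitness).
    """
    final = np.asarray(final_freq, dtype=float)
    initial = np.asarray(initial_freq, dtype=float)
    if (initial <= 0).any():
        raise ValueError("initial_freq must be > 0 (strain absent from inoculum)")
    if (final < 0).any():
        raise ValueError("final_freq must be >= 0")
    with np.errstate(divide="ignore"):
        w = np.log2(final / initial)
    w = np.where(final == 0, floor, w)
    if np.isscalar(final_freq) or (w.ndim == 0):
        return float(w)
    return w


def fitness_table(
    final_freqs: pd.DataFrame,
    initial_freqs: pd.Series,
    host_genotype: pd.Series,
    floor: float = -8.0,
) -> FitnessTable:
    """Per-replicate relative fitness for every strain and sample.

    ``final_freqs`` is strains x samples (each column a simplex),
    ``initial_freqs`` the per-strain inoculum frequencies and
    ``host_genotype`` maps sample id -> host genotype.
    """
    init = initial_freqs.reindex(final_freqs.index)
    if init.isna().any() or (init <= 0).any():
        raise ValueError("every strain needs a positive inoculum frequency")
    w = final_freqs.apply(lambda col: relative_fitness(col, init, floor=floor))
    w = pd.DataFrame(
        np.asarray(w, dtype=float), index=final_freqs.index, columns=final_freqs.columns
    )
    floored = final_freqs.eq(0.0)
    hosts = host_genotype.reindex(final_freqs.columns)
    if hosts.isna().any():
        raise ValueError("host_genotype missing for some samples")
    return FitnessTable(w=w, floored=floored, host_genotype=hosts, floor=floor)


def _aggregate(df: pd.DataFrame, how: str) -> pd.Series:
    if how == "mean":
        return df.mean(axis=1)
    if how == "median":
        return df.median(axis=1)
    raise ValueError("aggregate must be 'mean' or 'median'")


def fitness_shift(
    table: FitnessTable, wildtype: str, aggregate: str = "mean"
) -> ShiftTable:
    """Per-strain fitness shift of each mutant host versus wild type.

    Delta w_i = agg(w_i over mutant replicates) - agg(w_i over
    wild-type replicates). Cells touched by the -8 floor in either
    term are flagged (``any_floored``), not excluded.
    """
    hosts = table.host_genotype
    wt_cols = hosts.index[hosts == wildtype]
    if len(wt_cols) == 0:
        raise ValueError(f"no wild-type ({wildtype!r}) samples present")
    wt = _aggregate(table.w[wt_cols], aggregate)
    wt_floored = table.floored[wt_cols].any(axis=1)
    shifts, flags = {}, {}
    for host in pd.unique(hosts):
        if host == wildtype:
            continue
        cols = hosts.index[hosts == host]
        shifts[host] = _aggregate(table.w[cols], aggregate) - wt
        flags[host] = table.floored[cols].any(axis=1) | wt_floored
    return ShiftTable(
        shifts=pd.DataFrame(shifts),
        aggregate=aggregate,
        any_floored=pd.DataFrame(flags),
    )


def shannon_diversity(freqs) -> float:
    """Shannon's H (natural log) of a frequency vector."""
    f = np.asarray(freqs, dtype=float)
    if (f < 0).any() or abs(f.sum() - 1.0) > 1e-8:
        raise ValueError("freqs must be on the simplex")
    f = f[f > 0]
    return float(-(f * np.log(f)).sum())


def absolute_fitness(cfu_total: float, n_units: float) -> float:
    """log10 colony-forming units per plant or per nodule.

    Zero counts are reported as NaN (flagged missing) rather than
    -infinity, matching plate counts below the detection limit.
    """
    if n_units == 0:
        raise ValueError("n_units must be >= 1")
    if cfu_total < 0 or n_units < 0:
        raise ValueError("counts must be nonnegative")
    if cfu_total == 0:
        return float("nan")
    return float(np.log10(cfu_total / n_units))


def competitive_fitness(
    p_nodule: float, p_inoculum: float, total_cfu: float | None = None
):
    """log2 fold change of a focal strain's proportion, nodules vs inoculum.

    When the strain is undetected in the nodule pool (p_nodule == 0)
    the change is below the assay's detection limit; the bound
    log2((1/total_cfu)/p_inoculum) is returned as
    ``("below", bound)`` when ``total_cfu`` is given, else -inf.
    """
    if not 0.0 < p_inoculum < 1.0:
        raise ValueError("p_inoculum must be in (0, 1)")
    if not 0.0 <= p_nodule <= 1.0:
        raise ValueError("p_nodule must be in [0, 1]")
    if p_nodule == 0.0:
        if total_cfu is not None and total_cfu > 0:
            return ("below", float(np.log2((1.0 / total_cfu) / p_inoculum)))
        return float("-inf")
    return float(np.log2(p_nodule / p_inoculum))
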