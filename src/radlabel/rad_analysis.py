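"""Rank abundance diagrams (RADs), SAD histograms and diversity indices.

Turns an equilibrium community into a labeled RAD: species below a frequency
threshold are dropped, the rest renormalized and ranked by descending
frequency with competition ("min") tie ranks.  Species are flagged as *peak*
(frequency above both neighbors on the competitiveness axis) or *non-peak*;
the serrated equilibria of the colonization model make peak species cluster
at high abundance ranks, which is the signal the randomization test probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model_core import (CommunitySpec, ContinuousEquilibrium,
                         EquilibriumCommunity, interval_frequency,
                         solve_equilibrium)

__all__ = [
    "PEAK", "NONPEAK", "EXTINCT",
    "RankedCommunity", "SadHistogram",
    "EmptyRadError", "DegenerateHistogramError", "UndefinedIndexError",
    "label_peaks", "build_rad", "simpson_index", "sad_histograms",
    "deviation_index", "neighbor_survival_fraction", "rad_to_frame",
]

PEAK, NONPEAK, EXTINCT = 1, 0, -1


class EmptyRadError(ValueError):
    """All species fall below the inclusion threshold."""


class DegenerateHistogramError(ValueError):
    """Histogram normalization needs at least two species."""


class UndefinedIndexError(ValueError):
    """No species has a positive analytic reference frequency."""


@dataclass(frozen=True)
class RankedCommunity:
    """A rank abundance diagram: entries ordered by rank (ties by input order).

    ``frequency`` is normalized over the included species (sums to 1),
    ``rank`` uses competition ("min") ranking so tied species share the
    smallest applicable rank, and ``peak`` carries PEAK/NONPEAK flags when
    the RAD came from a model equilibrium (None for empirical tables).
    """

    species_id: np.ndarray
    frequency: np.ndarray
    rank: np.ndarray
    peak: np.ndarray | None = None
    group_key: np.ndarray | None = None

    def __post_init__(self) -> None:
        if abs(float(self.frequency.sum()) - 1.0) > 1e-9:
            raise ValueError("included frequencies must sum to 1")

    def __len__(self) -> int:
        return int(self.species_id.size)

    @property
    def tie_structure(self) -> dict[int, int]:
        """Mapping rank -> number of species sharing it."""
        ranks, counts = np.unique(self.rank, return_counts=True)
        return {int(r): int(c) for r, c in zip(ranks, counts)}


@dataclass(frozen=True)
class SadHistogram:
    """Species abundance histogram over 11 equal classes.

    Frequencies (optionally log2-transformed) are rescaled to [0, 1] between
    the community minimum and maximum and counted into classes of width 0.1;
    class ``k`` covers ``[(k-1)/10, k/10)`` so the maximum species falls
    alone in class 11.
    """

    scale: str
    counts: np.ndarray
    class_edges: np.ndarray = field(
        default_factory=lambda: np.arange(12) / 10.0)


def label_peaks(eq: EquilibriumCommunity) -> np.ndarray:
    """Peak flags on the competitiveness grid.

    A surviving species is a peak iff its frequency exceeds both neighbors'
    (extinct neighbors count as frequency 0; endpoint species compare against
    their single neighbor).  Extinct species get the EXTINCT code.
    """
    p = eq.frequencies
    padded = np.concatenate(([0.0], p, [0.0]))
    flags = np.full(p.size, EXTINCT, dtype=np.int8)
    alive = p > 0
    is_peak = (padded[1:-1] > padded[:-2]) & (padded[1:-1] > padded[2:])
    if p.size == 1:
        is_peak = alive.copy()
    else:
        # endpoints compare against their single neighbor only
        is_peak[0] = p[0] > p[1]
        is_peak[-1] = p[-1] > p[-2]
    flags[alive & is_peak] = PEAK
    flags[alive & ~is_peak] = NONPEAK
    return flags


def build_rad(eq: EquilibriumCommunity, threshold: float = 1e-7) -> RankedCommunity:
    """RAD of a model equilibrium.

    Species with frequency below ``threshold`` are excluded (together with
    empty sites); the remainder are renormalized to sum 1 and ranked by
    descending frequency with min-rank ties.  Species ids are the 1-based
    grid indices and peak flags are carried along.
    """
    p = eq.frequencies
    keep = p >= threshold
    if not keep.any():
        raise EmptyRadError("every species falls below the inclusion threshold")
    flags = label_peaks(eq)[keep]
    freq = p[keep] / p[keep].sum()
    order = np.argsort(-freq, kind="stable")
    ranks_sorted = rankdata(-freq[order], method="min").astype(int)
    ids = (np.flatnonzero(keep) + 1)[order]
    return RankedCommunity(species_id=ids, frequency=freq[order],
                           rank=ranks_sorted, peak=flags[order])


def simpson_index(rad: RankedCommunity) -> float:
    """Simpson's diversity 1 - sum(p_i^2) over the normalized frequencies."""
    return float(1.0 - np.sum(rad.frequency ** 2))


def _histogram(values: np.ndarray, scale: str) -> SadHistogram:
    lo, hi = values.min(), values.max()
    scaled = (values - lo) / (hi - lo)
    classes = np.floor(scaled * 10.0).astype(int)  # max lands alone in class 11
    counts = np.bincount(np.clip(classes, 0, 10), minlength=11)
    return SadHistogram(scale=scale, counts=counts)


def sad_histograms(rad: RankedCommunity) -> tuple[SadHistogram, SadHistogram]:
    """Linear- and log2-scale abundance histograms with 11 classes.

    Frequencies are rescaled between the community minimum (0) and maximum
    (1) before binning; the log2 version applies the same rescaling to
    ``log2(frequency)``.  Requires at least two distinct frequencies.
    """
    freq = rad.frequency
    if freq.size < 2 or freq.min() == freq.max():
        raise DegenerateHistogramError(
            "histogram normalization needs >= 2 distinct frequencies")
    return _histogram(freq, "linear"), _histogram(np.log2(freq), "log2")


def deviation_index(spec: CommunitySpec) -> float:
    """Mean relative deviation between discrete and continuum equilibria.

    Each species is assigned the analytic frequency mass of its half-interval
    cell ``[x_i - h/2, x_i + h/2]`` (h = x_hat / n) truncated to
    ``[x_c, x_hat]``; the index is the mean of
    ``|p_numeric - p_analytic| / p_analytic`` over species whose analytic
    reference is positive.  Values above ~0.2 indicate strong serration.
    """
    ce = ContinuousEquilibrium(spec.trade_off, spec.m, spec.q)
    eq = solve_equilibrium(spec)
    h = spec.trade_off.x_hat / spec.n
    x_hat = spec.trade_off.x_hat
    ratios = []
    for x_i, p_num in zip(spec.positions, eq.frequencies):
        lo = max(x_i - h / 2.0, ce.x_c)
        hi = min(x_i + h / 2.0, x_hat)
        if hi <= lo:
            continue
        p_ana = interval_frequency(ce, lo, hi - lo)
        if p_ana > 0:
            ratios.append(abs(p_num - p_ana) / p_ana)
    if not ratios:
        raise UndefinedIndexError("no species has positive analytic frequency")
    return float(np.mean(ratios))


def neighbor_survival_fraction(eq: EquilibriumCommunity) -> tuple[int, int]:
    """(survivors with a surviving grid-neighbor, total survivors)."""
    alive = eq.survivors
    padded = np.concatenate(([False], alive, [False]))
    has_neighbor = padded[:-2] | padded[2:]
    return int(np.sum(alive & has_neighbor)), int(np.sum(alive))


def rad_to_frame(rad: RankedCommunity) -> pd.DataFrame:
    """Tidy RAD table with columns rank, species_id, frequency, peak, group."""
    peak = (np.full(len(rad), "", dtype=object) if rad.peak is None
            else np.where(rad.peak == PEAK, "peak", "nonpeak"))
    group = (np.full(len(rad), "", dtype=object) if rad.group_key is None
             else np.asarray([str(g) for g in rad.group_key], dtype=object))
    return pd.DataFrame({
        "rank": rad.rank,
        "species_id": rad.species_id,
        "frequency": rad.frequency,
        "peak_flag": peak,
        "group_key": group,
    })
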