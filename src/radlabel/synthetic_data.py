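"""Generators for every input the pipeline needs, with no downloads.

Three kinds of inputs are emulated:

* *null tables* — grouped abundance tables (lognormal or log-series
  abundances, optional tied ranks, genus x guild group structure) whose
  group labels are assigned independently of abundance; the null hypothesis
  of the randomization test, used for type-I calibration.
* *structured tables* — community tables derived from a model equilibrium
  whose groups join adjacent surviving grid-neighbors; these carry the
  quasi-exclusion signal the test is meant to detect.
* *perturbed ensembles* — copies of a community specification with jittered
  or fully random positions on the competitiveness axis, for robustness
  checks of the serrated equilibria.

All generators are pure functions of their specification and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import logser

from .community_io import CommunityTable
from .model_core import (CommunitySpec, DEFAULT_SEED, make_positions,
                         solve_equilibrium)
from .rank_test import GroupAssignment

__all__ = [
    "SyntheticTableSpec", "InfeasibleSpecError",
    "generate_null_table", "generate_structured_table",
    "generate_perturbed_ensemble", "adjacency_groups",
]


class InfeasibleSpecError(ValueError):
    """Group sizes exceed the species count, or too few survivors."""


@dataclass(frozen=True)
class SyntheticTableSpec:
    """Blueprint for a grouped null abundance table.

    Defaults mirror the layout of a 39-species bat community with five
    two-species groups and one three-species group; abundances come from a
    lognormal (meanlog 3, sdlog 1.2) producing a realistic hollow curve, and
    integer rounding plus ``tie_rate`` reproduce the tied ranks of field
    tables.
    """

    S: int = 39
    group_sizes: tuple[int, ...] = (2, 2, 2, 2, 2, 3)
    abundance_model: str = "lognormal"
    meanlog: float = 3.0
    sdlog: float = 1.2
    logser_p: float = 0.98
    tie_rate: float = 0.0
    round_to_int: bool = True
    seed: int = field(default=DEFAULT_SEED)

    def __post_init__(self) -> None:
        if self.S < 1:
            raise InfeasibleSpecError("S must be >= 1")
        if any(g < 2 for g in self.group_sizes):
            raise InfeasibleSpecError("group sizes must be >= 2")
        if sum(self.group_sizes) > self.S:
            raise InfeasibleSpecError("group sizes exceed species count")
        if self.abundance_model not in ("lognormal", "logseries"):
            raise InfeasibleSpecError(
                f"unknown abundance model {self.abundance_model!r}")
        if not (0.0 <= self.tie_rate <= 1.0):
            raise InfeasibleSpecError("tie_rate must lie in [0, 1]")


def _draw_abundances(spec: SyntheticTableSpec,
                     rng: np.random.Generator) -> np.ndarray:
    if spec.abundance_model == "lognormal":
        a = rng.lognormal(spec.meanlog, spec.sdlog, spec.S)
        if spec.round_to_int:
            a = np.ceil(a)  # integer counts; rounding creates natural ties
    else:
        a = logser.rvs(spec.logser_p, size=spec.S,
                       random_state=rng).astype(float)
    a = np.maximum(a, 1.0)
    if spec.tie_rate > 0:
        order = np.argsort(-a, kind="stable")
        tie = rng.random(spec.S - 1) < spec.tie_rate
        for k in np.flatnonzero(tie):
            a[order[k + 1]] = a[order[k]]
    return a


def generate_null_table(spec: SyntheticTableSpec) -> CommunityTable:
    """Grouped abundance table with group labels independent of abundance.

    Each multi-species group gets its own genus and guild code; remaining
    species are singletons with unique genera.  Labels are scattered
    uniformly at random over the species, so any rank structure within
    groups is pure chance.
    """
    rng = np.random.default_rng(spec.seed)
    abund = _draw_abundances(spec, rng)

    genera = np.array([f"Singleton{j:03d}" for j in range(spec.S)], dtype=object)
    guilds = np.full(spec.S, "XX", dtype=object)
    slots = rng.permutation(spec.S)
    pos = 0
    for g, size in enumerate(spec.group_sizes):
        members = slots[pos:pos + size]
        genera[members] = f"Genus{g:02d}"
        guilds[members] = f"G{g:02d}"
        pos += size

    df = pd.DataFrame({
        "species": [f"sp{j:03d}" for j in range(spec.S)],
        "genus": genera, "guild": guilds, "abundance": abund})
    return CommunityTable(df)


def adjacency_groups(eq) -> GroupAssignment:
    """Similarity groups for a model equilibrium: maximal runs of adjacent
    surviving grid positions share a group; isolated survivors are
    singletons.  Keys are 1-based grid indices (matching ``build_rad``)."""
    alive = np.flatnonzero(eq.survivors) + 1
    mapping: dict[int, str] = {}
    run = 0
    for k, idx in enumerate(alive):
        if k > 0 and idx != alive[k - 1] + 1:
            run += 1
        mapping[int(idx)] = f"run{run:03d}"
    return GroupAssignment(mapping)


def generate_structured_table(model_spec: CommunitySpec,
                              grouping: str = "adjacent_runs",
                              seed: int | None = None,
                              scale: float = 1000.0) -> CommunityTable:
    """Community table carrying the model's quasi-exclusion signal.

    The equilibrium of ``model_spec`` is converted to integer abundances
    (frequency x ``scale``, rounded; rounding naturally creates tied ranks).
    With ``grouping='adjacent_runs'`` species in a maximal run of adjacent
    surviving grid positions share a genus/guild; ``'none'`` leaves all
    species as singletons.  ``seed`` is accepted for interface symmetry; the
    construction is deterministic.
    """
    del seed  # deterministic given the model spec
    if grouping not in ("adjacent_runs", "none"):
        raise ValueError(f"unknown grouping rule {grouping!r}")
    eq = solve_equilibrium(model_spec)
    alive = np.flatnonzero(eq.survivors)
    if alive.size < 2:
        raise InfeasibleSpecError("need at least two survivors")

    p_alive = eq.frequencies[alive]
    abund = np.round(p_alive / p_alive.sum() * scale)  # population of `scale`
    genera = np.array([f"Singleton{int(i) + 1:03d}" for i in alive], dtype=object)
    guilds = np.full(alive.size, "XX", dtype=object)
    if grouping == "adjacent_runs":
        labels = adjacency_groups(eq).mapping
        counts: dict[str, int] = {}
        for lab in labels.values():
            counts[lab] = counts.get(lab, 0) + 1
        for k, i in enumerate(alive):
            lab = labels[int(i) + 1]
            if counts[lab] >= 2:
                genera[k] = lab.replace("run", "Genus")
                guilds[k] = lab.replace("run", "G")

    df = pd.DataFrame({
        "species": [f"sp{int(i) + 1:03d}" for i in alive],
        "genus": genera, "guild": guilds, "abundance": abund})
    return CommunityTable(df)


def generate_perturbed_ensemble(spec: CommunitySpec, mode: str,
                                n_replicates: int,
                                seed: int | None = None) -> list[CommunitySpec]:
    """Replicate specs with perturbed positions.

    ``jitter_half_interval`` displaces each species uniformly within half a
    grid interval of its original position; ``uniform_random`` redraws all
    positions uniformly on ``[0, x_hat]``.  Replicates use independent
    streams spawned from ``seed``.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    x_hat = spec.trade_off.x_hat
    ss = np.random.SeedSequence(DEFAULT_SEED if seed is None else seed)
    out = []
    for child in ss.spawn(n_replicates):
        rng = np.random.default_rng(child)
        pos = make_positions(spec.n, x_hat, perturbation=mode, rng=rng)
        out.append(CommunitySpec(positions=pos, m=spec.m, q=spec.q,
                                 trade_off=spec.trade_off))
    return out
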