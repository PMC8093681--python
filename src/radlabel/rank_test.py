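"""Randomization test for similarity-group structure on a labeled RAD.

Species in a ranked community are grouped by ecological similarity (shared
genus x foraging guild for field data; adjacency on the competitiveness axis
for model communities).  Two indices summarize where similar species sit on
the RAD:

* ``sd_distance`` — the standard deviation of pairwise rank distances within
  multi-species groups.  Quasi-exclusion predicts similar species fall at
  consistent rank offsets, so the observed SD should be *small*.
* ``mean_rank`` — the mean rank of all species belonging to a multi-species
  group, which the serrated equilibria skew away from the community average.

The null model permutes group labels uniformly across the ranked species
while the abundance/rank structure (including ties) stays fixed.  The test
reports the one-sided probability ``p_sd`` that a random labeling yields an
SD at most the observed one, the conditional probability ``p_rank`` that a
random labeling on the observed side of the null grand mean is at least as
extreme, and their product, the joint probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping

import numpy as np

from .model_core import DEFAULT_SEED
from .rad_analysis import RankedCommunity

__all__ = [
    "GroupAssignment", "RankTestResult", "NoPairsError", "UndefinedSDError",
    "pairwise_rank_distances", "observed_statistics", "randomize_identities",
    "randomization_test", "significance_mark",
]


class NoPairsError(ValueError):
    """No group holds two or more ranked species."""


class UndefinedSDError(ValueError):
    """Fewer than two pairwise distances: the SD is undefined."""


@dataclass(frozen=True)
class GroupAssignment:
    """Mapping species_id -> group_key; groups of size >= 2 are the
    "similar species" sets, all others are singletons."""

    mapping: Mapping[Hashable, Hashable]

    def group_of(self, species_id) -> Hashable:
        return self.mapping[species_id]

    def label_vector(self, rad: RankedCommunity) -> np.ndarray:
        """Group labels aligned with the RAD's entry order."""
        out = np.empty(len(rad), dtype=object)
        out[:] = [self.mapping[s] for s in rad.species_id]
        return out

    def multi_groups(self, rad: RankedCommunity) -> dict[Hashable, np.ndarray]:
        """Group key -> RAD entry indices, for groups of size >= 2."""
        labels = self.label_vector(rad)
        out: dict[Hashable, list[int]] = {}
        for idx, lab in enumerate(labels):
            out.setdefault(lab, []).append(idx)
        return {k: np.asarray(v) for k, v in out.items() if len(v) >= 2}


@dataclass(frozen=True)
class RankTestResult:
    """Observed indices, null summaries and randomization probabilities."""

    observed_sd: float
    observed_mean_rank: float
    n_trials: int
    p_sd: float
    p_rank: float
    side: str                    # "below" | "above" the null grand mean
    joint_p: float
    null_sd_mean: float
    null_sd_sd: float
    null_mean_mean: float        # grand mean M of within-trial mean ranks
    null_mean_sd: float
    seed: int | None = None
    rank_scale: str = "absolute"
    mode: str = "all_pairs"
    degenerate_side: bool = False

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "observed_sd", "observed_mean_rank", "n_trials", "p_sd", "p_rank",
            "side", "joint_p", "null_sd_mean", "null_sd_sd", "null_mean_mean",
            "null_mean_sd", "seed", "rank_scale", "mode", "degenerate_side")}
        d["significance_sd"] = significance_mark(self.p_sd)
        d["significance_rank"] = significance_mark(self.p_rank)
        return d


def _group_distances(ranks_by_group: list[np.ndarray], mode: str) -> np.ndarray:
    """Pool within-group pairwise rank distances.

    ``all_pairs`` enumerates every unordered pair; ``adjacent_only`` sorts
    each group's ranks and takes consecutive differences (the bias check for
    groups of three or more, where all-pairs double-counts long distances).
    """
    chunks = []
    for r in ranks_by_group:
        if mode == "all_pairs":
            a, b = np.triu_indices(r.size, k=1)
            chunks.append(np.abs(r[a] - r[b]))
        elif mode == "adjacent_only":
            chunks.append(np.abs(np.diff(np.sort(r))))
        else:
            raise ValueError(f"unknown distance mode {mode!r}")
    return np.concatenate(chunks) if chunks else np.empty(0)


def pairwise_rank_distances(rad: RankedCommunity, groups: GroupAssignment,
                            mode: str = "all_pairs") -> np.ndarray:
    """Within-group rank distances pooled over groups of size >= 2."""
    multi = groups.multi_groups(rad)
    if not multi:
        raise NoPairsError("no group holds two or more species")
    return _group_distances([rad.rank[idx].astype(float) for idx in multi.values()],
                            mode)


def observed_statistics(rad: RankedCommunity, groups: GroupAssignment,
                        rank_scale: str = "absolute",
                        resolution: int | None = None,
                        mode: str = "all_pairs") -> tuple[float, float]:
    """(sample SD of pooled distances, mean rank of grouped species).

    ``rank_scale='relative'`` divides ranks by the community resolution
    (defaults to the number of ranked species) before averaging, matching
    indices quoted as relative rank positions.
    """
    dists = pairwise_rank_distances(rad, groups, mode=mode)
    if dists.size < 2:
        raise UndefinedSDError("need at least two distances for an SD")
    multi = groups.multi_groups(rad)
    grouped_idx = np.concatenate([idx for idx in multi.values()])
    scale = 1.0
    if rank_scale == "relative":
        scale = float(resolution if resolution is not None else len(rad))
    elif rank_scale != "absolute":
        raise ValueError(f"unknown rank scale {rank_scale!r}")
    sd = float(np.std(dists / scale, ddof=1))
    mean_rank = float(np.mean(rad.rank[grouped_idx] / scale))
    return sd, mean_rank


def randomize_identities(rad: RankedCommunity, groups: GroupAssignment,
                         rng: np.random.Generator | int | None = None
                         ) -> GroupAssignment:
    """Permute group labels uniformly across the ranked species.

    The abundance vector, the rank multiset (ties included) and all group
    sizes are conserved; only which species carries which label changes.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(DEFAULT_SEED if rng is None else rng)
    labels = groups.label_vector(rad)
    permuted = labels[rng.permutation(labels.size)]
    return GroupAssignment(dict(zip(rad.species_id.tolist(), permuted.tolist())))


def _null_statistics(ranks: np.ndarray, group_sizes: list[int],
                     n_trials: int, rng: np.random.Generator,
                     mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized null draws of (sd_distance, mean_rank).

    Permuting labels over species is equivalent to permuting the rank vector
    over fixed label slots, so each trial permutes ``ranks`` and reads the
    first ``size`` entries of consecutive blocks as the multi-groups.
    """
    S = ranks.size
    perm = rng.permuted(np.tile(np.arange(S), (n_trials, 1)), axis=1)
    R = ranks[perm]                                  # (n_trials, S)
    # multi-group members occupy the leading slots, one block per group
    offsets = np.cumsum([0] + group_sizes)
    n_grouped = offsets[-1]
    mean_rank = R[:, :n_grouped].mean(axis=1)
    dist_cols = []
    for g, size in enumerate(group_sizes):
        block = R[:, offsets[g]:offsets[g + 1]]
        if mode == "all_pairs":
            a, b = np.triu_indices(size, k=1)
            dist_cols.append(np.abs(block[:, a] - block[:, b]))
        else:  # adjacent_only
            dist_cols.append(np.abs(np.diff(np.sort(block, axis=1), axis=1)))
    D = np.concatenate(dist_cols, axis=1)
    sd = D.std(axis=1, ddof=1)
    return sd, mean_rank


def randomization_test(rad: RankedCommunity, groups: GroupAssignment,
                       n_trials: int = 5000,
                       seed: int | None = None,
                       rank_scale: str = "absolute",
                       mode: str = "all_pairs",
                       resolution: int | None = None,
                       p_rank_denominator: str = "same_side") -> RankTestResult:
    """Monte-Carlo randomization test of the two labeled-RAD indices.

    ``p_sd`` is the fraction of trials whose null SD is at most the observed
    SD.  The side of the mean-rank index is set against the null grand mean
    M; ``p_rank`` is the fraction of same-side trials at least as extreme as
    observed (conditional, the default) or of all trials
    (``p_rank_denominator='all'``).  The joint probability is their product.
    Identical inputs and seed reproduce the result bit for bit.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    multi = groups.multi_groups(rad)
    if not multi:
        raise NoPairsError("no group holds two or more species")
    obs_sd, obs_mean = observed_statistics(rad, groups, rank_scale=rank_scale,
                                           resolution=resolution, mode=mode)
    scale = 1.0
    if rank_scale == "relative":
        scale = float(resolution if resolution is not None else len(rad))

    group_sizes = [idx.size for idx in multi.values()]
    # reorder ranks so multi-group members occupy the leading label slots;
    # under uniform permutation the slot order is immaterial
    grouped_idx = np.concatenate([idx for idx in multi.values()])
    rest = np.setdiff1d(np.arange(len(rad)), grouped_idx)
    ranks = rad.rank.astype(float)[np.concatenate([grouped_idx, rest])] / scale

    rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
    null_sd, null_mean = _null_statistics(ranks, group_sizes, n_trials, rng, mode)

    p_sd = float(np.count_nonzero(null_sd <= obs_sd)) / n_trials
    M = float(null_mean.mean())
    side = "below" if obs_mean < M else "above"
    if side == "below":
        same_side = null_mean < M
        extreme = null_mean <= obs_mean
    else:
        same_side = null_mean > M
        extreme = null_mean >= obs_mean
    degenerate = False
    if p_rank_denominator == "same_side":
        denom = int(np.count_nonzero(same_side))
        if denom == 0:
            p_rank = 1.0 / (n_trials + 1)
            degenerate = True
        else:
            p_rank = float(np.count_nonzero(extreme & same_side)) / denom
    elif p_rank_denominator == "all":
        p_rank = float(np.count_nonzero(extreme)) / n_trials
    else:
        raise ValueError(f"unknown p_rank denominator {p_rank_denominator!r}")

    return RankTestResult(
        observed_sd=obs_sd, observed_mean_rank=obs_mean, n_trials=n_trials,
        p_sd=p_sd, p_rank=p_rank, side=side, joint_p=p_sd * p_rank,
        null_sd_mean=float(null_sd.mean()), null_sd_sd=float(null_sd.std(ddof=1)),
        null_mean_mean=M, null_mean_sd=float(null_mean.std(ddof=1)),
        seed=seed, rank_scale=rank_scale, mode=mode, degenerate_side=degenerate)


def significance_mark(p: float) -> str:
    """Band marks: p<=0.05 '+++', <=0.10 '++', <=0.15 '+', else ''."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("probability must lie in [0, 1]")
    if p <= 0.05:
        return "+++"
    if p <= 0.10:
        return "++"
    if p <= 0.15:
        return "+"
    return ""
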