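"""Shared fixtures: small communities with hand-checkable equilibria and an
exhaustive-enumeration oracle for the randomization test."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from radlabel import CommunitySpec, TradeOff
from radlabel.rank_test import observed_statistics


def tradeoff_through(positions, f_values, x_hat=2.5):
    """Strictly increasing piecewise-linear trade-off hitting f(x_i) = f_i.

    Pads the interpolation knots at 0 and x_hat so the function keeps rising
    across the whole domain (the validity requirement), which lets tests pin
    arbitrary increasing fecundity vectors to arbitrary positions.
    """
    positions = np.asarray(positions, dtype=float)
    f_values = np.asarray(f_values, dtype=float)
    step = min(np.min(np.diff(f_values)) if f_values.size > 1 else 1.0, 1.0,
               1.8 * f_values[0])  # keep the padded intercept positive
    xs = np.concatenate(([0.0], positions, [x_hat])) if positions[0] > 0 \
        else np.concatenate((positions, [x_hat]))
    fs = np.concatenate(([f_values[0] - 0.5 * step], f_values,
                         [f_values[-1] + 0.5 * step])) if positions[0] > 0 \
        else np.concatenate((f_values, [f_values[-1] + 0.5 * step]))
    if positions[-1] >= x_hat:
        xs, fs = xs[:-1], fs[:-1]
    return TradeOff.from_callable(lambda x: np.interp(x, xs, fs), x_hat)


def spec_with_fecundities(f_values, m=1.0, q=1.0,
                          positions=None) -> CommunitySpec:
    f_values = np.asarray(f_values, dtype=float)
    if positions is None:
        positions = 0.5 + 1.5 * np.arange(f_values.size) / max(f_values.size, 2)
    return CommunitySpec(positions=np.asarray(positions, dtype=float),
                         m=m, q=q,
                         trade_off=tradeoff_through(positions, f_values))


def exhaustive_rank_test(rad, groups, mode="all_pairs"):
    """Brute-force the randomization test over all S! label placements.

    Returns (p_sd, p_rank, grand_mean).  Independent of the vectorized
    Monte-Carlo path: plain itertools enumeration with per-placement Python
    arithmetic.
    """
    labels = [groups.mapping[s] for s in rad.species_id]
    ranks = rad.rank.astype(float)
    S = len(ranks)
    obs_sd, obs_mean = observed_statistics(rad, groups, mode=mode)
    sds, means = [], []
    for perm in itertools.permutations(range(S)):
        placed = {}
        for slot, sp in enumerate(perm):
            placed.setdefault(labels[slot], []).append(ranks[sp])
        dists, grouped = [], []
        for rs in placed.values():
            if len(rs) < 2:
                continue
            grouped.extend(rs)
            if mode == "all_pairs":
                dists.extend(abs(a - b) for a, b in
                             itertools.combinations(rs, 2))
            else:
                rs = sorted(rs)
                dists.extend(rs[k + 1] - rs[k] for k in range(len(rs) - 1))
        mean_d = sum(dists) / len(dists)
        sds.append(math.sqrt(sum((d - mean_d) ** 2 for d in dists)
                             / (len(dists) - 1)))
        means.append(sum(grouped) / len(grouped))
    sds, means = np.asarray(sds), np.asarray(means)
    p_sd = float(np.mean(sds <= obs_sd + 1e-12))
    grand = float(means.mean())
    if obs_mean < grand:
        same_side = means < grand
        extreme = means <= obs_mean + 1e-12
    else:
        same_side = means > grand
        extreme = means >= obs_mean - 1e-12
    p_rank = float((extreme & same_side).sum() / same_side.sum())
    return p_sd, p_rank, grand


@pytest.fixture
def linear_tradeoff():
    return TradeOff.linear(1.0, 1.0, 2.5)


@pytest.fixture
def strong_saturating_tradeoff():
    """Strongly concave trade-off: the quasi-exclusion showcase regime."""
    return TradeOff.saturating(1.0, 2.5, 3.0, 2.5)


@pytest.fixture
def quasi_exclusion_spec():
    """f = (2, 5, 6), m = q = 1: equilibrium (0.5, 0.1, 0) — species 3
    excluded, species 2 suppressed but coexisting."""
    return spec_with_fecundities([2.0, 5.0, 6.0])


@pytest.fixture
def serrated_spec():
    """f = (2, 3, 6), m = q = 1: equilibrium (0.5, 0, 1/6) — the middle
    species driven out, a serrated survivor pattern."""
    return spec_with_fecundities([2.0, 3.0, 6.0])
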