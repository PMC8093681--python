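"""Patch-occupancy colonization model with a competition-fecundity trade-off.

A habitat of many sites hosts ``n`` species ordered by competitive ability
(index 1 = strongest competitor).  Each species ``i`` carries a competitive
inferiority ``x_i`` on ``[0, x_hat]``; fecundity ``f_i = f(x_i)`` rises with
inferiority through a monotone trade-off ``f``.  Propagules encounter sites
at rate ``q``, colonies are destroyed at rate ``m``, and competition follows
the dominance rule: the superior species instantly displaces the inferior
one on encounter.  The site-frequency dynamics are

    dp_i/dt = q f_i p_i (1 - sum_{j<=i} p_j)
              - q (sum_{j<i} f_j p_j) p_i - m p_i .

The equilibrium admits a forward recursion (each ``p_i`` depends only on
species that outcompete it), and in the continuum limit an analytic density
``p(x) = (1/2) f'(x) f(x)^(-3/2) sqrt(m/q)`` on ``[x_c, x_hat]`` with the
critical inferiority ``x_c`` solving ``f(x_c) = m/q``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "TradeOff",
    "CommunitySpec",
    "EquilibriumCommunity",
    "ContinuousEquilibrium",
    "DomainError",
    "ParameterError",
    "StateError",
    "NoViableSpeciesError",
    "DEFAULT_SEED",
    "evaluate_tradeoff",
    "make_positions",
    "solve_equilibrium",
    "dynamics_rhs",
    "integrate_to_steady_state",
    "critical_inferiority",
    "continuous_density",
    "interval_frequency",
    "gap_variant",
]

#: Default seed for stochastic fixtures (date-derived, arbitrary).
DEFAULT_SEED = 20210316

#: Survival guard: recursion values at or below this are treated as exactly 0.
_ZERO_GUARD = 1e-15

#: Finite-difference step for derivatives of user-supplied trade-offs.
_FD_STEP = 1e-6


class DomainError(ValueError):
    """Argument outside the trade-off or density domain."""


class ParameterError(ValueError):
    """Invalid model parameter."""


class StateError(ValueError):
    """Frequency vector outside the simplex."""


class NoViableSpeciesError(ValueError):
    """No inferiority value satisfies f(x) > m/q: the community is empty."""


# ---------------------------------------------------------------------------
# Trade-off
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TradeOff:
    """Monotone increasing fecundity ``f(x)`` on ``[0, x_hat]``.

    Construct through the family classmethods (:meth:`linear`,
    :meth:`saturating`, :meth:`convex`, :meth:`sigmoid`) or wrap an arbitrary
    callable with :meth:`from_callable`.  ``f`` must be continuous, strictly
    increasing and positive on the domain; this is spot-checked on a dense
    grid at construction.
    """

    family: str
    params: tuple[float, ...]
    x_hat: float
    _f: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    _df: Callable[[np.ndarray], np.ndarray] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not (self.x_hat > 0):
            raise ParameterError(f"x_hat must be positive, got {self.x_hat}")
        grid = np.linspace(0.0, self.x_hat, 257)
        vals = np.asarray(self._f(grid), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ParameterError("trade-off is not finite on [0, x_hat]")
        if np.any(vals <= 0):
            raise ParameterError("trade-off must be positive on [0, x_hat]")
        if np.any(np.diff(vals) <= 0):
            raise ParameterError("trade-off must be strictly increasing on [0, x_hat]")

    # -- evaluation ---------------------------------------------------------

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x < -1e-12) or np.any(x > self.x_hat + 1e-12):
            raise DomainError(f"x outside [0, {self.x_hat}]")
        out = self._f(np.clip(x, 0.0, self.x_hat))
        return float(out) if np.isscalar(out) or out.ndim == 0 else out

    def derivative(self, x):
        """f'(x); closed form when registered, else central difference."""
        x = np.asarray(x, dtype=float)
        if np.any(x < -1e-12) or np.any(x > self.x_hat + 1e-12):
            raise DomainError(f"x outside [0, {self.x_hat}]")
        x = np.clip(x, 0.0, self.x_hat)
        if self._df is not None:
            out = self._df(x)
        else:
            h = _FD_STEP
            lo = np.clip(x - h, 0.0, self.x_hat)
            hi = np.clip(x + h, 0.0, self.x_hat)
            out = (self._f(hi) - self._f(lo)) / (hi - lo)
        out = np.asarray(out, dtype=float)
        return float(out) if out.ndim == 0 else out

    # -- families -----------------------------------------------------------

    @classmethod
    def linear(cls, a: float = 1.0, b: float = 1.0, x_hat: float = 2.5) -> "TradeOff":
        """f(x) = a + b x."""
        return cls("linear", (a, b), x_hat,
                   _f=lambda x: a + b * x, _df=lambda x: b * np.ones_like(x))

    @classmethod
    def saturating(cls, a: float = 1.0, c: float = 3.0, k: float = 1.0,
                   x_hat: float = 2.5) -> "TradeOff":
        """Concave saturating f(x) = a + c (1 - exp(-k x)); asymptote a + c."""
        return cls("saturating", (a, c, k), x_hat,
                   _f=lambda x: a + c * (1.0 - np.exp(-k * x)),
                   _df=lambda x: c * k * np.exp(-k * x))

    @classmethod
    def convex(cls, a: float = 1.0, b: float = 1.0, gamma: float = 2.0,
               x_hat: float = 2.5) -> "TradeOff":
        """f(x) = a + b x**gamma with gamma > 1 (accelerating fecundity)."""
        if gamma <= 1:
            raise ParameterError("convex family requires gamma > 1")
        return cls("convex", (a, b, gamma), x_hat,
                   _f=lambda x: a + b * np.power(x, gamma),
                   _df=lambda x: b * gamma * np.power(x, gamma - 1.0))

    @classmethod
    def sigmoid(cls, a: float = 1.0, c: float = 3.0, k: float = 4.0,
                x0: float = 1.25, x_hat: float = 2.5) -> "TradeOff":
        """f(x) = a + c / (1 + exp(-k (x - x0)))."""
        def f(x):
            return a + c / (1.0 + np.exp(-k * (x - x0)))

        def df(x):
            s = 1.0 / (1.0 + np.exp(-k * (x - x0)))
            return c * k * s * (1.0 - s)

        return cls("sigmoid", (a, c, k, x0), x_hat, _f=f, _df=df)

    @classmethod
    def from_callable(cls, f: Callable, x_hat: float,
                      derivative: Callable | None = None,
                      params: tuple[float, ...] = ()) -> "TradeOff":
        """Wrap a user-supplied fecundity function (derivative optional)."""
        return cls("user-defined", params, x_hat, _f=f, _df=derivative)

    @classmethod
    def from_config(cls, family: str, params: Mapping[str, float],
                    x_hat: float = 2.5) -> "TradeOff":
        """Build a shipped family from a plain mapping (config-file entry)."""
        family = family.replace("-", "_").lower()
        makers = {
            "linear": cls.linear,
            "saturating": cls.saturating,
            "saturating_concave": cls.saturating,
            "convex": cls.convex,
            "sigmoid": cls.sigmoid,
        }
        if family not in makers:
            raise ParameterError(f"unknown trade-off family {family!r}")
        return makers[family](**dict(params), x_hat=x_hat)


def evaluate_tradeoff(trade_off: TradeOff, x) -> float:
    """Fecundity f(x); raises :class:`DomainError` outside [0, x_hat]."""
    return trade_off(x)


# ---------------------------------------------------------------------------
# Community specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CommunitySpec:
    """A finite community on the competitiveness axis.

    Parameters
    ----------
    positions : array-like
        Strictly increasing competitive inferiorities ``x_1 < ... < x_n``
        within ``[0, x_hat]``.
    m : float
        Colony destruction rate (per time), ``m >= 0``.
    q : float
        Propagule-site encounter rate (per time), ``q > 0``.
    trade_off : TradeOff
        Competition-fecundity trade-off supplying ``f_i = f(x_i)``.
    """

    positions: np.ndarray
    m: float
    q: float
    trade_off: TradeOff

    def __post_init__(self) -> None:
        pos = np.atleast_1d(np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "positions", pos)
        if pos.size < 1:
            raise ParameterError("community needs at least one species")
        if np.any(np.diff(pos) <= 0):
            raise ParameterError("positions must be strictly increasing")
        if pos[0] < -1e-12 or pos[-1] > self.trade_off.x_hat + 1e-12:
            raise ParameterError("positions must lie within [0, x_hat]")
        if self.m < 0:
            raise ParameterError("m must be non-negative")
        if self.q <= 0:
            raise ParameterError("q must be positive")
        f = np.asarray(self.trade_off(pos), dtype=float)
        if np.any(np.diff(f) <= 0):
            raise ParameterError("fecundities must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.positions.size)

    @property
    def fecundities(self) -> np.ndarray:
        return np.atleast_1d(np.asarray(self.trade_off(self.positions), dtype=float))


def make_positions(n: int, x_hat: float, relative_shift: float = 0.0,
                   perturbation: str = "none",
                   seed: int | None = None,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Competitive-inferiority grid for ``n`` species on ``[0, x_hat]``.

    Base positions are even-interval points ``x_i = (i - 1) * x_hat / n``
    shifted by ``relative_shift * (x_hat / n)``.  ``jitter_half_interval``
    adds independent uniform noise on +/- half an interval;
    ``uniform_random`` draws positions uniformly on ``[0, x_hat]``.  Results
    are sorted, clipped to the domain and separated by at least 1e-12.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if not (0.0 <= relative_shift <= 1.0):
        raise ParameterError("relative_shift must lie in [0, 1]")
    if perturbation not in ("none", "jitter_half_interval", "uniform_random"):
        raise ParameterError(f"unknown perturbation mode {perturbation!r}")

    h = x_hat / n
    base = (np.arange(n) + relative_shift) * h
    if perturbation == "none":
        pos = base
    else:
        if rng is None:
            rng = np.random.default_rng(DEFAULT_SEED if seed is None else seed)
        if perturbation == "jitter_half_interval":
            pos = base + rng.uniform(-h / 2.0, h / 2.0, size=n)
        else:  # uniform_random
            pos = rng.uniform(0.0, x_hat, size=n)
    pos = np.sort(np.clip(pos, 0.0, x_hat))
    # enforce strict monotonicity with a minimal separation
    for i in range(1, n):
        if pos[i] <= pos[i - 1]:
            pos[i] = pos[i - 1] + 1e-12
    return pos


# ---------------------------------------------------------------------------
# Discrete equilibrium
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EquilibriumCommunity:
    """Equilibrium site frequencies of a finite community."""

    spec: CommunitySpec
    frequencies: np.ndarray
    converged: bool = True

    @property
    def survivors(self) -> np.ndarray:
        return self.frequencies > 0

    @property
    def empty_fraction(self) -> float:
        return float(1.0 - self.frequencies.sum())


def solve_equilibrium(spec: CommunitySpec) -> EquilibriumCommunity:
    """Forward-recursive equilibrium.

    Proceeding from the strongest competitor,

        p_i = 1 - sum_{j<i} p_j - (1/f_i) (sum_{j<i} f_j p_j + m/q)

    kept when positive and set to zero otherwise (values below 1e-15 are
    zeroed as a floating-point guard).  The first survivor is the first
    species with ``f_i > m/q``; an all-extinct community is a valid result.
    """
    f = spec.fecundities
    ratio = spec.m / spec.q
    p = np.zeros(spec.n)
    cum_p = 0.0
    cum_fp = 0.0
    for i in range(spec.n):
        cand = 1.0 - cum_p - (cum_fp + ratio) / f[i]
        if cand > _ZERO_GUARD:
            p[i] = cand
            cum_p += cand
            cum_fp += f[i] * cand
    return EquilibriumCommunity(spec=spec, frequencies=p)


def dynamics_rhs(spec: CommunitySpec, p: Sequence[float]) -> np.ndarray:
    """Right-hand side dp/dt of the site-frequency dynamics."""
    p = np.asarray(p, dtype=float)
    if p.shape != (spec.n,):
        raise StateError(f"p must have shape ({spec.n},)")
    if np.any(p < -1e-12):
        raise StateError("negative frequency")
    if p.sum() > 1.0 + 1e-9:
        raise StateError("frequencies sum beyond 1")
    return _rhs(p, spec.fecundities, spec.m, spec.q)


def _rhs(p: np.ndarray, f: np.ndarray, m: float, q: float) -> np.ndarray:
    occ_incl = np.cumsum(p)                     # sum_{j<=i} p_j
    fp = f * p
    sup = np.concatenate(([0.0], np.cumsum(fp)[:-1]))  # sum_{j<i} f_j p_j
    return q * f * p * (1.0 - occ_incl) - q * sup * p - m * p


def _per_capita_growth(p: np.ndarray, f: np.ndarray, m: float,
                       q: float) -> np.ndarray:
    """Per-capita rate lambda_i = q f_i (1 - sum_{j<=i} p_j)
    - q sum_{j<i} f_j p_j - m (the invasion fitness at state p)."""
    fp = f * p
    sup = np.concatenate(([0.0], np.cumsum(fp)[:-1]))
    return q * f * (1.0 - np.cumsum(p)) - q * sup - m


def integrate_to_steady_state(spec: CommunitySpec,
                              p0: Sequence[float] | None = None,
                              tol: float = 1e-12,
                              t_max: float = 1e7) -> EquilibriumCommunity:
    """Integrate the dynamics to a steady state with an adaptive stiff solver.

    Starts from uniform ``p0 = 1e-3`` by default and integrates on doubling
    horizons (LSODA, rtol 1e-12 / atol 1e-14).  A state counts as steady
    only when ``max |dp/dt| < tol`` *and* no near-zero species has positive
    per-capita growth: species with tiny positive equilibria can transiently
    crash to numerical zero, where the raw rate criterion alone would
    declare convergence long before they regrow.  A run that exhausts
    ``t_max`` is returned with ``converged=False`` rather than raising.
    """
    f = spec.fecundities
    if p0 is None:
        p0 = np.full(spec.n, 1e-3)
    p0 = np.asarray(p0, dtype=float)
    if np.any(p0 <= 0):
        raise StateError("initial frequencies must be positive")
    if p0.sum() > 1.0 + 1e-9:
        raise StateError("initial frequencies sum beyond 1")

    def rhs(_t, p):
        return _rhs(p, f, spec.m, spec.q)

    floor = 1e-14  # solver atol: crashed species stay resolvable
    t0, horizon = 0.0, 100.0
    p = p0
    while t0 < t_max:
        sol = solve_ivp(rhs, (t0, min(t0 + horizon, t_max)), p, method="LSODA",
                        rtol=1e-12, atol=1e-14)
        # keep crashed species at a positive floor so they can re-invade
        p = np.where(sol.y[:, -1] > floor, sol.y[:, -1], floor)
        t0 = sol.t[-1]
        rate = _rhs(p, f, spec.m, spec.q)
        lam = _per_capita_growth(p, f, spec.m, spec.q)
        # a rare species still below its equilibrium has lam > 0 but a rate
        # lam * p that can sit under tol; it must keep integrating
        invading = (p < 1e-6) & (lam > 1e-9)
        dying = (p <= 10 * floor) & ~invading
        settled = np.where(dying, 0.0, np.abs(rate)).max() < tol
        if settled and not invading.any():
            return EquilibriumCommunity(
                spec=spec, frequencies=np.where(dying, 0.0, p),
                converged=True)
        horizon *= 2.0
    return EquilibriumCommunity(spec=spec, frequencies=p, converged=False)


def gap_variant(spec: CommunitySpec, g: float) -> CommunitySpec:
    """Forest-gap variant: gaps open at rate ``g``, so ``q`` becomes ``q g``.

    The gap dynamics have the same structure as the base model with the
    effective encounter rate ``q' = q g``; every downstream operation applies
    unchanged.
    """
    if g <= 0:
        raise ParameterError("gap formation rate g must be positive")
    return replace(spec, q=spec.q * g)


# ---------------------------------------------------------------------------
# Continuous-competitiveness equilibrium
# ---------------------------------------------------------------------------

def critical_inferiority(trade_off: TradeOff, m: float, q: float) -> float:
    """Root ``x_c`` of ``f(x) = m/q`` on ``[0, x_hat]``, clamped at 0.

    Bisection to absolute tolerance 1e-10 (robust for non-differentiable
    user trade-offs).  Raises :class:`NoViableSpeciesError` when even the
    most fecund species cannot persist (``f(x_hat) <= m/q``).
    """
    if q <= 0:
        raise ParameterError("q must be positive")
    ratio = m / q
    if trade_off(0.0) >= ratio:
        return 0.0
    if trade_off(trade_off.x_hat) <= ratio:
        raise NoViableSpeciesError(
            f"f(x_hat) = {trade_off(trade_off.x_hat):g} <= m/q = {ratio:g}")
    lo, hi = 0.0, trade_off.x_hat
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        if trade_off(mid) < ratio:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class ContinuousEquilibrium:
    """Analytic equilibrium density in the continuum (n -> infinity) limit."""

    trade_off: TradeOff
    m: float
    q: float
    x_c: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "x_c", critical_inferiority(self.trade_off, self.m, self.q))

    @property
    def total_frequency(self) -> float:
        """Total occupied-site fraction over [x_c, x_hat].

        Equals ``(f(x_c)^(-1/2) - f(x_hat)^(-1/2)) sqrt(m/q)``, which
        telescopes to the closed form ``1 - sqrt((m/q)/f(x_hat))`` whenever
        the critical inferiority is an interior root (``f(x_c) = m/q``); a
        clamped ``x_c = 0`` with ``f(0) > m/q`` gives a smaller total.
        """
        return interval_frequency(self, self.x_c,
                                  self.trade_off.x_hat - self.x_c)

    def density(self, x):
        return continuous_density(self, x)

    def interval_frequency(self, x: float, dx: float) -> float:
        return interval_frequency(self, x, dx)


def continuous_density(ce: ContinuousEquilibrium, x):
    """Equilibrium density p(x) = (1/2) f'(x) f(x)^(-3/2) sqrt(m/q)."""
    xa = np.asarray(x, dtype=float)
    if np.any(xa < ce.x_c - 1e-9) or np.any(xa > ce.trade_off.x_hat + 1e-9):
        raise DomainError(f"x outside [{ce.x_c}, {ce.trade_off.x_hat}]")
    fx = np.asarray(ce.trade_off(xa), dtype=float)
    dfx = np.asarray(ce.trade_off.derivative(xa), dtype=float)
    out = 0.5 * dfx * np.power(fx, -1.5) * math.sqrt(ce.m / ce.q)
    return float(out) if out.ndim == 0 else out


def interval_frequency(ce: ContinuousEquilibrium, x: float, dx: float) -> float:
    """Frequency mass on [x, x+dx]: (f(x)^(-1/2) - f(x+dx)^(-1/2)) sqrt(m/q)."""
    if dx < 0:
        raise DomainError("dx must be non-negative")
    if x < ce.x_c - 1e-9 or x + dx > ce.trade_off.x_hat + 1e-9:
        raise DomainError(f"interval outside [{ce.x_c}, {ce.trade_off.x_hat}]")
    fa = ce.trade_off(max(x, 0.0))
    fb = ce.trade_off(min(x + dx, ce.trade_off.x_hat))
    return (fa ** -0.5 - fb ** -0.5) * math.sqrt(ce.m / ce.q)
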