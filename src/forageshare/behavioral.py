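"""Spatially implicit behavioral-state model of social foraging.

A population of ``N`` predators forages on a patchy landscape. Each predator
is, at any moment, in one of four behavioral states:

``s``
    searching alone for a prey patch,
``h``
    harvesting (consuming) a patch it found itself,
``m``
    moving toward a patch whose location another predator broadcast,
``b``
    bound: co-feeding at the caller's patch.

Space enters only through three timescales -- the lone-predator first-passage
(search) time ``tau_s``, the lone-predator patch handling time ``tau_h`` and
the landscape change (patch lifetime) timescale ``tau_l`` -- plus the expected
travel time between predators ``tau_d``. Social behavior enters through the
group size ``N`` and the communication propensity ``lambda`` in [0, 1]: the
probability that a patch discovery is broadcast along a social tie.

At stationarity the fluxes between the states balance, which reduces to a
single scalar equation for ``s``. Foraging efficiency -- consumption rate
``H`` relative to its upper bound ``H*`` -- is the total fraction of time
spent feeding, ``h + b``. With no communication this collapses to the
classical Type II functional response ``1 / (1 + tau_s / tau_h)``.

The only carrier of spatial/temporal correlation between predators is
``n_p``, the expected number of predators consuming the same patch. It is
closed with a blended estimator that reproduces the two analytically known
limits (``n_p -> N`` for full sharing, ``n_p -> 1 + b/h`` for rare sharing)
and is solved self-consistently with the state occupancies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "Timescales",
    "SocialConfig",
    "StateOccupancy",
    "TransitionRates",
    "FunctionalResponse",
    "InvalidParameterError",
    "DegenerateStateError",
    "SolverFailureError",
    "single_predator_response",
    "transition_rates",
    "occupancy_np",
    "solve_steady_state",
    "functional_response",
    "group_partition_response",
]


class InvalidParameterError(ValueError):
    """A model parameter violates its domain constraint."""


class DegenerateStateError(ValueError):
    """A state combination for which the requested quantity is undefined."""


class SolverFailureError(RuntimeError):
    """The steady-state solver could not locate a valid root."""


def _check_positive(name: str, value: float, allow_inf: bool = False) -> None:
    if not (value > 0):
        raise InvalidParameterError(f"{name} must be strictly positive, got {value!r}")
    if math.isinf(value) and not allow_inf:
        raise InvalidParameterError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class Timescales:
    """The key timescales that interface spatial detail with the state model.

    Parameters
    ----------
    tau_s
        Expected lone-search first-passage time (time units).
    tau_h
        Lone-predator patch handling time: expected time for one predator to
        consume an entire patch (time units).
    tau_l
        Landscape change timescale: expected patch lifetime at a location.
        May be ``inf`` for an immobile landscape.
    tau_d
        Expected travel time to a calling predator. Defaults to 1, i.e. all
        other timescales are measured in units of the travel time.
    """

    tau_s: float
    tau_h: float
    tau_l: float = math.inf
    tau_d: float = 1.0

    def __post_init__(self) -> None:
        _check_positive("tau_s", self.tau_s)
        _check_positive("tau_h", self.tau_h)
        _check_positive("tau_l", self.tau_l, allow_inf=True)
        _check_positive("tau_d", self.tau_d)

    @property
    def landscape_hazard(self) -> float:
        """Patch loss rate from landscape change, ``1/tau_l`` (0 if immobile)."""
        return 0.0 if math.isinf(self.tau_l) else 1.0 / self.tau_l


@dataclass(frozen=True)
class SocialConfig:
    """Group size and communication propensity.

    ``lam`` is the probability that a discovery is broadcast across a social
    tie; ``n_predators`` is the number of predators within communication
    range of each other.
    """

    n_predators: int
    lam: float

    def __post_init__(self) -> None:
        if int(self.n_predators) != self.n_predators or self.n_predators < 1:
            raise InvalidParameterError(
                f"n_predators must be an integer >= 1, got {self.n_predators!r}"
            )
        if not (0.0 <= self.lam <= 1.0):
            raise InvalidParameterError(f"lam must lie in [0, 1], got {self.lam!r}")


@dataclass(frozen=True)
class StateOccupancy:
    """Stationary population fractions and derived quantities.

    ``s + h + m + b = 1`` up to solver tolerance; ``n_p`` is the expected
    number of co-feeders on an occupied patch and ``W_L`` the common rate at
    which feeding or travelling predators revert to lone search.
    """

    s: float
    h: float
    m: float
    b: float
    n_p: float
    W_L: float

    def as_dict(self) -> dict[str, float]:
        return {"s": self.s, "h": self.h, "m": self.m, "b": self.b,
                "n_p": self.n_p, "W_L": self.W_L}


@dataclass(frozen=True)
class TransitionRates:
    """Per-capita fluxes between behavioral states (1/time)."""

    w_sh: float
    w_sm: float
    w_mb: float
    w_loss: float


@dataclass(frozen=True)
class FunctionalResponse:
    """Generalized functional response: efficiency ``H/H* = h + b``."""

    efficiency: float
    occupancy: StateOccupancy
    timescales: Timescales
    social: SocialConfig
    diagnostics: dict = field(default_factory=dict)

    def to_record(self) -> dict[str, float]:
        """Flat record suitable for CSV/JSON serialization."""
        ts, sc, occ = self.timescales, self.social, self.occupancy
        return {
            "tau_s": ts.tau_s, "tau_h": ts.tau_h, "tau_l": ts.tau_l,
            "tau_d": ts.tau_d, "N": sc.n_predators, "lambda": sc.lam,
            "s": occ.s, "h": occ.h, "m": occ.m, "b": occ.b,
            "n_p": occ.n_p, "W_L": occ.W_L, "efficiency": self.efficiency,
        }


def single_predator_response(tau_s: float, tau_h: float) -> float:
    """Type II functional response of an independent predator.

    With only two states (search/harvest), flux balance ``s/tau_s = h/tau_h``
    and ``s + h = 1`` give the fraction of time spent feeding

    ``H/H* = 1 / (1 + tau_s / tau_h)``.
    """
    _check_positive("tau_s", tau_s)
    _check_positive("tau_h", tau_h)
    return 1.0 / (1.0 + tau_s / tau_h)


def transition_rates(
    ts: Timescales, sc: SocialConfig, s: float, n_p: float
) -> TransitionRates:
    """Per-capita state transition rates at searcher fraction ``s``.

    * ``w_sh = 1/tau_s``: lone searchers find patches at the inverse search
      time.
    * ``w_sm = N * lam * s * w_sh``: calls arrive in proportion to the number
      of searchers about to discover, times the tie strength.
    * ``w_mb = 1/tau_d``: travelling predators reach their caller at the
      inverse expected travel time.
    * ``w_loss = 1/tau_l + n_p/tau_h``: a patch is lost either because it
      moved (Poisson hazard ``1/tau_l``) or because ``n_p`` co-feeders
      depleted it (hazard ``n_p/tau_h``); the combined hazard is the sum.
    """
    if not (0.0 <= s <= 1.0):
        raise InvalidParameterError(f"s must lie in [0, 1], got {s!r}")
    if n_p < 1.0:
        raise InvalidParameterError(f"n_p must be >= 1, got {n_p!r}")
    w_sh = 1.0 / ts.tau_s
    w_sm = sc.n_predators * sc.lam * s * w_sh
    w_mb = 1.0 / ts.tau_d
    w_loss = ts.landscape_hazard + n_p / ts.tau_h
    return TransitionRates(w_sh=w_sh, w_sm=w_sm, w_mb=w_mb, w_loss=w_loss)


def occupancy_np(sc: SocialConfig, b: float, h: float) -> float:
    """Blended estimator of the expected number of co-feeders per patch.

    The two analytically known limits are ``n_p -> N`` when every discovery
    is broadcast (``lam -> 1``: the group moves as one pack) and
    ``n_p -> 1 + b/h`` when sharing is rare (``lam << 1``: the finder plus
    the time-averaged ratio of bound to harvesting predators). The default
    closure interpolates linearly in ``lam``::

        n_p = (1 - lam) * (1 + b / h) + lam * N

    clipped to ``[1, N]``.
    """
    n, lam = sc.n_predators, sc.lam
    if b < 0:
        raise InvalidParameterError(f"b must be >= 0, got {b!r}")
    if lam >= 1.0:
        return float(n)
    if h <= 0.0:
        raise DegenerateStateError(
            "n_p is undefined for h = 0 with lam < 1: no self-found feeding"
        )
    raw = (1.0 - lam) * (1.0 + b / h) + lam * n
    return float(min(max(raw, 1.0), float(n)))


# ---------------------------------------------------------------------------
# steady state


def _coupling(sc: SocialConfig) -> float:
    # Communication requires a partner: a single predator cannot receive a
    # call, so the N*lam coupling of the mean-field rate is suppressed at N=1.
    return sc.n_predators * sc.lam if sc.n_predators > 1 else 0.0


def _np_self_consistent(ts: Timescales, sc: SocialConfig, s):
    """Co-feeder count n_p solving n = (1-lam)(1 + b/h) + lam*N at fixed s.

    From the balance equations, ``b/h = C*s / (1 + tau_d * W_L)`` with
    ``C = N*lam`` and ``W_L = 1/tau_l + n_p/tau_h``, so the closure is a
    quadratic in ``n_p``; we take its positive root and clip to [1, N].
    Accepts scalar or ndarray ``s``.
    """
    n, lam = sc.n_predators, sc.lam
    c = _coupling(sc)
    if lam >= 1.0 or n == 1:
        return np.full_like(np.asarray(s, dtype=float), float(n)) if np.ndim(s) else float(n)
    base = (1.0 - lam) + lam * n          # value of n_p when b/h = 0
    a_coef = 1.0 + ts.tau_d * ts.landscape_hazard
    b_coef = ts.tau_d / ts.tau_h
    # n*(A + B*n) = base*(A + B*n) + (1-lam)*C*s
    beta = a_coef - b_coef * base
    gamma = a_coef * base + (1.0 - lam) * c * np.asarray(s, dtype=float)
    root = (-beta + np.sqrt(beta * beta + 4.0 * b_coef * gamma)) / (2.0 * b_coef)
    return np.clip(root, 1.0, float(n))


def _residual(ts: Timescales, sc: SocialConfig, s):
    """Residual of the scalar steady-state equation over the searcher fraction.

    ``(C*s^2 + s)/tau_s - (1 - s)*W_L(s)`` with ``C = N*lam`` (0 for N=1);
    its root in (0, 1] is the stationary ``s``. Vectorized over ``s``.
    """
    s = np.asarray(s, dtype=float)
    n_p = _np_self_consistent(ts, sc, s)
    w_l = ts.landscape_hazard + n_p / ts.tau_h
    return (_coupling(sc) * s * s + s) / ts.tau_s - (1.0 - s) * w_l


def _occupancy_at(ts: Timescales, sc: SocialConfig, s: float) -> StateOccupancy:
    c = _coupling(sc)
    n_p = float(_np_self_consistent(ts, sc, s))
    w_l = ts.landscape_hazard + n_p / ts.tau_h
    h = (s / ts.tau_s) / w_l
    m = (c * s * s / ts.tau_s) / (w_l + 1.0 / ts.tau_d)
    b = m / (ts.tau_d * w_l)
    return StateOccupancy(s=float(s), h=h, m=m, b=b, n_p=n_p, W_L=w_l)


def solve_steady_state(
    ts: Timescales,
    sc: SocialConfig,
    tol: float = 1e-10,
    n_brackets: int = 512,
) -> StateOccupancy:
    """Solve the stationary behavioral-state distribution.

    The four balance equations reduce to one scalar equation for the
    searching fraction ``s``; its residual is negative as ``s -> 0`` and
    positive at ``s = 1``, so a root always exists in (0, 1]. We bracket sign
    changes on a uniform grid and polish with Brent's method. If the residual
    has several roots, the one with the largest ``s`` is returned with a
    warning.

    Raises
    ------
    SolverFailureError
        If no sign change is found (never for valid parameters) or the
        returned state violates normalization.
    """
    lo = 1e-9
    grid = np.linspace(lo, 1.0, n_brackets)
    res = _residual(ts, sc, grid)
    sign_change = np.nonzero(np.sign(res[:-1]) * np.sign(res[1:]) < 0)[0]
    exact = np.nonzero(res == 0.0)[0]
    roots = [float(grid[i]) for i in exact]
    f = lambda x: float(_residual(ts, sc, x))
    for i in sign_change:
        roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-15, rtol=8.9e-16))
    if not roots:
        raise SolverFailureError(
            f"no steady-state root in (0, 1] for {ts!r}, {sc!r}"
        )
    if len(roots) > 1:
        warnings.warn(
            f"multiple steady-state roots {sorted(roots)}; returning the "
            "largest searcher fraction",
            RuntimeWarning,
            stacklevel=2,
        )
    occ = _occupancy_at(ts, sc, max(roots))
    total = occ.s + occ.h + occ.m + occ.b
    if abs(total - 1.0) > max(1e-7, tol * 100):
        raise SolverFailureError(
            f"steady state violates normalization: s+h+m+b = {total!r}"
        )
    return occ


def functional_response(
    ts: Timescales, sc: SocialConfig, debug: bool = False
) -> FunctionalResponse:
    """Generalized functional response ``H/H* = h + b`` at steady state.

    ``h + b`` is the total fraction of time spent consuming prey, whether at
    a self-found patch or at a caller's patch. For ``lam = 0`` and an
    immobile landscape this reduces exactly to the Type II response.

    With ``debug=True`` the diagnostics also carry the closed-form printed
    expression ``(1/tau_s + lam*N*s/(1 + tau_d*W_L)) * s / W_L``, which
    differs from the flux-balance value by a ``1/tau_s`` factor in its
    second term; the flux-balance value is the one reported.
    """
    occ = solve_steady_state(ts, sc)
    eff = occ.h + occ.b
    eff = min(max(eff, 0.0), 1.0)
    diagnostics: dict = {}
    if debug:
        closed = (
            (1.0 / ts.tau_s)
            + sc.lam * sc.n_predators * occ.s / (1.0 + ts.tau_d * occ.W_L)
        ) * occ.s / occ.W_L
        diagnostics["efficiency_flux_balance"] = occ.h + occ.b
        diagnostics["efficiency_printed_form"] = closed
    return FunctionalResponse(
        efficiency=eff, occupancy=occ, timescales=ts, social=sc,
        diagnostics=diagnostics,
    )


def group_partition_response(
    ts: Timescales, total_n: int, partition: list[int]
) -> list[float]:
    """Per-predator efficiency for each group of a partition of the population.

    ``total_n`` predators are arranged into non-interacting groups; within a
    group all information is shared (``lam = 1``), between groups none. A
    member of a size-``k`` group therefore forages at the efficiency of a
    fully communicating group of ``k``; a group of one forages at the lone
    (``lam = 0``) efficiency. Returns one efficiency per group, aligned with
    ``partition``.
    """
    sizes = [int(k) for k in partition]
    if sizes != list(partition) or any(k < 1 for k in sizes):
        raise InvalidParameterError(f"group sizes must be integers >= 1: {partition!r}")
    if sum(sizes) != total_n:
        raise InvalidParameterError(
            f"partition {partition!r} does not sum to total_n={total_n}"
        )
    cache: dict[int, float] = {}
    out = []
    for k in sizes:
        if k not in cache:
            lam = 0.0 if k == 1 else 1.0
            cache[k] = functional_response(ts, SocialConfig(k, lam)).efficiency
        out.append(cache[k])
    return out
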