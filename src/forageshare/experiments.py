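"""Experiment drivers: functional-response surfaces, value-of-information
maps, and optimal-group-size analyses.

Three result sets couple the analytic behavioral-state model and the
agent-based simulator:

* **Sweeps / value of information** -- the three key timescales are explored
  two at a time, normalized by the third (e.g. ``tau_h/tau_s`` against
  ``tau_l/tau_s``). For a two-predator system the *value of information* in
  an environment is the fractional change of consumption rate between full
  sharing and no sharing, ``(H(lam=1) - H(lam=0)) / H(lam=0)``; its zero
  contour separates environments where sharing pays from those where it
  costs.
* **Group size** -- with a fixed population (default 30) partitioned into
  all-sharing groups, a member's expected efficiency as a function of its
  group size can be concave (an interior optimal group size) or convex
  (being alone and the full super-group both beat intermediate sizes); the
  mean curvature of the curve summarizes which regime an environment is in.
* **ABM validation** -- drivers that measure the simulator's timescales,
  run matched simulations and compare measured efficiencies with the
  analytic prediction.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from forageshare import abm
from forageshare.behavioral import (
    InvalidParameterError,
    SocialConfig,
    SolverFailureError,
    Timescales,
    functional_response,
)

__all__ = [
    "SweepGrid",
    "VoiMap",
    "GroupSizeCurve",
    "GroupSizeMap",
    "voi_map",
    "group_size_curve",
    "curvature",
    "optimal_group_size_map",
    "validation_base_config",
    "single_predator_validation",
    "sharing_validation",
]

_AXES = ("tau_s", "tau_h", "tau_l")


@dataclass(frozen=True)
class SweepGrid:
    """Log-spaced grid of two normalized timescale ratios.

    ``axis1`` and ``axis2`` name the swept timescales; the remaining one is
    the normalizer, held constant at ``normalizer_value`` in units of the
    inter-predator travel time ``tau_d`` (the swept values are the ratios to
    the normalizer). The default of 5 travel times reflects the simulator's
    regime, where crossing to a caller is substantially faster than finding
    a patch unaided; with the normalizer equal to ``tau_d`` a called
    predator gains nothing over searching and the social structure of the
    maps degenerates. Default bounds span four decades around unity.
    """

    axis1: str = "tau_h"
    axis2: str = "tau_l"
    log10_min: float = -2.0
    log10_max: float = 2.0
    resolution: int = 41
    normalizer_value: float = 5.0
    tau_d: float = 1.0

    def __post_init__(self) -> None:
        if self.axis1 not in _AXES or self.axis2 not in _AXES or self.axis1 == self.axis2:
            raise InvalidParameterError(
                f"axes must be two distinct of {_AXES}, got {self.axis1!r}, {self.axis2!r}"
            )
        if not (self.log10_max > self.log10_min):
            raise InvalidParameterError("log10_max must exceed log10_min")
        if self.resolution < 2:
            raise InvalidParameterError("resolution must be >= 2")
        if self.normalizer_value <= 0 or self.tau_d <= 0:
            raise InvalidParameterError("normalizer_value and tau_d must be positive")

    @property
    def normalizer(self) -> str:
        return next(a for a in _AXES if a not in (self.axis1, self.axis2))

    def ratios(self) -> tuple[np.ndarray, np.ndarray]:
        r = np.logspace(self.log10_min, self.log10_max, self.resolution)
        return r, r.copy()

    def timescales(self, ratio1: float, ratio2: float) -> Timescales:
        """Timescales for one cell (in travel-time units)."""
        v = self.normalizer_value
        values = {self.normalizer: v, self.axis1: float(ratio1) * v,
                  self.axis2: float(ratio2) * v}
        return Timescales(tau_s=values["tau_s"], tau_h=values["tau_h"],
                          tau_l=values["tau_l"], tau_d=self.tau_d)


@dataclass(frozen=True)
class VoiMap:
    """Fractional change of consumption rate, full vs no information sharing.

    ``values[i, j]`` corresponds to ``axis1`` ratio ``i`` and ``axis2`` ratio
    ``j``; masked cells had an undefined fractional change (zero no-sharing
    consumption). ``zero_contour`` flags cells adjacent to a sign change.
    """

    grid: SweepGrid
    values: np.ndarray
    efficiency_lam0: np.ndarray
    efficiency_lam1: np.ndarray
    mask: np.ndarray
    se: np.ndarray | None = None

    @property
    def zero_contour(self) -> np.ndarray:
        sgn = np.sign(self.values)
        flag = np.zeros_like(sgn, dtype=bool)
        flag[:-1, :] |= sgn[:-1, :] * sgn[1:, :] < 0
        flag[1:, :] |= sgn[:-1, :] * sgn[1:, :] < 0
        flag[:, :-1] |= sgn[:, :-1] * sgn[:, 1:] < 0
        flag[:, 1:] |= sgn[:, :-1] * sgn[:, 1:] < 0
        return flag & ~self.mask

    def to_frame(self) -> pd.DataFrame:
        r1, r2 = self.grid.ratios()
        i, j = np.meshgrid(np.arange(len(r1)), np.arange(len(r2)), indexing="ij")
        return pd.DataFrame({
            self.grid.axis1 + "_ratio": r1[i.ravel()],
            self.grid.axis2 + "_ratio": r2[j.ravel()],
            "efficiency_lambda0": self.efficiency_lam0.ravel(),
            "efficiency_lambda1": self.efficiency_lam1.ravel(),
            "fractional_change": self.values.ravel(),
            "masked": self.mask.ravel(),
        })


def voi_map(
    grid: SweepGrid,
    engine: str = "analytic",
    n_predators: int = 2,
    base_config: "abm.AbmConfig | None" = None,
    n_replicates: int = 30,
    rng: np.random.Generator | None = None,
) -> VoiMap:
    """Map the value of information sharing over an environment grid.

    Per cell the efficiency is computed at ``lam = 0`` and ``lam = 1`` with
    the chosen engine and the fractional change recorded. The analytic
    engine is exact per cell; the ABM engine runs matched simulations (see
    ``sharing_validation``) and attaches standard errors. Cells with zero
    no-sharing consumption are masked.
    """
    if engine not in ("analytic", "abm"):
        raise InvalidParameterError(f"unknown engine {engine!r}")
    r1, r2 = grid.ratios()
    n1, n2 = len(r1), len(r2)
    e0 = np.full((n1, n2), np.nan)
    e1 = np.full((n1, n2), np.nan)
    se = np.full((n1, n2), np.nan) if engine == "abm" else None
    if engine == "analytic":
        for i, a in enumerate(r1):
            for j, b in enumerate(r2):
                ts = grid.timescales(a, b)
                e0[i, j] = functional_response(ts, SocialConfig(n_predators, 0.0)).efficiency
                e1[i, j] = functional_response(ts, SocialConfig(n_predators, 1.0)).efficiency
    else:
        df = sharing_validation(
            base_config=base_config,
            ratios_h=r1 if grid.axis1 == "tau_h" else r2,
            ratios_l=r1 if grid.axis1 == "tau_l" else r2,
            n_replicates=n_replicates,
            rng=rng,
        )
        for _, row in df.iterrows():
            key = {"tau_h": row["ratio_h"], "tau_l": row["ratio_l"]}
            i = int(np.argmin(np.abs(r1 - key[grid.axis1])))
            j = int(np.argmin(np.abs(r2 - key[grid.axis2])))
            if row["lam"] == 0.0:
                e0[i, j] = row["efficiency_abm"]
            else:
                e1[i, j] = row["efficiency_abm"]
                se[i, j] = row["efficiency_se"]
    mask = ~(e0 > 0)
    if mask.any():
        warnings.warn(
            f"{int(mask.sum())} cells masked: no-sharing consumption is zero",
            RuntimeWarning,
            stacklevel=2,
        )
    values = np.where(mask, np.nan, (e1 - e0) / np.where(mask, 1.0, e0))
    return VoiMap(grid=grid, values=values, efficiency_lam0=e0,
                  efficiency_lam1=e1, mask=mask, se=se)


# ---------------------------------------------------------------------------
# group size


@dataclass(frozen=True)
class GroupSizeCurve:
    """Per-member efficiency against all-sharing group size 1..N.

    A member of a size-``k`` group has ``k - 1`` social ties; the size-1
    point is the lone (no sharing) efficiency. ``optimum`` is the smallest
    size attaining the maximal efficiency; ``curvature`` the mean pointwise
    curvature of the curve (positive = convex).
    """

    sizes: np.ndarray
    efficiency: np.ndarray
    curvature: float
    optimum: int

    def interior_optimum(self) -> bool:
        return 1 < self.optimum < int(self.sizes[-1])


def group_size_curve(ts: Timescales, n_total: int = 30) -> GroupSizeCurve:
    """Efficiency of a member of a size-k all-sharing group, k = 1..n_total.

    Groups are non-interacting (patch replacement keeps coverage constant),
    so a member's efficiency depends only on its own group size; scanning k
    is equivalent to averaging over random partitions. Ties for the optimum
    go to the smallest size.
    """
    if n_total < 2:
        raise InvalidParameterError("n_total must be >= 2")
    sizes = np.arange(1, n_total + 1)
    eff = np.full(n_total, np.nan)
    for idx, k in enumerate(sizes):
        lam = 0.0 if k == 1 else 1.0
        try:
            eff[idx] = functional_response(ts, SocialConfig(int(k), lam)).efficiency
        except SolverFailureError:
            warnings.warn(f"steady state failed at group size {k}; point masked",
                          RuntimeWarning, stacklevel=2)
    valid = ~np.isnan(eff)
    optimum = int(sizes[valid][np.argmax(eff[valid])])
    curv = curvature(np.column_stack([sizes[valid], eff[valid]]))
    return GroupSizeCurve(sizes=sizes, efficiency=eff, curvature=curv, optimum=optimum)


def curvature(curve) -> float:
    """Mean pointwise curvature of a sampled curve y(x).

    Uses central finite differences on the (uniform) sample grid: the mean
    over interior points of ``y'' / (1 + y'^2)^1.5``. Positive values mean a
    convex relationship, negative a concave one.
    """
    pts = np.asarray(list(curve), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise InvalidParameterError("curvature needs >= 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    hsteps = np.diff(x)
    if not np.allclose(hsteps, hsteps[0]):
        raise InvalidParameterError("curvature expects a uniformly spaced grid")
    h = hsteps[0]
    d1 = (y[2:] - y[:-2]) / (2 * h)
    d2 = (y[2:] - 2 * y[1:-1] + y[:-2]) / (h * h)
    return float(np.mean(d2 / (1.0 + d1 * d1) ** 1.5))


@dataclass(frozen=True)
class GroupSizeMap:
    """Optimal group size and curve curvature over an environment grid."""

    grid: SweepGrid
    n_total: int
    optimum: np.ndarray
    curvature: np.ndarray
    supergroup: np.ndarray  # cells where the full group is optimal

    def to_frame(self) -> pd.DataFrame:
        r1, r2 = self.grid.ratios()
        i, j = np.meshgrid(np.arange(len(r1)), np.arange(len(r2)), indexing="ij")
        return pd.DataFrame({
            self.grid.axis1 + "_ratio": r1[i.ravel()],
            self.grid.axis2 + "_ratio": r2[j.ravel()],
            "optimum": self.optimum.ravel(),
            "curvature": self.curvature.ravel(),
            "supergroup": self.supergroup.ravel(),
        })


def optimal_group_size_map(grid: SweepGrid, n_total: int = 30) -> GroupSizeMap:
    """Optimal group size and curvature per environment cell.

    Cells where the full population (``k = n_total``) is optimal are flagged
    as the super-group regime.
    """
    r1, r2 = grid.ratios()
    opt = np.zeros((len(r1), len(r2)), dtype=int)
    curv = np.full((len(r1), len(r2)), np.nan)
    for i, a in enumerate(r1):
        for j, b in enumerate(r2):
            gc = group_size_curve(grid.timescales(a, b), n_total)
            opt[i, j] = gc.optimum
            curv[i, j] = gc.curvature
    return GroupSizeMap(grid=grid, n_total=n_total, optimum=opt,
                        curvature=curv, supergroup=opt == n_total)


# ---------------------------------------------------------------------------
# ABM validation drivers


def validation_base_config(seed: int = 0) -> "abm.AbmConfig":
    """Reference simulator setting used by the validation studies.

    Unit domain, four patches of radius 0.04 (about 2% coverage), unit
    predator speed, dt = 0.01 and per-consumer consumption rate 10; the
    handling time is varied through the prey count per patch so the per-step
    drained fraction stays well resolved, and the search time through the
    sensing radius.
    """
    return abm.AbmConfig(
        domain_size=1.0,
        n_patches=4,
        prey_per_patch=20.0,
        patch_radius=0.04,
        landscape_rate=0.0,
        n_predators=1,
        sensing_radius=0.06,
        speed=1.0,
        consumption_rate=10.0,
        turning_rate=8.0,
        dt=0.01,
        seed=seed,
    )


def _tuned_base(base, rng: np.random.Generator, n_trials: int = 120):
    """Set the turning rate to the empirical tau_s minimizer.

    Candidates are capped at 0.1/dt so per-step turning probabilities stay
    within the discretization guard.
    """
    cap = 0.1 / base.dt
    cands = np.geomspace(1.0, cap, 6) * base.speed / base.domain_size
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r_p = abm.optimize_turning_rate(
            base, candidates=cands, n_trials=n_trials, refine=False,
            rng_seed=int(rng.integers(2**31 - 1)),
        )
    return base.replace(turning_rate=float(r_p))


def single_predator_validation(
    base: "abm.AbmConfig | None" = None,
    sensing_radii: tuple[float, ...] = (0.04, 0.06, 0.09, 0.13, 0.18),
    n_trials: int = 200,
    n_replicates: int = 16,
    sim_time: float = 300.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Single-predator efficiency against the Type II prediction.

    For each sensing radius, the search time is measured empirically
    (``n_trials`` first passages), the turning rate re-optimized, and the
    simulated efficiency on a frozen landscape compared with
    ``1 / (1 + tau_s_hat / tau_h)``. The returned frame carries the z-score
    of the deviation using the combined (simulation + tau_s) standard error.
    """
    if base is None:
        base = validation_base_config()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(base.seed))
    base = base.replace(n_predators=1, landscape_rate=0.0,
                        network=abm.SocialNetwork.full(1, 0.0))
    tau_h = base.prey_per_patch / base.consumption_rate
    rows = []
    for sig in sensing_radii:
        cfg = _tuned_base(base.replace(sensing_radius=float(sig)), rng)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            fpt = abm.first_passage_times(cfg, n_trials, rng=rng)
        tau_s_hat = float(fpt.mean())
        tau_s_se = float(fpt.std(ddof=1) / math.sqrt(len(fpt)))
        n_steps = int(sim_time / cfg.dt)
        metrics = abm.run(cfg.replace(n_steps=n_steps), n_replicates=n_replicates,
                          rng=rng)
        theory = 1.0 / (1.0 + tau_s_hat / tau_h)
        # propagate tau_s uncertainty through the Type II curve
        dtheory = tau_s_se * theory**2 / tau_h
        se = math.hypot(metrics.efficiency_se, dtheory)
        rows.append({
            "sensing_radius": sig,
            "turning_rate": cfg.turning_rate,
            "tau_s_hat": tau_s_hat,
            "tau_s_se": tau_s_se,
            "tau_h": tau_h,
            "efficiency_abm": metrics.efficiency,
            "efficiency_se": metrics.efficiency_se,
            "efficiency_theory": theory,
            "combined_se": se,
            "z": (metrics.efficiency - theory) / se,
            "rel_dev": (metrics.efficiency - theory) / theory,
        })
    return pd.DataFrame(rows)


def sharing_validation(
    base_config: "abm.AbmConfig | None" = None,
    ratios_h: tuple[float, ...] = (0.5, 1.5, 4.5),
    ratios_l: tuple[float, ...] = (0.5, 1.5, 4.5),
    lam_values: tuple[float, ...] = (0.0, 1.0),
    n_predators: int = 2,
    n_replicates: int = 30,
    n_trials: int = 800,
    cycles: float = 60.0,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Two-predator ABM efficiencies against the analytic model, with sharing.

    The environment grid is built in units of the base search time: the
    static-landscape search time ``tau_s0`` is measured once, then each cell
    sets the handling time to ``ratio_h * tau_s0`` (through the prey count
    per patch) and the patch lifetime to ``ratio_l * tau_s0`` (through the
    relocation rate). The analytic prediction for a cell uses that cell's
    own in-environment first-passage time (measured with relocation active,
    consumption disabled), since patch relocation genuinely contributes to
    encounters. One row per (cell, lam) with ABM efficiency, encounter
    rates, the analytic efficiency and their relative deviation.
    """
    if base_config is None:
        base_config = validation_base_config()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(base_config.seed))
    base = _tuned_base(base_config.replace(n_predators=1, landscape_rate=0.0), rng)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est = abm.derived_timescales(base, n_trials=n_trials, rng=rng, detail=True)
    tau_s0 = est.timescales.tau_s
    tau_d = est.timescales.tau_d
    r_q = base.consumption_rate
    rows = []
    for rh in ratios_h:
        for rl in ratios_l:
            n_i = max(2.0, float(round(r_q * rh * tau_s0)))
            tau_h = n_i / r_q
            r_l = 1.0 / (rl * tau_s0)
            cell = base.replace(prey_per_patch=n_i, landscape_rate=r_l)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fpt = abm.first_passage_times(cell, n_trials, rng=rng)
            tau_s_cell = float(fpt.mean())
            ts = Timescales(tau_s=tau_s_cell, tau_h=tau_h, tau_l=1.0 / r_l,
                            tau_d=tau_d)
            n_steps = int(cycles * (tau_s0 + tau_h) / base.dt)
            for lam in lam_values:
                cfg = cell.replace(
                    n_predators=n_predators,
                    network=abm.SocialNetwork.full(n_predators, float(lam)),
                    n_steps=n_steps,
                )
                m = abm.run(cfg, n_replicates=n_replicates, rng=rng)
                ana = functional_response(ts, SocialConfig(n_predators, float(lam)))
                rows.append({
                    "ratio_h": rh, "ratio_l": rl, "lam": lam,
                    "tau_s0": tau_s0, "tau_s_cell": tau_s_cell,
                    "tau_h": tau_h, "tau_l": 1.0 / r_l, "tau_d": tau_d,
                    "efficiency_abm": m.efficiency,
                    "efficiency_se": m.efficiency_se,
                    "efficiency_analytic": ana.efficiency,
                    "rel_dev": (m.efficiency - ana.efficiency) / ana.efficiency,
                    "encounter_rate": m.encounter_rate,
                    "encounter_rate_se": m.encounter_rate_se,
                    "encounter_rate_self": m.encounter_rate_self,
                    "encounter_rate_called": m.encounter_rate_called,
                    "mean_co_feeders": m.mean_co_feeders,
                })
    return pd.DataFrame(rows)


def plot_heatmap(values: np.ndarray, grid: SweepGrid, path, title: str = "",
                 cmap: str = "RdBu_r") -> None:
    """Render a sweep result as a heat map image (diverging around zero)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    vmax = np.nanmax(np.abs(values)) or 1.0
    im = ax.imshow(
        values.T, origin="lower", aspect="auto", cmap=cmap,
        vmin=-vmax, vmax=vmax,
        extent=[grid.log10_min, grid.log10_max, grid.log10_min, grid.log10_max],
    )
    ax.set_xlabel(f"log10({grid.axis1}/{grid.normalizer})")
    ax.set_ylabel(f"log10({grid.axis2}/{grid.normalizer})")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
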