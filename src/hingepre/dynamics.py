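"""Langevin sampling on toy landscapes with accelerated-MD boosting.

The accelerated-MD (aMD) boost flattens basins below a threshold E:

    ΔV(V) = (E − V)² / (α + E − V)        for V < E, else 0,

so the dynamics runs on V* = V + ΔV with forces scaled by
dV*/dV = (α/(α + E − V))².  "Dual boost" applies a secondary boost to a
declared sub-potential (the hinge-angle term here, the torsional term in
all-atom practice) and the total boost on top of the already-boosted sum.
Canonical statistics are recovered by reweighting each visited
configuration with exp(ΔV/k_BT).

The integrator is BAOAB-split underdamped Langevin by default (stable at
moderate timesteps); an overdamped Euler-Maruyama update is available by
flag.  Boosted step counts are never mapped to physical time — the
effective clock of boosted dynamics is non-linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import KB_KCAL, ToyLandscape


@dataclass(frozen=True)
class AMDParameters:
    """Boost thresholds and smoothing (kcal/mol).

    ``e_total``/``alpha_total`` control the boost on the full potential;
    ``e_tors``/``alpha_tors`` (optional) control the secondary boost on the
    declared sub-potential in dual mode.  ``v0_total``/``v0_tors`` record
    the reference average potentials the thresholds were derived from, so
    configs can be written as offsets E − V₀ the way practitioners quote
    them.
    """

    e_total: float
    alpha_total: float
    e_tors: float | None = None
    alpha_tors: float | None = None
    v0_total: float = 0.0
    v0_tors: float = 0.0

    def __post_init__(self):
        if self.alpha_total <= 0:
            raise ValueError("alpha_total must be positive")
        if self.e_tors is not None and (self.alpha_tors is None
                                        or self.alpha_tors <= 0):
            raise ValueError("dual boost requires positive alpha_tors")
        if not np.isfinite(self.e_total):
            raise ValueError("e_total must be finite")

    @classmethod
    def from_offsets(cls, v0_total, e_minus_v0_total, alpha_total,
                     v0_tors=None, e_minus_v0_tors=None, alpha_tors=None):
        """Build from the (V₀, E−V₀, α) triples practitioners report."""
        e_tors = None
        if v0_tors is not None and e_minus_v0_tors is not None:
            e_tors = v0_tors + e_minus_v0_tors
        return cls(e_total=v0_total + e_minus_v0_total,
                   alpha_total=alpha_total, e_tors=e_tors,
                   alpha_tors=alpha_tors,
                   v0_total=v0_total, v0_tors=v0_tors or 0.0)


def amd_boost(v, e: float, alpha: float):
    """Boost energy ΔV and force scale dV*/dV for potential value(s) v.

    ΔV = (E−V)²/(α+E−V) and dV*/dV = α²/(α+E−V)² below threshold;
    both ΔV = 0 and scale = 1 at or above it.  V* = V + ΔV is continuous
    and once-differentiable at V = E.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    v = np.asarray(v, dtype=float)
    gap = e - v
    below = gap > 0
    dv = np.where(below, gap ** 2 / (alpha + np.where(below, gap, 0.0)), 0.0)
    scale = np.where(below, (alpha / (alpha + np.where(below, gap, 1.0))) ** 2,
                     1.0)
    if np.ndim(v) == 0:
        return float(dv), float(scale)
    return dv, scale


@dataclass(frozen=True)
class LangevinSettings:
    """Integration settings; energies kcal/mol, time in reduced units."""

    timestep: float = 0.01
    friction: float = 1.0
    temperature: float = 300.0
    n_steps: int = 10000
    seed: int = 0
    x0: float | tuple = 0.0
    integrator: str = "baoab"

    def __post_init__(self):
        if self.timestep <= 0 or self.friction <= 0 or self.temperature < 0:
            raise ValueError("timestep and friction must be positive, "
                             "temperature non-negative")
        if self.integrator not in ("baoab", "overdamped"):
            raise ValueError("integrator must be 'baoab' or 'overdamped'")


@dataclass
class Trajectory:
    """Positions, unboosted potential and boost per step (ΔV ≡ 0 unboosted)."""

    positions: np.ndarray
    potential: np.ndarray
    boost: np.ndarray

    def __post_init__(self):
        if not (len(self.positions) == len(self.potential) == len(self.boost)):
            raise ValueError("per-step arrays must have equal length")
        if np.any(self.boost < -1e-12):
            raise ValueError("boost energies must be non-negative")

    @property
    def primary(self) -> np.ndarray:
        """The first (reaction) coordinate as a 1D series."""
        if self.positions.ndim == 1:
            return self.positions
        return self.positions[:, 0]


def _boosted_energy_force(landscape: ToyLandscape, x, amd, dual: bool):
    """(V_unboosted, ΔV_total, force) at configuration x."""
    arg = x if landscape.kind == "double_well_2d" else float(x[0])
    v = float(landscape.potential(arg))
    grad = np.atleast_1d(np.asarray(landscape.gradient(arg), dtype=float))
    if amd is None:
        return v, 0.0, -grad
    dv_tors = 0.0
    if dual and amd.e_tors is not None:
        if landscape.kind == "double_well_2d":
            # secondary boost acts on the hinge-angle (primary-coordinate) term
            a, b, c, x0 = landscape._dw_params()
            u = float(np.asarray(x)[0]) - x0
            v_sub = a * (u ** 2 - b ** 2) ** 2 + c * u
            g_sub = 4.0 * a * u * (u ** 2 - b ** 2) + c
            dv_tors, scale_tors = amd_boost(v_sub, amd.e_tors, amd.alpha_tors)
            grad = grad.copy()
            grad[0] += (scale_tors - 1.0) * g_sub
        else:
            dv_tors, scale_tors = amd_boost(v, amd.e_tors, amd.alpha_tors)
            grad = grad * scale_tors
    v1 = v + dv_tors
    dv_tot, scale_tot = amd_boost(v1, amd.e_total, amd.alpha_total)
    return v, dv_tors + dv_tot, -(scale_tot * grad)


def run_langevin(landscape: ToyLandscape, settings: LangevinSettings,
                 amd: AMDParameters | None = None,
                 dual: bool = False) -> Trajectory:
    """Sample the (optionally boosted) landscape; deterministic per seed.

    Trajectories escaping three domain-widths beyond the landscape domain
    raise with a suggestion to reduce the timestep.
    """
    rng = np.random.default_rng(settings.seed)
    dim = 2 if landscape.kind == "double_well_2d" else 1
    x = np.atleast_1d(np.asarray(settings.x0, dtype=float))
    if x.shape[0] != dim:
        x = np.resize(x, dim)
    lo, hi = landscape.domain
    width = hi - lo
    bound_lo, bound_hi = lo - 3 * width, hi + 3 * width

    dt, gamma, kt = settings.timestep, settings.friction, \
        KB_KCAL * settings.temperature
    n = settings.n_steps
    positions = np.empty((n, dim))
    potential = np.empty(n)
    boost = np.empty(n)

    if settings.integrator == "baoab":
        p = np.zeros(dim)
        c1 = np.exp(-gamma * dt)
        c2 = np.sqrt(kt * (1.0 - c1 ** 2))
        _, _, force = _boosted_energy_force(landscape, x, amd, dual)
        for i in range(n):
            p = p + 0.5 * dt * force
            x = x + 0.5 * dt * p
            p = c1 * p + c2 * rng.standard_normal(dim)
            x = x + 0.5 * dt * p
            v, dv, force = _boosted_energy_force(landscape, x, amd, dual)
            p = p + 0.5 * dt * force
            positions[i] = x
            potential[i] = v
            boost[i] = dv
            if not (bound_lo < x[0] < bound_hi):
                raise RuntimeError(
                    f"trajectory diverged at step {i} (x={x[0]:.3g}); "
                    "try a smaller timestep")
    else:  # overdamped Euler-Maruyama
        sigma = np.sqrt(2.0 * kt * dt / gamma)
        for i in range(n):
            v, dv, force = _boosted_energy_force(landscape, x, amd, dual)
            x = x + dt * force / gamma + sigma * rng.standard_normal(dim)
            positions[i] = x
            potential[i] = v
            boost[i] = dv
            if not (bound_lo < x[0] < bound_hi):
                raise RuntimeError(
                    f"trajectory diverged at step {i} (x={x[0]:.3g}); "
                    "try a smaller timestep")

    if dim == 1:
        positions = positions[:, 0]
    return Trajectory(positions=positions, potential=potential, boost=boost)


def _check_basins(basins):
    basins = [tuple(map(float, b)) for b in basins]
    for lo, hi in basins:
        if hi <= lo:
            raise ValueError("basin intervals must have hi > lo")
    ordered = sorted(basins)
    for (l1, h1), (l2, h2) in zip(ordered, ordered[1:]):
        if l2 < h1:
            raise ValueError("basin intervals must be disjoint")
    return basins


def reweight_populations(trajectory: Trajectory, basins,
                         temperature: float = 300.0,
                         n_blocks: int = 20):
    """Boost-reweighted basin populations with block-averaged errors.

    Each step is weighted exp(ΔV/k_BT) (computed with a log-sum-exp shift
    so large boosts cannot overflow); with ΔV ≡ 0 this reduces to raw
    occupancy.  Returns (populations, standard_errors) over the basins.
    """
    basins = _check_basins(basins)
    x = trajectory.primary
    kt = KB_KCAL * temperature
    logw = trajectory.boost / kt
    logw = logw - logw.max()
    w = np.exp(logw)

    def pops(xs, ws):
        total = ws.sum()
        return np.array([ws[(xs >= lo) & (xs < hi)].sum() / total
                         for lo, hi in basins])

    p = pops(x, w)
    # block averaging absorbs the trajectory autocorrelation
    blocks = np.array_split(np.arange(len(x)), n_blocks)
    bp = np.array([pops(x[idx], w[idx]) for idx in blocks if len(idx)])
    se = bp.std(axis=0, ddof=1) / np.sqrt(len(bp))
    return p, se


def count_transitions(series, basins, dwell: int = 1) -> int:
    """Debounced basin-crossing count.

    A transition is registered only after ``dwell`` consecutive steps in
    the new basin; steps outside every basin are transparent.
    """
    basins = _check_basins(basins)
    x = np.asarray(series, dtype=float)
    assign = np.full(len(x), -1)
    for k, (lo, hi) in enumerate(basins):
        assign[(x >= lo) & (x < hi)] = k

    current = -1
    candidate = -1
    streak = 0
    transitions = 0
    for a in assign:
        if a == -1 or a == current:
            candidate, streak = -1, 0
            continue
        if a == candidate:
            streak += 1
        else:
            candidate, streak = a, 1
        if streak >= dwell:
            if current != -1:
                transitions += 1
            current = candidate
            candidate, streak = -1, 0
    return transitions
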