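"""Synthetic two-state hinge ensembles and analytic toy landscapes.

The generator emulates a two-domain protein in a pre-existing two-state
equilibrium: a major open state and a minor semi-closed state that differ
by a rigid rotation of the C-terminal domain about the hinge.  Each domain
is a rigid cap of beads on a sphere; per-frame interdomain angles are drawn
from a two-component normal mixture and every bead receives isotropic
positional jitter, so measured order parameters are below 1 and internal
correlation times are finite.  A spin-label bead on the NTD carries extra
independent wobble, mirroring the flexibility of a nitroxide side chain.

Toy landscapes (harmonic and tilted double wells) come with analytic
potentials, gradients and Boltzmann populations by quadrature, providing
ground truth for the boosted-sampling and adaptive-biasing-force stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from .ensemble import ConformerEnsemble

KB_KCAL = 0.0019872041  # Boltzmann constant, kcal mol^-1 K^-1


# --------------------------------------------------------------------------
# two-state hinge model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoStateModel:
    """Populations of the open and minor (semi-closed) states."""

    p_open: float
    p_minor: float
    temperature: float = 300.0

    def __post_init__(self):
        if not (0.0 <= self.p_open <= 1.0 and 0.0 <= self.p_minor <= 1.0):
            raise ValueError("populations must lie in [0, 1]")
        if abs(self.p_open + self.p_minor - 1.0) > 1e-12:
            raise ValueError("p_open + p_minor must equal 1")

    @classmethod
    def from_minor(cls, p_minor: float, temperature: float = 300.0):
        return cls(1.0 - p_minor, p_minor, temperature)


@dataclass(frozen=True)
class HingeModelSpec:
    """Geometry and statistics of the coarse-grained two-domain model.

    Angles in degrees, lengths in Å.  Defaults mirror the maltose-binding
    protein picture: open basin near 160°, semi-closed near 146°, 95:5
    populations, with bead jitter chosen to give order parameters S² in the
    0.85–0.99 range typical of amide-proton interaction vectors.
    """

    n_beads_ntd: int = 15
    n_beads_ctd: int = 15
    hinge_position: tuple = (0.0, 0.0, 0.0)
    domain_radius: float = 15.0
    com_distance: float = 20.0
    label_arm: float = 4.0
    angle_open: float = 160.0
    angle_minor: float = 146.0
    angle_sd: float = 2.0
    p_minor: float = 0.05
    jitter_sd: float = 0.6
    label_jitter_sd: float = 1.5
    label_site: int = 0
    h_sites: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_beads_ntd < 1 or self.n_beads_ctd < 1:
            raise ValueError("n_beads_ntd and n_beads_ctd must be positive")
        if not (0.0 <= self.p_minor <= 1.0):
            raise ValueError("p_minor must lie in [0, 1]")
        if self.angle_open <= self.angle_minor:
            raise ValueError("angle_open must exceed angle_minor")
        if self.angle_sd <= 0:
            raise ValueError("angle_sd must be positive")
        if self.jitter_sd < 0 or self.label_jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")
        n = self.n_beads_ntd + self.n_beads_ctd
        if not (0 <= self.label_site < self.n_beads_ntd):
            raise ValueError("label_site must index an NTD bead")
        h = self.h_sites or tuple(i for i in range(n) if i != self.label_site)
        if any(not (0 <= i < n) for i in h):
            raise ValueError("h_sites must be valid bead indices")
        object.__setattr__(self, "h_sites", tuple(h))
        object.__setattr__(self, "hinge_position",
                           tuple(float(v) for v in self.hinge_position))

    @property
    def n_beads(self) -> int:
        return self.n_beads_ntd + self.n_beads_ctd


def _fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """Quasi-uniform points on a sphere (deterministic)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return radius * np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _rotation_z(angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ctd_beads(spec: HingeModelSpec, theta_deg: float) -> np.ndarray:
    hinge = np.asarray(spec.hinge_position)
    rot = _rotation_z(theta_deg)
    ctd_center = hinge + rot @ np.array([spec.com_distance, 0.0, 0.0])
    local = _fibonacci_sphere(spec.n_beads_ctd, spec.domain_radius)
    local -= local.mean(axis=0)  # COM exactly at the cap center
    return ctd_center + local @ rot.T


def _label_direction(spec: HingeModelSpec) -> np.ndarray:
    """Cleft-facing label orientation, chosen once per model geometry.

    The nitroxide arm is pointed at the surface direction that maximises
    the open↔minor contrast in Σ⟨r⁻⁶⟩ over the CTD beads — emulating the
    experimental choice of a labelling site that reports on domain
    closure — subject to a 10 Å clash floor in the minor state.
    """
    key = (spec.n_beads_ctd, spec.hinge_position, spec.domain_radius,
           spec.com_distance, spec.label_arm, spec.angle_open,
           spec.angle_minor)
    cached = _label_dir_cache.get(key)
    if cached is not None:
        return cached
    hinge = np.asarray(spec.hinge_position)
    ntd_center = hinge + np.array([spec.com_distance, 0.0, 0.0])
    reach = spec.domain_radius + spec.label_arm
    ctd_open = _ctd_beads(spec, spec.angle_open)
    ctd_minor = _ctd_beads(spec, spec.angle_minor)
    directions = _fibonacci_sphere(400, 1.0)
    best, best_score = directions[0], -np.inf
    for u in directions:
        p = ntd_center + reach * u
        d_open = np.linalg.norm(ctd_open - p, axis=1)
        d_minor = np.linalg.norm(ctd_minor - p, axis=1)
        if d_minor.min() < 10.0:
            continue
        score = np.sum(d_minor ** -6 - d_open ** -6)
        if score > best_score:
            best, best_score = u, score
    _label_dir_cache[key] = best
    return best


_label_dir_cache: dict = {}


def hinge_template(spec: HingeModelSpec, theta_deg: float):
    """Rigid bead coordinates at a given interdomain angle.

    The NTD cap is fixed with its center ``com_distance`` Å from the hinge
    along +x; the CTD cap center sits at the same distance, rotated by θ
    about the z-axis through the hinge (closure is a pure in-plane
    rotation).  The label bead sits ``label_arm`` Å beyond the NTD surface
    in the cleft-facing orientation (see :func:`_label_direction`).
    Returns (coords (n_beads+3, 3), meta DataFrame) — the last three beads
    mark the hinge region.
    """
    hinge = np.asarray(spec.hinge_position)
    ntd_center = hinge + np.array([spec.com_distance, 0.0, 0.0])
    ntd_local = _fibonacci_sphere(spec.n_beads_ntd, spec.domain_radius)
    # recentre the cap on the beads that carry the NTD tag (the label bead
    # is tagged separately) so the measured COM sits exactly at the center
    backbone = np.delete(np.arange(spec.n_beads_ntd), spec.label_site)
    if len(backbone):
        ntd_local[backbone] -= ntd_local[backbone].mean(axis=0)
    ntd = ntd_center + ntd_local
    ntd[spec.label_site] = ntd_center + (
        (spec.domain_radius + spec.label_arm) * _label_direction(spec))
    ctd = _ctd_beads(spec, theta_deg)
    hinge_beads = hinge + np.array([[0.0, 0.0, 0.0],
                                    [1.5, 0.0, 1.0],
                                    [-1.5, 0.0, -1.0]])
    coords = np.vstack([ntd, ctd, hinge_beads])
    domains = ["NTD"] * spec.n_beads_ntd + ["CTD"] * spec.n_beads_ctd \
        + ["HINGE"] * 3
    domains[spec.label_site] = "OTHER"  # the spin label is not backbone
    meta = pd.DataFrame({
        "residue_id": np.arange(1, coords.shape[0] + 1),
        "atom_name": ["CA"] * coords.shape[0],
        "domain": domains,
    })
    return coords, meta


def generate_hinge_ensemble(spec: HingeModelSpec, n_frames: int,
                            seed: int | None = None) -> ConformerEnsemble:
    """Draw a two-state hinge ensemble with per-frame state labels.

    Random-stream order is fixed and documented: state draws, then angle
    draws, then bead jitter, then label wobble — so fixtures are stable
    under a fixed seed.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    states = rng.random(n_frames) < spec.p_minor  # True = minor
    means = np.where(states, spec.angle_minor, spec.angle_open)
    angles = means + spec.angle_sd * rng.standard_normal(n_frames)

    _, meta = hinge_template(spec, spec.angle_open)
    n_atoms = len(meta)
    coords = np.empty((n_frames, n_atoms, 3))
    for i in range(n_frames):
        coords[i] = hinge_template(spec, angles[i])[0]
    coords += rng.normal(0.0, spec.jitter_sd, size=coords.shape) \
        if spec.jitter_sd > 0 else 0.0
    if spec.label_jitter_sd > 0:
        coords[:, spec.label_site, :] += rng.normal(
            0.0, spec.label_jitter_sd, size=(n_frames, 3))

    labels = np.where(states, "minor", "open")
    return ConformerEnsemble(coords=coords, atom_meta=meta,
                             source="synthetic two-state hinge model",
                             frame_labels=labels)


def single_state_ensemble(spec: HingeModelSpec, state: str, n_frames: int,
                          seed: int | None = None) -> ConformerEnsemble:
    """Ensemble drawn entirely from one basin ('open' or 'minor')."""
    if state not in ("open", "minor"):
        raise ValueError("state must be 'open' or 'minor'")
    mean = spec.angle_open if state == "open" else spec.angle_minor
    # p_minor=0 pins every frame to the "open" slot, whose mean we set
    one_state = replace(spec, p_minor=0.0, angle_open=mean,
                        angle_minor=mean - 1.0)
    ens = generate_hinge_ensemble(one_state, n_frames, seed=seed)
    ens.frame_labels = np.full(n_frames, state)
    return ens


# --------------------------------------------------------------------------
# toy landscapes
# --------------------------------------------------------------------------

@dataclass
class ToyLandscape:
    """Analytic 1D/2D potential with gradient and Boltzmann ground truth."""

    kind: str
    parameters: tuple
    domain: tuple = (-5.0, 5.0)

    _kinds = ("harmonic", "double_well_1d", "double_well_2d")

    def __post_init__(self):
        if self.kind not in self._kinds:
            raise ValueError(f"unknown landscape kind {self.kind!r}")
        self.parameters = tuple(float(p) for p in self.parameters)

    # -- potentials (kcal/mol); x in Å ------------------------------------
    def potential(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "harmonic":
            (k,) = self.parameters
            return 0.5 * k * x ** 2
        a, b, c, x0 = self._dw_params()
        u = (x[..., 0] if self.kind == "double_well_2d" else x) - x0
        v = a * (u ** 2 - b ** 2) ** 2 + c * u
        if self.kind == "double_well_2d":
            ky = self.parameters[4]
            v = v + 0.5 * ky * x[..., 1] ** 2
        return v

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        if self.kind == "harmonic":
            (k,) = self.parameters
            return k * x
        a, b, c, x0 = self._dw_params()
        u = (x[..., 0] if self.kind == "double_well_2d" else x) - x0
        g = 4.0 * a * u * (u ** 2 - b ** 2) + c
        if self.kind == "double_well_2d":
            ky = self.parameters[4]
            return np.stack([g, ky * x[..., 1]], axis=-1)
        return g

    def _dw_params(self):
        p = self.parameters
        if self.kind == "double_well_1d":
            a, b = p[0], p[1]
            c = p[2] if len(p) > 2 else 0.0
            x0 = p[3] if len(p) > 3 else 0.0
        else:  # double_well_2d: (a, b, c, x0, ky)
            a, b, c, x0 = p[0], p[1], p[2], p[3]
        return a, b, c, x0

    # -- analytic reference ----------------------------------------------
    def analytic_pmf(self, x):
        """Free-energy profile along the primary coordinate, anchored so the
        global minimum over the domain is 0."""
        if self.kind == "double_well_2d":
            a, b, c, x0 = self._dw_params()
            x = np.asarray(x, dtype=float)
            v = a * ((x - x0) ** 2 - b ** 2) ** 2 + c * (x - x0)
        else:
            v = self.potential(x)
        return v - self._vmin()

    def minima(self):
        if self.kind == "harmonic":
            return (0.0,)
        a, b, c, x0 = self._dw_params()
        left = minimize_scalar(lambda u: float(self.analytic_pmf(u)),
                               bounds=(x0 - 2 * b, x0), method="bounded").x
        right = minimize_scalar(lambda u: float(self.analytic_pmf(u)),
                                bounds=(x0, x0 + 2 * b), method="bounded").x
        return (float(left), float(right))

    def barrier_location(self):
        if self.kind == "harmonic":
            raise ValueError("harmonic landscape has no barrier")
        lo, hi = self.minima()
        res = minimize_scalar(lambda u: -float(self.analytic_pmf(u)),
                              bounds=(lo, hi), method="bounded")
        return float(res.x)

    def barrier_height(self):
        """Barrier measured from the lower minimum (kcal/mol)."""
        return float(self.analytic_pmf(self.barrier_location()))

    def populations(self, temperature: float = 300.0):
        """(p_left, p_right) Boltzmann populations by quadrature (abs tol 1e-8)."""
        if self.kind == "harmonic":
            return (1.0,)
        beta = 1.0 / (KB_KCAL * temperature)
        xb = self.barrier_location()
        lo, hi = self.domain

        def boltz(u):
            if self.kind == "double_well_2d":
                a, b, c, x0 = self._dw_params()
                v = a * ((u - x0) ** 2 - b ** 2) ** 2 + c * (u - x0)
            else:
                v = float(self.potential(u))
            return np.exp(-beta * (v - self._vmin()))

        zl, _ = quad(boltz, lo, xb, epsabs=1e-8, limit=200)
        zr, _ = quad(boltz, xb, hi, epsabs=1e-8, limit=200)
        z = zl + zr
        return (zl / z, zr / z)

    def _vmin(self):
        xs = np.linspace(self.domain[0], self.domain[1], 4001)
        if self.kind == "double_well_2d":
            a, b, c, x0 = self._dw_params()
            return float(np.min(a * ((xs - x0) ** 2 - b ** 2) ** 2 + c * (xs - x0)))
        return float(np.min(self.potential(xs)))


def generate_landscape(kind: str, parameters, domain=None) -> ToyLandscape:
    """Build a toy landscape; see :class:`ToyLandscape` for parameter layout.

    * ``harmonic``: (k,) — V = k x²/2
    * ``double_well_1d``: (a, b[, c[, x0]]) — V = a((x−x0)²−b²)² + c(x−x0)
    * ``double_well_2d``: (a, b, c, x0, ky) — the 1D well plus ky y²/2
    """
    kwargs = {} if domain is None else {"domain": tuple(domain)}
    return ToyLandscape(kind=kind, parameters=tuple(parameters), **kwargs)


def barrier_calibrated_double_well(barrier: float, minima: tuple = (-1.0, 1.0),
                                   tilt: float = 0.0,
                                   domain=None) -> ToyLandscape:
    """Symmetric-well positions with an exact analytic barrier height.

    For tilt = 0 the barrier from either minimum is exactly ``barrier``
    kcal/mol: a = barrier / b⁴ with b the half-separation.
    """
    x0 = 0.5 * (minima[0] + minima[1])
    b = 0.5 * (minima[1] - minima[0])
    a = barrier / b ** 4
    if domain is None:
        domain = (minima[0] - 2.0 * b, minima[1] + 2.0 * b)
    return ToyLandscape(kind="double_well_1d", parameters=(a, b, tilt, x0),
                        domain=tuple(domain))


# --------------------------------------------------------------------------
# synthetic "experimental" PRE profiles
# --------------------------------------------------------------------------

def synthesize_pre_profile(open_ensemble: ConformerEnsemble,
                           minor_ensemble: ConformerEnsemble,
                           model: TwoStateModel,
                           spec: HingeModelSpec,
                           sbmf_params=None,
                           noise_sd: float = 2.0,
                           gamma2_max: float = 150.0,
                           seed: int = 0) -> pd.DataFrame:
    """Noisy population-weighted Γ₂ profile with ground truth attached.

    The observed profile is the population-weighted mean of the two
    single-state back-calculated profiles plus i.i.d. normal noise
    (default SD 2 s⁻¹, the few-per-second scale of experimental PRE
    uncertainties).  Sites whose noiseless rate exceeds ``gamma2_max``
    (default 150 s⁻¹) are dropped, mimicking label-proximal resonances
    broadened beyond detection.  Ground truth (noiseless profile,
    per-state profiles, populations) rides along in ``DataFrame.attrs``.
    """
    from . import pre as pre_mod

    if sbmf_params is None:
        sbmf_params = pre_mod.SBMFParameters()
    prof_open = pre_mod.ensemble_pre_profile(open_ensemble, spec.label_site,
                                             spec.h_sites, sbmf_params)
    prof_minor = pre_mod.ensemble_pre_profile(minor_ensemble, spec.label_site,
                                              spec.h_sites, sbmf_params)
    if not np.array_equal(prof_open["residue_id"].to_numpy(),
                          prof_minor["residue_id"].to_numpy()):
        raise ValueError("state ensembles must share the same 1H site list")
    combined = pre_mod.combine_states([prof_open, prof_minor],
                                      [model.p_open, model.p_minor])
    observable = combined["gamma2"].to_numpy() <= gamma2_max
    combined = combined.loc[observable].reset_index(drop=True)
    prof_open = prof_open.loc[observable].reset_index(drop=True)
    prof_minor = prof_minor.loc[observable].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(combined)) if noise_sd > 0 else 0.0
    out = combined.copy()
    out["gamma2_true"] = combined["gamma2"]
    out["gamma2"] = combined["gamma2"] + noise
    out.attrs["p_minor_true"] = model.p_minor
    out.attrs["noise_sd"] = noise_sd
    out.attrs["profile_open"] = prof_open
    out.attrs["profile_minor"] = prof_minor
    return out
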