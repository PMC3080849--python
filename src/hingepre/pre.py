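"""Solomon-Bloembergen model-free (SBMF) back-calculation of transverse
paramagnetic relaxation enhancement (PRE) rates.

An unpaired electron on a nitroxide spin label relaxes nearby ¹H nuclei at
a rate Γ₂ that scales with the inverse sixth power of the electron-proton
distance, which makes PRE a long-range (≈15-35 Å) probe of conformational
ensembles.  In the model-free treatment the electron-¹H interaction vector
is characterised per residue by three ensemble statistics —

    ⟨r⁻⁶⟩   the frame-averaged inverse sixth distance,
    S²      the generalized order parameter of the vector
            (S² = (4π/5) Σ_m |⟨r⁻³ Y₂m(Ω)⟩|² / ⟨r⁻⁶⟩),
    τ_i     the internal correlation time of the vector,

and the transverse rate is

    Γ₂ = (1/15) (μ₀/4π)² γ_I² g² μ_B² s(s+1) [4 J(0) + 3 J(ω_I)],
    J(ω) = ⟨r⁻⁶⟩ [ S² τ_c/(1+(ωτ_c)²) + (1−S²) τ_t/(1+(ωτ_t)²) ],

with 1/τ_c = 1/τ_r + 1/τ_s and 1/τ_t = 1/τ_r + 1/τ_s + 1/τ_i.  The
electron relaxation time τ_s is ignored by default (τ_c = τ_r), the
standard assumption when τ_s far exceeds the rotational diffusion time.

Two-state population weighting, Q-factor agreement scoring, and grid
fitting of the minor-state population close the loop against observed
profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .ensemble import ConformerEnsemble
from .synthetic import TwoStateModel

ANGSTROM = 1e-10


@dataclass(frozen=True)
class PREPhysicalConstants:
    """CODATA constants entering the Γ₂ prefactor (SI units)."""

    s: float = 0.5                      # electron spin quantum number
    g: float = 2.00231930               # free-electron g-factor
    gamma_i: float = 2.6752218744e8     # 1H gyromagnetic ratio, rad s^-1 T^-1
    mu_0: float = 1.25663706212e-6      # vacuum permeability, T^2 m^3 J^-1
    mu_b: float = 9.2740100783e-24      # Bohr magneton, J T^-1

    def __post_init__(self):
        for name in ("s", "g", "gamma_i", "mu_0", "mu_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(2 * self.s - round(2 * self.s)) > 1e-9:
            raise ValueError("s must be a half-integer spin quantum number")

    @property
    def prefactor(self) -> float:
        """(1/15)(μ₀/4π)² γ_I² g² μ_B² s(s+1), units m⁶ s⁻²."""
        return ((self.mu_0 / (4 * np.pi)) ** 2 * self.gamma_i ** 2
                * self.g ** 2 * self.mu_b ** 2 * self.s * (self.s + 1) / 15.0)


@dataclass(frozen=True)
class CorrelationTimes:
    """Rotational, internal and (optional) electron relaxation times (s).

    τ_c and τ_t are derived: 1/τ_c = 1/τ_r + 1/τ_s and
    1/τ_t = 1/τ_r + 1/τ_s + 1/τ_i, with τ_s = None meaning "ignored"
    (infinite), the default.
    """

    tau_r: float = 20e-9
    tau_i: float = 0.5e-9
    tau_s: float | None = None

    def __post_init__(self):
        if self.tau_r <= 0 or self.tau_i <= 0:
            raise ValueError("tau_r and tau_i must be positive")
        if self.tau_s is not None and self.tau_s <= 0:
            raise ValueError("tau_s must be positive or None")

    @property
    def tau_c(self) -> float:
        if self.tau_s is None:
            return self.tau_r
        return 1.0 / (1.0 / self.tau_r + 1.0 / self.tau_s)

    @property
    def tau_t(self) -> float:
        return 1.0 / (1.0 / self.tau_c + 1.0 / self.tau_i)


@dataclass(frozen=True)
class SBMFParameters:
    """Everything needed to turn vector statistics into Γ₂.

    The spectrometer field (default 14.1 T, i.e. 600 MHz ¹H) sets the
    proton Larmor frequency ω_I = γ_I B₀; it is configuration, and every
    quantitative result is field-explicit.
    """

    constants: PREPhysicalConstants = field(default_factory=PREPhysicalConstants)
    times: CorrelationTimes = field(default_factory=CorrelationTimes)
    b0: float = 14.1

    @property
    def omega_i(self) -> float:
        return self.constants.gamma_i * self.b0


# --------------------------------------------------------------------------
# vector statistics from ensembles
# --------------------------------------------------------------------------

def _vectors(ensemble: ConformerEnsemble, label_site: int, h_sites):
    h_sites = np.asarray(list(h_sites), dtype=int)
    n = ensemble.n_atoms
    if not (0 <= label_site < n):
        raise ValueError(f"label_site {label_site} out of range")
    if np.any((h_sites < 0) | (h_sites >= n)):
        raise ValueError("h_sites contain out-of-range indices")
    v = ensemble.coords[:, h_sites, :] - ensemble.coords[:, [label_site], :]
    r = np.linalg.norm(v, axis=2)
    if np.any(r < 1e-6):
        raise ValueError("electron and 1H site coincide in some frame")
    return v, r, h_sites


def order_parameter(vectors: np.ndarray) -> np.ndarray:
    """Model-free S² with r⁻³ weighting for (n_frames, n_sites, 3) vectors.

    Uses the Cartesian identity S² ⟨r⁻⁶⟩ = (3/2) Σ_ij ⟨e_i e_j r⁻³⟩² −
    (1/2) ⟨r⁻³⟩², equivalent to the rank-2 spherical-harmonic definition.
    """
    r = np.linalg.norm(vectors, axis=2)
    e = vectors / r[..., None]
    inv_r3 = r ** -3
    inv_r6_mean = np.mean(inv_r3 ** 2, axis=0)
    # ⟨e_i e_j / r³⟩ per site: (n_sites, 3, 3)
    w = e * inv_r3[..., None]
    m = np.einsum("fsi,fsj->sij", w, e) / vectors.shape[0]
    s2 = (1.5 * np.einsum("sij,sij->s", m, m)
          - 0.5 * np.mean(inv_r3, axis=0) ** 2) / inv_r6_mean
    return np.clip(s2, 0.0, 1.0)


def internal_correlation(vectors: np.ndarray, max_lag: int | None = None
                         ) -> np.ndarray:
    """Rank-2, r⁻³-weighted internal correlation C(t) per site.

    C(t) = ⟨ P₂(ê(0)·ê(t)) r(0)⁻³ r(t)⁻³ ⟩ / ⟨r⁻⁶⟩; C(0) = 1 and
    C(t→∞) = S² for internal motion uncoupled from tumbling.
    Returns an array (n_lags, n_sites).
    """
    n_frames = vectors.shape[0]
    if max_lag is None:
        max_lag = n_frames // 2
    r = np.linalg.norm(vectors, axis=2)
    e = vectors / r[..., None]
    w = e * (r ** -3)[..., None]      # r⁻³ ê, shape (f, s, 3)
    inv_r6_mean = np.mean(r ** -6, axis=0)
    out = np.empty((max_lag + 1, vectors.shape[1]))
    for lag in range(max_lag + 1):
        a = w[: n_frames - lag]
        b = w[lag:]
        dot = np.einsum("fsi,fsi->fs", a, b)
        rr = (r[: n_frames - lag] * r[lag:]) ** -3
        c = 1.5 * np.mean(dot ** 2 / rr, axis=0) - 0.5 * np.mean(rr, axis=0)
        out[lag] = c / inv_r6_mean
    return out


def fit_tau_i(corr: np.ndarray, s2: np.ndarray, dt: float,
              fit_fraction: float = 0.2) -> np.ndarray:
    """Single-exponential internal time from the initial correlation decay.

    (C(t) − S²)/(C(0) − S²) is fitted to exp(−t/τ_i) over the first
    ``fit_fraction`` of available lags.  Degenerate decays (C(0) ≈ S²,
    i.e. essentially rigid vectors) return the shortest resolvable time
    dt/10 with a warning, as a lower bound.
    """
    n_lags, n_sites = corr.shape
    n_fit = max(3, int(fit_fraction * n_lags))
    t = np.arange(n_fit) * dt
    tau = np.empty(n_sites)
    for s in range(n_sites):
        amp = corr[0, s] - s2[s]
        if amp < 1e-6:
            warnings.warn("near-rigid vector: tau_i reported as lower bound")
            tau[s] = dt / 10.0
            continue
        y = np.clip((corr[:n_fit, s] - s2[s]) / amp, 1e-12, None)
        try:
            popt, _ = curve_fit(lambda tt, tau_: np.exp(-tt / tau_), t, y,
                                p0=[max(dt, 1e-12)], maxfev=2000)
            tau[s] = abs(popt[0])
        except RuntimeError:
            warnings.warn("tau_i fit failed; reporting lag-time lower bound")
            tau[s] = dt / 10.0
    return tau


def vector_statistics(ensemble: ConformerEnsemble, label_site: int, h_sites,
                      frame_dt: float | None = None,
                      tau_i_default: float = 0.5e-9) -> pd.DataFrame:
    """Per-site ⟨r⁻⁶⟩ (Å⁻⁶), S², and τ_i (s) for the electron→¹H vectors.

    If ``frame_dt`` (seconds between frames) is given the frames are
    treated as a time series and τ_i is fitted from the internal
    correlation decay; otherwise frames are treated as independent draws
    and τ_i falls back to ``tau_i_default``.
    """
    if ensemble.n_frames < 2:
        raise ValueError("need at least 2 frames for vector statistics")
    v, r, h_idx = _vectors(ensemble, label_site, h_sites)
    mean_inv_r6 = np.mean(r ** -6, axis=0)
    s2 = order_parameter(v)
    if frame_dt is not None:
        corr = internal_correlation(v)
        tau_i = fit_tau_i(corr, s2, frame_dt)
    else:
        tau_i = np.full(len(h_idx), tau_i_default)
    meta = ensemble.atom_meta.iloc[h_idx]
    return pd.DataFrame({
        "residue_id": meta["residue_id"].to_numpy(),
        "domain": meta["domain"].to_numpy(),
        "mean_inv_r6": mean_inv_r6,
        "s2": s2,
        "tau_i": tau_i,
    })


# --------------------------------------------------------------------------
# spectral density and Γ₂
# --------------------------------------------------------------------------

def spectral_density(omega: float, mean_inv_r6, s2, times: CorrelationTimes,
                     tau_i=None):
    """Reduced SBMF spectral density J(ω) (units of mean_inv_r6 × s)."""
    mean_inv_r6 = np.asarray(mean_inv_r6, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    tau_c = times.tau_c
    if tau_i is None:
        tau_t = times.tau_t
    else:
        tau_i = np.asarray(tau_i, dtype=float)
        tau_t = 1.0 / (1.0 / tau_c + 1.0 / tau_i)
    return mean_inv_r6 * (s2 * tau_c / (1.0 + (omega * tau_c) ** 2)
                          + (1.0 - s2) * tau_t / (1.0 + (omega * tau_t) ** 2))


def gamma2(stats: pd.DataFrame, params: SBMFParameters | None = None
           ) -> pd.DataFrame:
    """Transverse PRE rate Γ₂ (s⁻¹) per residue from vector statistics.

    Input ⟨r⁻⁶⟩ must be in Å⁻⁶ (interface convention); conversion to SI
    happens here and a sentinel rejects values that look like m⁻⁶.
    """
    if params is None:
        params = SBMFParameters()
    inv_r6 = np.asarray(stats["mean_inv_r6"], dtype=float)
    if np.any(inv_r6 <= 0):
        raise ValueError("mean_inv_r6 must be positive")
    if np.any(inv_r6 > 1e6):
        raise ValueError(
            "mean_inv_r6 looks like m^-6; the interface convention is Å^-6")
    inv_r6_si = inv_r6 / ANGSTROM ** 6
    s2 = np.asarray(stats["s2"], dtype=float)
    tau_i = np.asarray(stats["tau_i"], dtype=float) if "tau_i" in stats else None
    j0 = spectral_density(0.0, inv_r6_si, s2, params.times, tau_i)
    jw = spectral_density(params.omega_i, inv_r6_si, s2, params.times, tau_i)
    g2 = params.constants.prefactor * (4.0 * j0 + 3.0 * jw)
    out = pd.DataFrame({
        "residue_id": stats["residue_id"].to_numpy(),
        "gamma2": g2,
    })
    if "domain" in stats:
        out["domain"] = stats["domain"].to_numpy()
    return out


def ensemble_pre_profile(ensemble: ConformerEnsemble, label_site: int,
                         h_sites, params: SBMFParameters | None = None,
                         frame_dt: float | None = None) -> pd.DataFrame:
    """Convenience: vector statistics then Γ₂ for one ensemble."""
    if params is None:
        params = SBMFParameters()
    stats = vector_statistics(ensemble, label_site, h_sites, frame_dt,
                              tau_i_default=params.times.tau_i)
    return gamma2(stats, params)


# --------------------------------------------------------------------------
# population weighting, agreement, fitting
# --------------------------------------------------------------------------

def combine_states(profiles, populations) -> pd.DataFrame:
    """Population-weighted linear average of per-state Γ₂ profiles."""
    populations = np.asarray(populations, dtype=float)
    if len(profiles) != len(populations):
        raise ValueError("one population per profile required")
    if np.any(populations < 0) or abs(populations.sum() - 1.0) > 1e-9:
        raise ValueError("populations must be non-negative and sum to 1")
    base = profiles[0]["residue_id"].to_numpy()
    for p in profiles[1:]:
        if not np.array_equal(p["residue_id"].to_numpy(), base):
            raise ValueError("profiles have mismatched residue lists")
    g2 = sum(w * p["gamma2"].to_numpy() for w, p in zip(populations, profiles))
    out = pd.DataFrame({"residue_id": base, "gamma2": g2})
    if "domain" in profiles[0]:
        out["domain"] = profiles[0]["domain"].to_numpy()
    return out


def agreement(calculated: pd.DataFrame, observed: pd.DataFrame):
    """Q-factor and Pearson correlation between Γ₂ profiles.

    Q = sqrt( Σ(Γ_calc − Γ_obs)² / Σ Γ_obs² ); profiles are matched on
    residue_id and need ≥3 common residues.
    """
    merged = calculated.merge(observed, on="residue_id",
                              suffixes=("_calc", "_obs"))
    if len(merged) < 3:
        raise ValueError("need at least 3 common residues")
    gc = merged["gamma2_calc"].to_numpy()
    go = merged["gamma2_obs"].to_numpy()
    denom = np.sum(go ** 2)
    if denom == 0:
        raise ValueError("observed profile is all zero; Q undefined")
    q = float(np.sqrt(np.sum((gc - go) ** 2) / denom))
    r = float(np.corrcoef(gc, go)[0, 1])
    return q, r


@dataclass
class PopulationFitResult:
    model: TwoStateModel
    q_min: float
    p_grid: np.ndarray
    q_grid: np.ndarray
    degenerate: bool = False

    @property
    def p_minor(self) -> float:
        return self.model.p_minor


def fit_populations(state_profiles, observed: pd.DataFrame,
                    grid_step: float = 0.005,
                    temperature: float = 300.0) -> PopulationFitResult:
    """Minor-state population minimising the Q-factor.

    Scans p_minor over [0, 1] at ``grid_step`` resolution and refines the
    minimum with a parabola through the three bracketing grid points.
    With indistinguishable state profiles the misfit is flat and the fit
    is flagged degenerate.
    """
    if len(state_profiles) != 2:
        raise ValueError("exactly two state profiles (open, minor) expected")
    open_prof, minor_prof = state_profiles
    merged = open_prof.merge(minor_prof, on="residue_id",
                             suffixes=("_open", "_minor")) \
                      .merge(observed, on="residue_id")
    if len(merged) < 3:
        raise ValueError("need at least 3 common residues")
    go = merged["gamma2_open"].to_numpy()
    gm = merged["gamma2_minor"].to_numpy()
    gobs = merged["gamma2"].to_numpy()
    denom = np.sum(gobs ** 2)
    if denom == 0:
        raise ValueError("observed profile is all zero; Q undefined")
    p_grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    # Q(p) = ||g_open + p (g_minor - g_open) - g_obs|| / ||g_obs||
    resid = (go - gobs)[None, :] + p_grid[:, None] * (gm - go)[None, :]
    q_grid = np.sqrt(np.sum(resid ** 2, axis=1) / denom)
    degenerate = bool(np.ptp(q_grid) < 1e-12)
    if degenerate:
        warnings.warn("state profiles are indistinguishable; "
                      "population is undetermined (flat misfit)")
    i = int(np.argmin(q_grid))
    p_best, q_best = p_grid[i], q_grid[i]
    if 0 < i < len(p_grid) - 1 and not degenerate:
        # parabolic refinement through the bracketing points
        y0, y1, y2 = q_grid[i - 1], q_grid[i], q_grid[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            shift = 0.5 * (y0 - y2) / denom
            p_best = float(np.clip(p_grid[i] + shift * grid_step, 0.0, 1.0))
            q_best = float(np.sqrt(np.sum(
                ((1 - p_best) * go + p_best * gm - gobs) ** 2) / np.sum(gobs ** 2)))
    model = TwoStateModel.from_minor(float(p_best), temperature)
    return PopulationFitResult(model=model, q_min=float(q_best),
                               p_grid=p_grid, q_grid=q_grid,
                               degenerate=degenerate)
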