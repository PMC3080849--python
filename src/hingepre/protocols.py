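"""End-to-end study protocols at desk scale.

Each function wires several stages into one reproducible numerical
experiment on synthetic systems: two-state PRE population recovery,
boosted-vs-conventional transition sampling, forward/reverse ABF PMF
recovery, and PCA of an open/closed reference set.  They are the
package's reference workflows — the test suite and the reproduction
script both call them, so reported numbers always come from the same
code path.

Problem sizes (ensemble frames, step counts, seed counts) are chosen so
every protocol runs in seconds to a couple of minutes on one core while
keeping Monte-Carlo errors well inside the tolerances they are judged
against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import abf as abf_mod
from . import dynamics as dyn
from . import pre as pre_mod
from .ensemble import ConformerEnsemble
from .geometry import interdomain_angle_series, partition_from_tags
from .pca import EnsemblePCA
from .synthetic import (HingeModelSpec, TwoStateModel,
                        barrier_calibrated_double_well, generate_landscape,
                        single_state_ensemble, synthesize_pre_profile)


# --------------------------------------------------------------------------
# PRE two-state recovery (the population-fitting experiment)
# --------------------------------------------------------------------------

@dataclass
class PRERecoveryResult:
    p_true: float
    p_fitted: np.ndarray          # one fit per noise seed
    median_abs_error: float
    q_open_only: np.ndarray
    q_weighted: np.ndarray
    improved_fraction: float


def pre_population_recovery(seed: int = 0, n_noise_seeds: int = 100,
                            n_frames: int = 200,
                            p_minor: float = 0.05) -> PRERecoveryResult:
    """Recover the minor-state population from noisy synthetic PRE data.

    One pair of state ensembles generates the "experimental" profiles;
    an independently sampled pair supplies the back-calculated state
    profiles used for fitting, so finite-ensemble error enters the fit
    the way it would with real simulations.  The Q-factor of the
    95:5-weighted profile is compared against the open-only profile for
    every noise realisation.
    """
    spec = HingeModelSpec(p_minor=p_minor, seed=seed)
    model = TwoStateModel.from_minor(p_minor)
    base = int(seed) * 101 + 1
    truth_open = single_state_ensemble(spec, "open", n_frames, seed=base)
    truth_minor = single_state_ensemble(spec, "minor", n_frames, seed=base + 1)
    fit_open = single_state_ensemble(spec, "open", n_frames, seed=base + 2)
    fit_minor = single_state_ensemble(spec, "minor", n_frames, seed=base + 3)
    prof_open = pre_mod.ensemble_pre_profile(fit_open, spec.label_site,
                                             spec.h_sites)
    prof_minor = pre_mod.ensemble_pre_profile(fit_minor, spec.label_site,
                                              spec.h_sites)

    p_fits, q_open, q_weighted = [], [], []
    for k in range(n_noise_seeds):
        obs = synthesize_pre_profile(truth_open, truth_minor, model, spec,
                                     seed=base + 10 + k)
        keep = obs["residue_id"]
        po = prof_open[prof_open["residue_id"].isin(keep)] \
            .reset_index(drop=True)
        pm = prof_minor[prof_minor["residue_id"].isin(keep)] \
            .reset_index(drop=True)
        fit = pre_mod.fit_populations([po, pm], obs)
        p_fits.append(fit.p_minor)
        q_open.append(pre_mod.agreement(po, obs)[0])
        weighted = pre_mod.combine_states([po, pm], [0.95, 0.05])
        q_weighted.append(pre_mod.agreement(weighted, obs)[0])

    p_fits = np.array(p_fits)
    q_open = np.array(q_open)
    q_weighted = np.array(q_weighted)
    return PRERecoveryResult(
        p_true=p_minor,
        p_fitted=p_fits,
        median_abs_error=float(np.median(np.abs(p_fits - p_minor))),
        q_open_only=q_open,
        q_weighted=q_weighted,
        improved_fraction=float(np.mean(q_weighted < q_open)),
    )


# --------------------------------------------------------------------------
# boosted vs conventional sampling on the hinge-angle double well
# --------------------------------------------------------------------------

@dataclass
class TransitionStudyResult:
    unboosted_transitions: np.ndarray
    boosted_transitions: np.ndarray
    reweighted_p_open: np.ndarray
    reweighted_se: np.ndarray
    quadrature_p_open: float
    reweight_z_scores: np.ndarray
    unboosted_theta_ranges: list
    boosted_theta_ranges: list

    @property
    def pooled_p_open(self) -> float:
        """Replicate-mean reweighted open population."""
        return float(self.reweighted_p_open.mean())

    @property
    def pooled_se(self) -> float:
        """Standard error from the spread of independent replicates —
        the robust estimate for autocorrelated trajectories."""
        n = len(self.reweighted_p_open)
        return float(self.reweighted_p_open.std(ddof=1) / np.sqrt(n))

    @property
    def pooled_z(self) -> float:
        return abs(self.pooled_p_open - self.quadrature_p_open) \
            / max(self.pooled_se, 1e-12)


def amd_transition_study(seed: int = 0, n_seeds: int = 5,
                         n_steps: int = 60_000,
                         barrier: float = 7.0,
                         tilt: float = 0.05) -> TransitionStudyResult:
    """Conventional vs dual-boost Langevin sampling of hinge closure.

    The hinge angle lives on a tilted double well with minima at the
    semi-closed (146°) and open (160°) angles and a barrier several times
    k_BT, plus one harmonic orthogonal coordinate so the "dual" boost has
    a sub-potential (the angle term) and a total potential to act on.
    Matched step counts; transitions are counted with a 50-step dwell
    filter; boosted runs are reweighted by exp(ΔV/k_BT) and compared with
    Boltzmann quadrature.
    """
    land1d = barrier_calibrated_double_well(barrier, minima=(146.0, 160.0),
                                            tilt=tilt)
    land2d = generate_landscape("double_well_2d",
                                list(land1d.parameters) + [1.0],
                                domain=land1d.domain)
    basins = [(138.0, 150.0), (152.0, 168.0)]
    # thresholds at/above the barrier top; smoothings flatten the wells to
    # an effective residual barrier of ~2 k_BT without inverting them
    amd = dyn.AMDParameters(e_total=barrier + 2.0, alpha_total=0.57 * barrier,
                            e_tors=barrier, alpha_tors=0.21 * barrier)
    p_ref = land1d.populations(300.0)

    n_un, n_bo, p_open, se_open, zs = [], [], [], [], []
    ranges_un, ranges_bo = [], []
    for k in range(n_seeds):
        s = dyn.LangevinSettings(timestep=0.05, friction=1.0,
                                 temperature=300.0, n_steps=n_steps,
                                 seed=int(seed) * 997 + k, x0=(160.0, 0.0))
        plain = dyn.run_langevin(land2d, s)
        boosted = dyn.run_langevin(land2d, s, amd=amd, dual=True)
        n_un.append(dyn.count_transitions(plain.primary, basins, dwell=50))
        n_bo.append(dyn.count_transitions(boosted.primary, basins, dwell=50))
        p, se = dyn.reweight_populations(boosted, basins, temperature=300.0)
        p_open.append(p[1])
        se_open.append(se[1])
        zs.append(abs(p[1] - p_ref[1]) / max(se[1], 1e-12))
        ranges_un.append((float(plain.primary.min()),
                          float(plain.primary.max())))
        ranges_bo.append((float(boosted.primary.min()),
                          float(boosted.primary.max())))

    return TransitionStudyResult(
        unboosted_transitions=np.array(n_un),
        boosted_transitions=np.array(n_bo),
        reweighted_p_open=np.array(p_open),
        reweighted_se=np.array(se_open),
        quadrature_p_open=float(p_ref[1]),
        reweight_z_scores=np.array(zs),
        unboosted_theta_ranges=ranges_un,
        boosted_theta_ranges=ranges_bo,
    )


# --------------------------------------------------------------------------
# forward / reverse ABF PMF recovery
# --------------------------------------------------------------------------

@dataclass
class ABFStudyResult:
    rms_error_forward: float
    rms_error_reverse: float
    hysteresis: float
    barrier_estimate: float
    barrier_true: float
    n_bins: int


def abf_pmf_study(seed: int = 0, n_steps: int = 300_000,
                  barrier: float = 2.0) -> ABFStudyResult:
    """Forward and reverse ABF runs on the calibrated toy barrier.

    Grid spans 4-15 Å in 0.1 Å bins (110 bins) with the 500-samples-per-
    bin linear ramp; one run starts in each basin.  The PMF is compared
    bin-wise against the analytic profile.
    """
    land = barrier_calibrated_double_well(barrier, minima=(6.0, 13.0),
                                          domain=(4.0, 15.0))
    profiles, rms = [], []
    for k, x0 in ((0, 6.0), (1, 13.0)):
        grid = abf_mod.ABFGrid(lower=4.0, upper=15.0, bin_width=0.1)
        s = dyn.LangevinSettings(timestep=0.002, friction=1.0,
                                 temperature=300.0, n_steps=n_steps,
                                 seed=int(seed) * 773 + k, x0=x0,
                                 integrator="overdamped")
        abf_mod.abf_run(land, grid, s)
        profile = abf_mod.integrate_pmf(grid)
        profiles.append(profile)
        rms.append(abf_mod.pmf_rms_error(profile, land))
    barrier_est = float(np.mean([
        p["free_energy"][(p["center"] > 8.0) & (p["center"] < 11.0)].max()
        for p in profiles]))
    return ABFStudyResult(
        rms_error_forward=rms[0],
        rms_error_reverse=rms[1],
        hysteresis=abf_mod.hysteresis_check(*profiles),
        barrier_estimate=barrier_est,
        barrier_true=land.barrier_height(),
        n_bins=110,
    )


# --------------------------------------------------------------------------
# PCA of an open/closed reference set
# --------------------------------------------------------------------------

@dataclass
class PCAStudyResult:
    variance_first_two: float
    cluster_separation_over_sd: float


def xray_cluster_pca_study(seed: int = 0,
                           n_per_cluster: int = 12) -> PCAStudyResult:
    """PCA over synthetic stand-ins for open/closed crystal structures.

    The reference set mixes tight clusters at the open (161°) and closed
    (137°) angles with crystal-scale heterogeneity (0.15 Å coordinate
    jitter, 0.5° angle spread).
    """
    spec = HingeModelSpec(angle_open=161.0, angle_minor=137.0, angle_sd=0.5,
                          jitter_sd=0.15, label_jitter_sd=0.0)
    base = int(seed) * 41 + 1
    open_ens = single_state_ensemble(spec, "open", n_per_cluster, seed=base)
    closed_ens = single_state_ensemble(spec, "minor", n_per_cluster,
                                       seed=base + 1)
    ens = ConformerEnsemble(
        np.concatenate([open_ens.coords, closed_ens.coords]),
        open_ens.atom_meta)
    basis = EnsemblePCA().fit(ens)
    pc1 = basis.transform(ens, 1)[:, 0]
    open_s, closed_s = pc1[:n_per_cluster], pc1[n_per_cluster:]
    gap = abs(open_s.mean() - closed_s.mean())
    within = 0.5 * (open_s.std() + closed_s.std())
    return PCAStudyResult(
        variance_first_two=float(basis.explained_variance_ratio_[:2].sum()),
        cluster_separation_over_sd=float(gap / max(within, 1e-12)),
    )


# --------------------------------------------------------------------------
# interdomain angles of open / closed reference geometries
# --------------------------------------------------------------------------

def reference_angle_standins(tmp_dir=None):
    """θ measured through the full file pipeline on synthetic stand-ins
    built at the open (161°) and closed (137°) crystal angles.

    Noiseless single-frame models are written as PDB and read back, so
    the measurement exercises exactly the path a real multi-model PDB
    would take.  Returns (theta_open, theta_closed) in degrees.
    """
    import tempfile
    from pathlib import Path
    from .ensemble import read_pdb, write_pdb

    spec = HingeModelSpec(angle_open=161.0, angle_minor=137.0,
                          jitter_sd=0.0, label_jitter_sd=0.0, angle_sd=1e-9)
    out = []
    with tempfile.TemporaryDirectory() as td:
        base = Path(tmp_dir or td)
        for state, name in (("open", "open_standin.pdb"),
                            ("minor", "closed_standin.pdb")):
            ens = single_state_ensemble(spec, state, 1, seed=0)
            path = base / name
            write_pdb(ens, path)
            back = read_pdb(path)
            series = interdomain_angle_series(back, partition_from_tags(back))
            out.append(float(series["theta_deg"].iloc[0]))
    return tuple(out)
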