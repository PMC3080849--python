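# Methods

This note documents the models, conventions and numerical choices behind
`hingepre`, in the spirit of a simulation package's model documentation:
what each stage computes, which knobs matter, and what the synthetic
systems do and do not emulate.

## The two-state hinge model

The synthetic generator (`hingepre.synthetic`) represents a two-domain
protein as two rigid caps of beads on spheres (default 15 beads each,
radius 15 Å) whose centres sit 20 Å from a common hinge.  Closure is a
pure rotation of the C-terminal cap about an axis through the hinge
perpendicular to the NTD–hinge–CTD plane, so the interdomain angle θ —
the vertex angle at the hinge-region centre of mass between the two
domain centres of mass — is the model's single conformational coordinate.
Per frame, the state is Bernoulli(p_minor) and θ is normal around the
state mean (defaults: open 160°, semi-closed 146°, SD 2°, p_minor 0.05,
mirroring the ~95:5 open/semi-closed picture of ligand-free
maltose-binding protein; the semi-closed mean is a choice within the
146–148° range simulations report, not a sharp constant).  Every bead
receives isotropic N(0, 0.6 Å) jitter; the caps are exactly recentred so
the tagged beads' centre of mass sits at the cap centre and measured
angles are unbiased estimates of the drawn ones.

The spin label is a dedicated bead tethered 4 Å beyond the NTD surface
(domain tag OTHER — it is not backbone and does not enter the NTD centre
of mass).  Its orientation is chosen deterministically as the cleft-facing
direction that maximises the open↔minor contrast in Σ⟨r⁻⁶⟩ over the CTD
beads, subject to a 10 Å clash floor in the minor state — emulating the
experimental practice of placing the label where it reports on domain
closure.  The label carries extra independent N(0, 1.5 Å) wobble, which
is what makes S² < 1 controllable.  Random-stream order is fixed (states,
then angles, then bead jitter, then label wobble) so fixtures are stable
under a seed.

What the generator does **not** emulate: side chains, sequence, solvent,
anisotropic domain shapes, correlated internal motions, and the coupling
of internal motion to tumbling.  Passing tests therefore demonstrate the
correctness and sensitivity of the estimators under the stated two-state
geometry, not the atomistic fidelity of any particular protein.

## Interdomain geometry

Centres of mass default to unit masses (centroids); standard atomic
masses are available by flag, since the mass convention is not fixed by
any of the quantities we compare against.  The arccosine argument is
clamped to [−1, 1]; angles are reported in degrees.  Superposition is
Kabsch (SVD with a determinant correction enforcing a proper rotation);
colinear fit sets are rejected.  Residue-pair distances use Cα atoms by
default and report the population SD (ddof = 0), documented because a
two-frame series at 2 and 4 Å then prints mean 3, SD 1.  Domain
partitions are always configuration (YAML of inclusive residue ranges);
a conventional maltose-binding-protein split ships as package data, with
the caveat that θ shifts by ~1–2° under alternative hinge definitions.

## PCA

Frames are superposed onto an iteratively refined mean structure (2
iterations; removes dependence on which frame happens to be first), the
covariance of the flattened coordinates uses the population normalisation
(divide by N), and eigenvector signs are fixed by making the
largest-magnitude loading positive so projections are reproducible.  On a
reference set mixing tight clusters at the open (161°) and closed (137°)
crystal angles with 0.15 Å coordinate heterogeneity, the closure mode
dominates and the first two components capture >95% of the variance; with
looser (simulation-scale) jitter the captured fraction drops, which is a
property of the variance budget, not of the estimator.

## Boosted Langevin sampling

The boost is ΔV(V) = (E−V)²/(α+E−V) below the threshold E (zero above),
giving a boosted surface that is continuous and once-differentiable at
V = E with force scale (α/(α+E−V))².  "Dual boost" applies a secondary
boost to the hinge-angle term alone and the total boost to the
already-boosted full potential — the closest toy analogue of
total + torsional boosting.  The integrator is BAOAB-split underdamped
Langevin (overdamped Euler–Maruyama by flag); k_B = 1.9872 × 10⁻³
kcal mol⁻¹ K⁻¹, unit mass, reduced time.  Boosted step counts are never
mapped to physical time (the effective clock of boosted dynamics is
non-linear); transition counts use debounced basin assignment (default
basins θ ≤ 150° / θ ≥ 152° with a 2° buffer, 50-step dwell).

Reweighting multiplies each visited configuration by exp(ΔV/k_BT)
(log-shifted, so large boosts cannot overflow).  Error bars come from
block averaging within a run; for the replicate protocol the pooled
population uses the spread of 5 independent replicates as its standard
error, which is the robust choice for autocorrelated trajectories —
within-run block SEs can underestimate when blocks remain correlated.

The transition study uses a tilted double well along θ (minima 146°/160°,
barrier 7 kcal/mol ≈ 12 k_BT at 300 K, tilt 0.05 kcal/mol/°) plus one
harmonic orthogonal coordinate so the dual boost has a sub-potential to
act on.  Thresholds sit at/above the barrier top (E_tors = barrier,
E_total = barrier + 2) with smoothings (0.21 and 0.57 × barrier) chosen
so the effective residual barrier is ~2 k_BT: conventional runs of 6×10⁴
steps never cross, boosted runs cross tens of times, and the boost is
small enough that reweighting retains a usable effective sample size.

## ABF

The instantaneous coordinate force (analytic for the toy landscapes — no
constraint-force estimator is needed in 1D) is accumulated per 0.1 Å bin
over 4–15 Å (110 bins); the applied bias is −(running mean force) ×
min(count/500, 1).  The linear ramp is standard practice and smooths the
early dynamics relative to a hard threshold.  Grid boundaries are
reflective and reflections are counted, never silently dropped.  The PMF
is the trapezoidal integral of −(mean force) over bin centres, anchored
to min = 0; empty bins raise a gap error listing them.  Forward/reverse
hysteresis is the maximum |difference| over commonly sampled bins after
re-anchoring both profiles at the forward profile's minimum-free-energy
bin, so a constant offset does not register.  On the calibrated
2 kcal/mol double well (minima 6 and 13 Å) 3×10⁵ steps per direction
recover the analytic PMF to ~2×10⁻³ kcal/mol RMS.

## SBMF PRE back-calculation

Distances stay in Å at every interface; conversion to SI happens once
inside the Γ₂ prefactor, guarded by a sentinel that rejects inputs that
look like m⁻⁶.  Constants are CODATA (g = 2.00231930,
γ_I = 2.6752218744×10⁸ rad s⁻¹ T⁻¹, μ_B = 9.2740100783×10⁻²⁴ J T⁻¹,
s = ½).  The proton Larmor frequency comes from the spectrometer field,
default B₀ = 14.1 T (600 MHz ¹H) — a configuration choice, stated
explicitly wherever quantitative agreement is claimed.  The rotational
correlation time defaults to τ_r = 20 ns (Stokes–Einstein scale for a
~40 kDa protein at 300 K) and the electron relaxation time τ_s is ignored
by default (τ_c = τ_r), the standard assumption when τ_s greatly exceeds
tumbling; a finite-τ_s mode implements the full composition rules
1/τ_c = 1/τ_r + 1/τ_s, 1/τ_t = 1/τ_c + 1/τ_i.

S² uses the rank-2, r⁻³-weighted model-free definition, computed through
the Cartesian identity S²⟨r⁻⁶⟩ = (3/2)Σ_ij⟨e_i e_j r⁻³⟩² − (1/2)⟨r⁻³⟩²
(equivalent to the spherical-harmonic form, and verified against the
wobble-in-cone closed form [cosβ(1+cosβ)/2]² and the isotropic limit).
τ_i comes from a single-exponential fit of (C(t)−S²)/(C(0)−S²) over the
first 20% of lags of the internal rank-2 correlation function; for
time-uncorrelated (independently drawn) ensembles the internal time is a
model parameter (default 0.5 ns) rather than a fitted one.  Near-rigid
vectors report a lower bound with a warning instead of a spurious fit.

Two-state weighting averages rates linearly (Γ₂ is linear in the
spectral density, and population averaging of rates is the fast-exchange
limit); whether profile-level averaging of intensity ratios would differ
materially is a known ambiguity, and rate averaging is the documented
choice.  Agreement is the Q-factor Q = √(Σ(Γ_calc−Γ_obs)²/ΣΓ_obs²) plus
the Pearson correlation.  Population fitting scans p_minor on a 0.005
grid with parabolic refinement of the bracketed minimum; indistinguishable
state profiles yield a flat misfit and a degeneracy flag.

The synthetic "experimental" profile is the population-weighted mean of
the two state profiles plus N(0, 2 s⁻¹) noise — the few-per-second scale
of experimental PRE uncertainties — with label-proximal sites whose
noiseless rate exceeds 150 s⁻¹ dropped, mimicking resonances broadened
beyond detection.  The recovery protocol generates the observed profiles
from one pair of ensembles and fits with profiles from an independently
sampled pair, so finite-ensemble error enters the fit realistically.

## MM-PBSA bookkeeping

Derived columns are always recomputed from base terms, never trusted from
input: PROT = ELE+VDW+INT, SOLV = PBSUR+PBCAL, PBTOT = PROT+SOLV.  The
packaged reference table's printed arithmetic satisfies PROT+SOLV exactly
for the open conformer, which is why PBTOT excludes the entropy column by
default; `include_ts=True` folds TS in for tables that define the total
that way.  Statistical-error rows combine in quadrature.  Note that the
reference table's semi-closed row is internally inconsistent at the last
printed decimal (its base terms sum to PROT = −507.0 against a printed
−506.7), so derived values recomputed from base terms can differ from
printed ones by ~0.1–0.3 kcal/mol; the package always reports the
recomputed arithmetic.  Population ↔ ΔG conversion uses the two-level
Boltzmann form p_minor = 1/(1+exp(ΔG/RT)) with R in kcal mol⁻¹ K⁻¹ and a
300 K default; the two directions are exact mutual inverses.

## Problem sizes

The reference protocols run on one core in well under a minute total:
200-frame ensembles and 100 noise realisations for the PRE recovery,
5 replicates × 6×10⁴ steps for the transition study, 3×10⁵ steps per ABF
direction, 24 structures for the PCA study.  These sizes keep Monte-Carlo
errors an order of magnitude inside the tolerances the results are judged
against; all of them are plain function arguments and scale up linearly.

## Known limitations

* The hinge model's closure is strictly planar and rigid; it cannot probe
  twist modes or intra-domain rearrangements.
* τ_i estimation assumes a single internal exponential and decoupling
  from tumbling; multi-timescale internal motion will bias it toward the
  dominant decay.
* The boosted-sampling layer makes no kinetic claims; only reweighted
  equilibrium populations are meaningful.
* Real-structure angle checks require user-supplied PDB files; the
  shipped domain partition follows the conventional split but angle
  values shift by ~1–2° under alternative hinge definitions.
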