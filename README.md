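# hingepre

Analysis toolkit for **pre-existing two-state hinge-bending equilibria** in
two-domain proteins, built around the prototype case of a periplasmic
binding protein whose ligand-free form exchanges between a major open state
(~95%) and a minor semi-closed state (~5%).  The package provides every
computational stage needed to characterise such an equilibrium at desk
scale and to confront it with NMR paramagnetic relaxation enhancement
(PRE) data:

* **Synthetic two-state ensembles** — a coarse-grained two-domain model
  whose interdomain angle θ is drawn from a two-component normal mixture
  (open ≈ 160°, semi-closed ≈ 146°, 95:5), with a cleft-facing spin-label
  bead and positional jitter producing realistic order parameters S² < 1.
* **Geometry** — Kabsch superposition and RMSD, the interdomain closure
  angle θ (vertex angle at the hinge-region centre of mass between the two
  domain centres of mass), and residue-pair distances over multi-model PDB
  ensembles.
* **PCA** — principal components of superposed coordinate ensembles; for
  open/closed crystal-structure sets the first two components capture the
  closure mode.
* **Boosted sampling** — Langevin dynamics on toy landscapes with the
  accelerated-MD "dual boost" bias ΔV(V) = (E−V)²/(α+E−V) for V < E, force
  scale (α/(α+E−V))², and exp(ΔV/k_BT) reweighting back to canonical
  statistics.
* **ABF** — adaptive-biasing-force estimation of a 1D potential of mean
  force with the min(count/500, 1) linear ramp and reflective grid
  boundaries.
* **MM-PBSA bookkeeping** — derived sums (PROT = ELE+VDW+INT,
  SOLV = PBSUR+PBCAL, PBTOT = PROT+SOLV), conformer ΔG with error
  propagation, Boltzmann population ↔ ΔG conversion, and per-residue
  decomposition ranking over term tables (no PB/GB solving).
* **PRE back-calculation** — Solomon–Bloembergen model-free (SBMF)
  transverse rates

  Γ₂ = (1/15)(μ₀/4π)² γ_I² g² μ_B² s(s+1) [4 J(0) + 3 J(ω_I)],
  J(ω) = ⟨r⁻⁶⟩ [ S² τ_c/(1+(ωτ_c)²) + (1−S²) τ_t/(1+(ωτ_t)²) ],

  with ⟨r⁻⁶⟩, S² (rank-2, r⁻³-weighted) and τ_i estimated per residue from
  ensembles, 1/τ_t = 1/τ_c + 1/τ_i, two-state population weighting,
  Q-factor agreement scoring and grid fitting of the minor-state
  population.

## Worked example

The `demo` subcommand runs the core loop — generate open and semi-closed
ensembles, back-calculate per-state Γ₂ profiles, synthesise a noisy
"experimental" profile at a 95:5 population ratio, and fit the minor
population back:

```text
$ hingepre demo --seed 1 --frames 200
true p_minor      : 0.050
fitted p_minor    : 0.044
Q (open only)     : 0.3424
Q (95:5 weighted) : 0.1087
```

The fitted minor population recovers the generating 5% within the
expected ±0.02 band, and the Q-factor of the 95:5-weighted profile is ~3×
smaller than the open-only profile — the signature that the observed PRE
carries the footprint of a lowly-populated, more compact state.

The free-energy side of the same statement:

```text
$ hingepre energy pop --dg 1.7554 --temp 300
p_minor = 0.0500 at 300 K (dG = 1.7554 kcal/mol)
```

i.e. a 95:5 split corresponds to ΔG = RT ln 19 ≈ 1.75 kcal/mol ("about
2 kcal/mol" at integer precision).

Other entry points: `gen-ensemble`, `gen-landscape`, `angle`, `rmsd`,
`distance`, `pca build/project`, `simulate` (boosted/unboosted hinge
sampling), `abf run/pmf/hysteresis`, `pre calc/combine/q/fit`,
`energy totals/delta/pop`.  See `hingepre <command> --help`.

## Scope notes

The package operates on coordinate ensembles, term tables and toy
landscapes; it does not run all-atom MD, solve Poisson–Boltzmann /
Generalized Born equations, build spin-label rotamers, or fetch
structures from the PDB.  Real multi-model PDB files (e.g. downloaded
crystal structures) are accepted by every geometric stage; a
maltose-binding-protein domain partition in the conventional
NTD/hinge/CTD split ships as `hingepre/data/mbp_partition.yaml`.
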