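# Methods

This note records the models implemented, the defaults and why they
were chosen, the numerical choices that affect results, and what the
synthetic-data generator does and does not emulate.

## Energy model and data format

All analysis consumes a flat CSV of per-snapshot energy components
keyed by `(ligand_id, system_kind, source, replica, frame)`, energies in
kcal/mol. `system_kind` ∈ {complex, receptor, ligand} identifies the
molecular system; `source` ∈ {complex, independent} identifies the
trajectory the snapshot's coordinates came from (receptor/ligand
energies re-evaluated on complex-trajectory frames vs. separate
simulations). Replica indices are 1-based, frame indices 0-based —
stated once to avoid off-by-one drift against common MD tooling.
Writing uses 17 significant digits so write→read round-trips are exact.

The per-snapshot free energy is `E_int + E_ele + E_vdW + G_pol +
G_nonpol`. The headline ΔG_MMPBSA **excludes** the nonpolar term by
default (`include_nonpolar=False`): published component tables in this
area tabulate the nonpolar term separately from the MMPBSA total, and
making the convention an explicit flag is safer than guessing. The flag
only shifts ΔG by the nonpolar breakdown term; it never changes
rankings produced from a single convention.

With `strict=False` the reader tolerates a missing `g_nonpol` column
(filled with zero, warned) and keeps the first of duplicated keys;
`strict=True` refuses both.

## Protocols

Per replica r, `ΔG_r = ⟨G_complex⟩_r − R_r − L_r` where each ⟨·⟩_r is
the frame average within that replica. Frames are averaged first and
replicas second because replicas — independent initial-velocity draws —
are the independent sampling unit; all bootstrap uncertainties resample
replica averages (default 5000 resamples, seeded `numpy` Generator, SE
= SD over resamples with ddof=1).

Source selection per protocol:

| protocol | receptor term | ligand term |
|----------|---------------|-------------|
| 1traj    | from complex, per replica | from complex, per replica |
| 1traj-ar | constant (complex-derived, averaged over the comparable set) | from complex |
| 2traj-fr | constant (independent receptor ensemble) | from complex |
| 2traj-fl | from complex, per replica | independent, per replica |
| 2traj-ar | constant (complex-derived) | independent |
| 3traj    | constant (independent) | independent |

Design choices:

- **Constant receptor terms.** The receptor is the same protein for
  every ligand, so both the cross-ligand average of complex-derived
  receptor energies and an independent receptor ensemble enter ΔG as a
  single ligand-independent constant. Both constants are computed by
  the same aggregation (per ligand: replica-averaged receptor energy;
  then an equal-weight mean over the comparable set), differing only in
  the `source` they read. Consequently ranking statistics are identical
  between 1traj-ar/2traj-fr and between 2traj-ar/3traj whenever the two
  sources contain the same records — bitwise identical in this
  implementation, since the ΔG vectors then share every float.
  `comparable_set` defaults to all ligands present at invocation.
- **1traj pairing.** Complex-derived legs are differenced per
  (replica, frame) when frames align (`pairing="frame"`, the default),
  which cancels the internal-energy term to machine precision;
  otherwise, and with `pairing="replica"`, per-replica means are
  differenced. Replica means of ΔG are mathematically identical either
  way; only within-replica variances (not reported) differ.
- **Independent legs.** An independent ligand ensemble has no natural
  pairing with complex replicas; replicas are paired positionally in
  sorted order when counts match, else the leg's grand mean is used as
  a constant. Pairing only relabels terms inside a mean over replicas,
  so ΔG_mean is unaffected.
- With fewer than two replicas every SE is reported as absent (None),
  never zero.

Input validation (`validate_for_protocol`) reports missing
(kind, source) combinations as errors and frame misalignment between
complex-derived legs as warnings, so adding records can never turn a
passing check into a failing one.

## Surface areas

Both kernels operate on spheres expanded by the probe radius (default
1.4 Å, the water-probe convention).

- **Lee–Richards** (primary): each expanded sphere is cut into z-bands
  that exactly tile its diameter at spacing ≤ `slice_spacing` (default
  0.25 Å). In each band the exposed arc of the atom's circle is found
  by merging angular occlusion intervals from neighbouring circles; by
  the hat-box theorem the band contributes `exposed_angle · R · dz`.
  The exposed angle has square-root kinks in z where neighbour circles
  appear or vanish, so each band is averaged over 10 sub-planes rather
  than sampled at its midpoint; measured worst-case error on the
  two-sphere closed form is ≈0.3% at the default spacing, and isolated
  spheres are exact to round-off.
- **Shrake–Rupley** (independent cross-check): a deterministic
  golden-angle Fibonacci lattice (default 960 points) on each expanded
  sphere; the accessible fraction of points scales the sphere area.
- **Canonical frame.** Both discretisations are direction-dependent, so
  coordinates are first expressed in the principal axes of the centred
  atom set, with eigenvector signs fixed by third moments. This makes
  results rigid-motion invariant to machine precision and a function of
  internal geometry only. (Mirror images may differ at the
  discretisation level; only proper motions are guaranteed.)
- Degenerate input: an atom entirely inside another's expanded sphere
  gets zero area; for exactly coincident centres with equal radii the
  higher-indexed atom is buried by convention.
- Radii are configuration: a Bondi-style element table ships as a YAML
  fixture (`esmacs/data/bondi_radii.yaml`) and is fully overridable.
  PDB input (Biopython) resolves altlocs to the highest occupancy
  (ties: first encountered) and excludes hydrogens by default, as usual
  for PDB-derived surface areas.

`BSAS_i = 4π(r_i + r_probe)² − SAS_i` (clipped at zero; SAS above the
sphere area beyond a 1e-6 tolerance is a domain error). The nonpolar
solvation term is the one-component model `γ·SASA + β` with γ =
0.00542 kcal mol⁻¹ Å⁻² and β = 0.92 kcal/mol.

## Entropy treatments

All three are reported as −TΔS in kcal/mol so the corrected estimate is
`ΔG + (−TΔS)`; SEs combine in quadrature when both are present.
Defaults: T = 300 K, k_B = 0.0019872041 kcal mol⁻¹ K⁻¹.

- **Normal mode:** ingested from CSV (`ligand_id, minus_t_delta_s[,
  se]`); computing normal modes is out of scope.
- **WSAS:** `S_WSAS = Σ wᵢ(SASᵢ − k·BSASᵢ)` with atom-type weights wᵢ
  and buried-area scale k (default 0.8). The published calibrated
  weights are not reproduced here; the weight table is mandatory user
  configuration with a declared unit (cal/(mol·K) or kcal/(mol·K)), and
  the shipped table is synthetic, for tests and examples only. ΔS on
  binding is `S_complex − S_receptor − S_ligand`, which vanishes
  exactly when binding buries no surface.
- **Variational:** `−TΔS = k_B T ln⟨exp(βΔE)⟩` over mean-centred
  interaction energies `E_inter = ΔE_ele + ΔE_vdW` (complex − receptor
  − ligand under 1traj sourcing). Evaluated as a log-mean-exp
  (shift-by-maximum), so it cannot overflow; it is non-negative by
  Jensen's inequality, exactly zero for constant series (early return),
  and invariant to constant shifts. Default grouping pools all
  snapshots of all replicas — the ensemble average is written over one
  ensemble — with `per_replica` available to attach a replica-level SE.
  Note the estimator's Monte-Carlo error grows like exp((βσ)²/2): at
  300 K the pooled estimate is accurate to a few percent for σ ≈ 1
  kcal/mol with 10⁵ samples, but degrades quickly for σ ≳ 2.

## Ranking statistics

- **Offset-corrected MUE:** mean |eᵢ − ē| of errors eᵢ = predᵢ − exptᵢ.
  End-state estimates carry a large systematic offset (entropy and
  other neglected terms), so the raw MUE would mostly measure that
  offset.
- **Predictive index:** the Pearlman–Charifson pairwise statistic,
  `Σ wᵢⱼ cᵢⱼ / Σ wᵢⱼ` with wᵢⱼ = |exptⱼ − exptᵢ| and cᵢⱼ = ±1 for
  concordant/discordant pairs, 0 for tied predictions. The name
  "predictive index" is used loosely in the literature; this standard
  definition is an interpretation choice and is undefined when all
  experimental values coincide.
- **r² and r_s** from scipy (average ranks on ties); zero variance in
  either vector is an undefined-statistic error, not a silent NaN.
- **Bootstrap:** correlation metrics resample (pred, expt) ligand pairs;
  per-ligand ΔG SEs resample replica averages. Resamples where a
  statistic is degenerate are skipped for that statistic and counted in
  the report.

## Synthetic data

`gen_ensemble` draws `ΔG_rs = ΔG_true + b_r + ε_rs` with b_r ~
N(0, σ_replica²), ε_rs ~ N(0, σ_frame²), partitions it across
(ele, vdw, pol, nonpol) by fixed split weights (0.5/0.3/0.15/0.05) and
embeds it in absolute complex/receptor/ligand records (large,
mostly-cancelling baselines) so that complex − receptor − ligand
reproduces ΔG_rs exactly and the internal-energy difference is zero.
Defaults are 25 replicas × 40 frames (4 ns sampled every 100 ps),
σ_replica = 2 and σ_frame = 4 kcal/mol — a replica-level spread
consistent with the ~10 kcal/mol disagreements reported for
single-trajectory estimates. All noise rides on the complex records;
independent-source records duplicate the complex-derived ones unless
adaptation shifts are requested, so protocol equivalences hold exactly
on generated tables by construction.

What the generator does **not** emulate: frame autocorrelation within a
replica (frames are treated as effectively independent), non-Gaussian
energy distributions, force-field- or solvent-model-specific component
structure, and adaptation energies (beyond the optional constant
shifts). Tests passing on this generator therefore validate the
*aggregation and statistics machinery*, not the physical accuracy of
end-state estimates on real trajectories.

Panel generation (`gen_ligand_panel`) spaces true ΔG evenly over a
default window of −11.0…−3.1 kcal/mol (a typical fragment-to-lead
affinity range) and adds Gaussian experimental noise, giving an
analytic attenuation target var(true)/(var(true)+σ²) for recovered r².

## Problem sizes used in checks

The standing verification suite uses deliberately small inputs chosen
for tight analytic control: single-snapshot tables for worked
arithmetic; 20-atom random clusters (50 of them) for cross-kernel
agreement; 10⁵ Gaussian draws for the variational closed form; 8-ligand
× 5-replica tables for protocol equivalences; and 20 seeded 25-replica
× 40-frame ensembles for ground-truth recovery within 3 bootstrap SEs.

## Known limitations

- The Lee–Richards kernel is a pure-Python loop over atoms × slices ×
  neighbours; it is comfortable for hundreds of atoms, not for whole
  large proteins at high slicing resolution.
- Normal-mode entropies and all MD/PB computations are upstream inputs;
  the toolkit neither runs simulations nor solves the
  Poisson–Boltzmann equation.
- Bootstrap SEs inherit the usual small-N caveats: with few replicas or
  few ligands they understate uncertainty, and degenerate-resample
  counts in the ranking report should be inspected for tiny panels.
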