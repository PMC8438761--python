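# esmacs

Ensemble end-state (MMPBSA) binding free-energy analysis for
protein–ligand systems: trajectory-sourcing protocols over replica
ensembles, surface-area and entropy corrections, and bootstrap-quantified
ligand-ranking statistics.

## The problem

Single-trajectory MMPBSA estimates of a binding free energy are
notoriously irreproducible — repeat simulations started from the same
structure can disagree by ~10 kcal/mol because classical MD trajectories
diverge from their initial conditions. The ensemble approach (ESMACS:
enhanced sampling of molecular dynamics with approximation of continuum
solvent) runs many short replicas, averages within each replica and then
over replicas, and attaches a bootstrap uncertainty to every quantity by
resampling replica averages. This package implements the *analysis*
layer of that approach: it consumes per-snapshot energy components (the
MD and Poisson–Boltzmann computations happen upstream) and produces
per-ligand free energies, component decompositions, entropy corrections
and ranking statistics. It is aimed at practitioners post-processing
ensemble MMPBSA runs and at method developers who need a controlled,
synthetic-data test bed.

## The model

Per snapshot, the MMPBSA free energy splits into five components
(kcal/mol):

```
G = E_int + E_ele + E_vdW + G_pol + G_nonpol
```

and the binding free energy is the ensemble-averaged difference

```
ΔG = ⟨G_complex⟩ − ⟨G_receptor⟩ − ⟨G_ligand⟩
```

Six protocols differ in where receptor/ligand snapshots come from: the
complex trajectory itself (`1traj`), independent simulations
(`2traj-fl`, `2traj-fr`, `3traj`), or a constant receptor term averaged
across a set of comparable ligands (`1traj-ar`, `2traj-ar`). Because a
constant receptor term is a ligand-independent shift, protocols sharing
it produce identical correlation statistics.

On top of ΔG_MMPBSA three entropy treatments are provided, each reported
as a −TΔS term: ingested normal-mode values; weighted solvent-accessible
surface area, `S_WSAS = Σᵢ wᵢ(SASᵢ − k·BSASᵢ)` with per-atom SAS from a
Lee–Richards kernel (a Shrake–Rupley kernel serves as an independent
cross-check) and `BSASᵢ = 4π(rᵢ+r_probe)² − SASᵢ`; and the variational
entropy `−TΔS = k_B T ln⟨exp(βΔE_inter)⟩` from fluctuations of the
receptor–ligand interaction energy `E_inter = ΔE_ele + ΔE_vdW`.

Ranking against experiment uses the offset-corrected mean unsigned
error, the Pearlman–Charifson predictive index, Pearson r² and Spearman
r_s, all with bootstrap standard errors (default 5000 resamples).

## Worked example

`python examples/decompose_worked_row.py` builds one-snapshot tables
from per-ligand component means and aggregates them under `1traj`:

```
  ligand       ele      vdw      pol   nonpol  dG_MMPBSA  dG(+nonpol)
  LDHA14     -7.38   -20.20    16.95    -2.09     -10.63       -12.72
  LDHA21   -380.30   -24.95   361.13    -3.23     -44.12       -47.35
  LDHA26   -410.61   -56.23   403.40    -5.89     -63.44       -69.33
```

The headline `dG_MMPBSA` is `ele + vdw + pol`; the separately tabulated
nonpolar term is added only when `include_nonpolar=True`. The pattern —
large attractive electrostatics mostly cancelled by a polar-solvation
penalty — is typical of charged binders.

`python examples/run_protocols.py` generates a 4-ligand, 25-replica
synthetic ensemble with known true ΔG and recovers it under all six
protocols, e.g. `LIG01: dg_mean = -11.24 ± 0.36` for a true value of
−11.00 (the bootstrap SE reflects the generated 2 kcal/mol
replica-level spread). The other examples exercise the surface-area
kernels against closed forms, the three entropy corrections, and the
ranking statistics on a noisy 22-ligand panel.

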