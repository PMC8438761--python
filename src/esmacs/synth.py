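"""Synthetic inputs with the statistical structure the analysis assumes.

Real ensemble MMPBSA data are replica-structured: independent replicas
of the same system differ by a replica-level mean shift (different
regions of conformational space) on top of frame-to-frame noise.  The
generator here emulates exactly that with a two-level Gaussian model:

    dG_rs = dG_true + b_r + eps_rs,   b_r ~ N(0, sigma_replica^2),
                                      eps_rs ~ N(0, sigma_frame^2)

The per-snapshot difference is partitioned across the electrostatic,
van der Waals, polar and nonpolar components by fixed split weights and
embedded in absolute complex/receptor/ligand records such that
complex - receptor - ligand reproduces dG_rs exactly.  Both
complex-derived and independent receptor/ligand records are emitted
(identical by default; optional adaptation shifts make them differ).

Defaults mirror a standard ensemble protocol: 25 replicas, 40 frames
per replica (4 ns of production sampled every 100 ps), replica-level
spread of 2 kcal/mol and frame-level spread of 4 kcal/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .energy_io import EnsembleTable
from .sasa import Atom, AtomSet

#: share of the binding signal carried by each component (cosmetic: it
#: only affects breakdown tests, not totals)
DEFAULT_SPLIT = {"e_ele": 0.5, "e_vdw": 0.3, "g_pol": 0.15, "g_nonpol": 0.05}

# absolute component baselines, kcal/mol; arbitrary but fixed so tables
# look like real (large, mostly-cancelling) end-state energies
_RECEPTOR_BASE = {"e_int": 350.0, "e_ele": -1200.0, "e_vdw": -240.0,
                  "g_pol": -900.0, "g_nonpol": 40.0}
_LIGAND_BASE = {"e_int": 20.0, "e_ele": -15.0, "e_vdw": -5.0,
                "g_pol": -30.0, "g_nonpol": 3.0}

_COMPONENTS = ("e_int", "e_ele", "e_vdw", "g_pol", "g_nonpol")


@dataclass
class EnsembleSpec:
    """Parameters of a synthetic replica-structured energy ensemble."""

    true_dg: Mapping[str, float]
    n_replicas: int = 25
    n_frames: int = 40
    sigma_replica: float = 2.0
    sigma_frame: float = 4.0
    split_weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SPLIT))
    adaptation_receptor: float = 0.0
    adaptation_ligand: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.true_dg:
            raise ValueError("at least one ligand required")
        if self.n_replicas < 1 or self.n_frames < 1:
            raise ValueError("n_replicas and n_frames must be >= 1")
        if self.sigma_replica < 0 or self.sigma_frame < 0:
            raise ValueError("noise SDs must be non-negative")
        total = sum(self.split_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("split weights must sum to 1")
        unknown = set(self.split_weights) - {"e_ele", "e_vdw", "g_pol", "g_nonpol"}
        if unknown:
            raise ValueError(f"unknown split component(s): {sorted(unknown)}")

    @property
    def ligand_ids(self) -> list[str]:
        return sorted(self.true_dg)


def gen_ensemble(spec: EnsembleSpec) -> EnsembleTable:
    """Generate a replica-structured energy table from a spec.

    All noise is carried on the complex records; receptor and ligand
    records are constant baselines, so the 1traj per-frame difference
    recovers dG_rs exactly and the internal-energy difference is zero.
    Independent-source receptor/ligand records duplicate the
    complex-derived ones plus the spec's adaptation shifts (zero by
    default), so with defaults all protocols agree on the same table.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple] = []
    split = {c: spec.split_weights.get(c, 0.0)
             for c in ("e_ele", "e_vdw", "g_pol", "g_nonpol")}

    for lig in spec.ligand_ids:
        dg_true = float(spec.true_dg[lig])
        b = rng.normal(0.0, spec.sigma_replica, size=spec.n_replicas)
        eps = rng.normal(0.0, spec.sigma_frame,
                         size=(spec.n_replicas, spec.n_frames))
        for r in range(spec.n_replicas):
            rep = r + 1
            for f in range(spec.n_frames):
                dg = dg_true + b[r] + eps[r, f]
                cx = {c: _RECEPTOR_BASE[c] + _LIGAND_BASE[c] for c in _COMPONENTS}
                for c, w in split.items():
                    cx[c] += w * dg
                rows.append((lig, "complex", "complex", rep, f,
                             *(cx[c] for c in _COMPONENTS)))
        # receptor/ligand legs: constant baselines, one row per (replica, frame)
        for kind, base, shift in (("receptor", _RECEPTOR_BASE, spec.adaptation_receptor),
                                  ("ligand", _LIGAND_BASE, spec.adaptation_ligand)):
            for src in ("complex", "independent"):
                vals = dict(base)
                if src == "independent" and shift:
                    vals["e_int"] = vals["e_int"] - shift
                for r in range(spec.n_replicas):
                    for f in range(spec.n_frames):
                        rows.append((lig, kind, src, r + 1, f,
                                     *(vals[c] for c in _COMPONENTS)))

    df = pd.DataFrame(rows, columns=["ligand_id", "system_kind", "source",
                                     "replica", "frame", *_COMPONENTS])
    return EnsembleTable(df, metadata={"generator": "gen_ensemble",
                                       "seed": spec.seed})


def gen_gaussian_einter(sigma: float, n: int, seed: int = 0) -> np.ndarray:
    """Seeded Gaussian interaction-energy series (mean 0, SD sigma, kcal/mol)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n < 2:
        raise ValueError("need at least 2 samples")
    return np.random.default_rng(seed).normal(0.0, sigma, size=n)


def gen_toy_structure(kind: str, n_atoms: int = 1, spacing: float = 2.8,
                      radius: float = 1.4, seed: int = 0,
                      element: str = "C") -> AtomSet:
    """Deterministic toy geometries for surface-area fixtures.

    kinds: ``single`` (one atom at the origin), ``dimer`` (two atoms
    along x separated by ``spacing``), ``chain`` (n equally spaced along
    x), ``random_cluster`` (n uniform in a cube of side
    ``spacing * n_atoms**(1/3)``, seeded).
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if kind == "single":
        coords = np.zeros((1, 3))
    elif kind == "dimer":
        coords = np.array([[0.0, 0.0, 0.0], [spacing, 0.0, 0.0]])
    elif kind == "chain":
        coords = np.column_stack([np.arange(n_atoms) * spacing,
                                  np.zeros(n_atoms), np.zeros(n_atoms)])
    elif kind == "random_cluster":
        side = spacing * max(1.0, n_atoms ** (1.0 / 3.0))
        coords = np.random.default_rng(seed).uniform(0.0, side, size=(n_atoms, 3))
    else:
        raise ValueError(f"unknown toy-structure kind {kind!r}")
    atoms = [Atom(name=f"{element}{i + 1}", element=element,
                  coord=c, radius=radius, wsas_type=element)
             for i, c in enumerate(coords)]
    return AtomSet(atoms, label=kind)


def gen_ligand_panel(n_ligands: int, dg_range: tuple[float, float] = (-11.0, -3.1),
                     expt_noise_sd: float = 1.0,
                     seed: int = 0) -> tuple[dict[str, float], dict[str, float]]:
    """A ligand panel with known ground truth and noisy 'experimental' values.

    True dG values are evenly spaced over ``dg_range`` (default spans a
    typical fragment-to-lead affinity window); experimental values add
    Gaussian noise of SD ``expt_noise_sd``.  Returns (true map,
    experimental map) keyed by LIG01..LIGnn.
    """
    lo, hi = dg_range
    if not lo < hi:
        raise ValueError("dg_range must satisfy lo < hi")
    if n_ligands < 3:
        raise ValueError("need at least 3 ligands")
    rng = np.random.default_rng(seed)
    true_vals = np.linspace(lo, hi, n_ligands)
    noise = rng.normal(0.0, expt_noise_sd, size=n_ligands)
    ids = [f"LIG{i + 1:02d}" for i in range(n_ligands)]
    true = {lig: float(v) for lig, v in zip(ids, true_vals)}
    expt = {lig: float(v + d) for lig, v, d in zip(ids, true_vals, noise)}
    return true, expt
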