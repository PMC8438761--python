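"""Ensemble binding free-energy aggregation under six trajectory-sourcing protocols.

The binding free energy is the ensemble-averaged difference

    dG = <G_complex> - <G_receptor> - <G_ligand>

where each G is the per-snapshot MMPBSA free energy.  The six protocols
differ only in where receptor and ligand snapshots come from:

============  =========  ==================  ==================
protocol      complex    receptor            ligand
============  =========  ==================  ==================
1traj         complex    from complex        from complex
1traj-ar      complex    constant (complex)  from complex
2traj-fr      complex    constant (indep.)   from complex
2traj-fl      complex    from complex        independent
2traj-ar      complex    constant (complex)  independent
3traj         complex    constant (indep.)   independent
============  =========  ==================  ==================

"constant" means a single receptor value shared by all ligands in the
comparable set: the receptor is the same protein for every ligand, so
its independently-simulated (or cross-ligand averaged) contribution is a
ligand-independent shift.  That makes correlation-based ranking
statistics identical between 1traj-ar/2traj-fr and between
2traj-ar/3traj whenever the two constants derive from the same records.

Averaging order: frames are averaged within each replica first, then
replicas are averaged; replicas are the independent sampling unit, so
the bootstrap standard error resamples replica averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .energy_io import COMPONENT_COLUMNS, EnergyComponents, EnsembleTable
from .errors import ProtocolInputError

#: (source, treatment) of the receptor and ligand legs per protocol.
#: treatment "per_replica" pairs replica averages with the complex
#: replicas; "constant" uses one shared value for the comparable set.
PROTOCOL_SOURCES: dict[str, dict[str, tuple[str, str]]] = {
    "1traj":    {"receptor": ("complex", "per_replica"),
                 "ligand": ("complex", "per_replica")},
    "1traj-ar": {"receptor": ("complex", "constant"),
                 "ligand": ("complex", "per_replica")},
    "2traj-fr": {"receptor": ("independent", "constant"),
                 "ligand": ("complex", "per_replica")},
    "2traj-fl": {"receptor": ("complex", "per_replica"),
                 "ligand": ("independent", "per_replica")},
    "2traj-ar": {"receptor": ("complex", "constant"),
                 "ligand": ("independent", "per_replica")},
    "3traj":    {"receptor": ("independent", "constant"),
                 "ligand": ("independent", "per_replica")},
}

PROTOCOL_NAMES = tuple(PROTOCOL_SOURCES)

#: breakdown key -> table column
_BREAKDOWN = {"ele": "e_ele", "vdw": "e_vdw", "pol": "g_pol",
              "nonpol": "g_nonpol", "int": "e_int"}

DEFAULT_N_BOOT = 5000


@dataclass(frozen=True)
class ProtocolSpec:
    """Which protocol to run and with what conventions.

    ``include_nonpolar`` controls whether the nonpolar solvation term
    enters the headline dG (it is always reported in the breakdown);
    the default False matches the convention in which the nonpolar term
    is tabulated separately from the MMPBSA total.  ``comparable_set``
    is the ligand set over which constant receptor terms are averaged;
    None means all ligands present at invocation.
    """

    name: str
    include_nonpolar: bool = False
    comparable_set: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.name not in PROTOCOL_SOURCES:
            raise ValueError(
                f"unknown protocol {self.name!r}; expected one of {PROTOCOL_NAMES}")
        if self.comparable_set is not None and len(self.comparable_set) == 0:
            raise ValueError("comparable_set must be non-empty when given")

    @property
    def sources(self) -> dict[str, tuple[str, str]]:
        return PROTOCOL_SOURCES[self.name]

    def resolve_comparable(self, table: EnsembleTable) -> tuple[str, ...]:
        if self.comparable_set is not None:
            return tuple(self.comparable_set)
        return tuple(table.ligand_ids)


@dataclass(frozen=True)
class ComponentStat:
    mean: float
    se: float | None


@dataclass
class ProtocolResult:
    """Per-ligand binding free energy with replica statistics."""

    ligand_id: str
    protocol: str
    include_nonpolar: bool
    replica_dg: np.ndarray
    dg_mean: float
    dg_se: float | None
    breakdown: dict[str, ComponentStat]
    n_replicas: int = field(default=0)

    def __post_init__(self) -> None:
        self.replica_dg = np.asarray(self.replica_dg, dtype=float)
        if not self.n_replicas:
            self.n_replicas = len(self.replica_dg)


def snapshot_free_energy(c: EnergyComponents, include_nonpolar: bool = False) -> float:
    """Single-snapshot MMPBSA free energy: e_int + e_ele + e_vdw + g_pol (+ g_nonpol)."""
    total = c.total(include_nonpolar=include_nonpolar)
    if not math.isfinite(total):
        raise ValueError("non-finite snapshot free energy")
    return total


def _replica_component_means(table: EnsembleTable, ligand_id: str,
                             system_kind: str, source: str) -> pd.DataFrame:
    """Frame-averaged components per replica; index replica, one column per component."""
    sel = table.select(ligand_id, system_kind, source)
    if sel.empty:
        raise ProtocolInputError(
            f"no {system_kind}/{source} records for ligand {ligand_id!r}")
    return sel.groupby("replica", sort=True)[list(COMPONENT_COLUMNS)].mean()


def receptor_constant_components(table: EnsembleTable, comparable_set: Sequence[str],
                                 source: str = "complex") -> pd.Series:
    """Per-component receptor constant: mean over ligands of replica-averaged values.

    Each ligand contributes with equal weight (its own replica average),
    not each frame, so ligands with longer trajectories do not dominate.
    """
    if len(comparable_set) == 0:
        raise ValueError("comparable_set must not be empty")
    per_ligand = []
    for lig in comparable_set:
        means = _replica_component_means(table, lig, "receptor", source)
        per_ligand.append(means.mean(axis=0))
    return pd.concat(per_ligand, axis=1).mean(axis=1)


def receptor_constant(table: EnsembleTable, comparable_set: Sequence[str],
                      include_nonpolar: bool = False,
                      source: str = "complex") -> float:
    """Scalar receptor constant (summed components) for '-ar'-style protocols."""
    comps = receptor_constant_components(table, comparable_set, source=source)
    cols = ["e_int", "e_ele", "e_vdw", "g_pol"] + (["g_nonpol"] if include_nonpolar else [])
    return float(comps[cols].sum())


def _leg_replica_values(table: EnsembleTable, ligand_id: str, system_kind: str,
                        source: str, complex_replicas: pd.Index) -> pd.DataFrame:
    """Per-replica component means for a leg, aligned with the complex replicas.

    Complex-derived legs share replica indices with the complex and are
    aligned on them.  Independent legs are their own simulations: their
    replicas are paired with the complex replicas positionally (sorted
    order) when counts match, otherwise the leg's grand mean is used as
    a constant for every complex replica.
    """
    means = _replica_component_means(table, ligand_id, system_kind, source)
    if source == "complex":
        try:
            return means.loc[complex_replicas]
        except KeyError as exc:
            raise ProtocolInputError(
                f"{system_kind}/complex records for ligand {ligand_id!r} lack "
                f"replicas present in the complex trajectory") from exc
    if len(means) == len(complex_replicas):
        aligned = means.copy()
        aligned.index = complex_replicas
        return aligned
    grand = means.mean(axis=0)
    return pd.DataFrame([grand] * len(complex_replicas), index=complex_replicas)


def _per_replica_deltas(table: EnsembleTable, protocol: ProtocolSpec,
                        ligand_id: str, pairing: str) -> pd.DataFrame:
    """Per-replica component differences complex - receptor - ligand.

    ``pairing='frame'`` differences complex-derived legs per (replica,
    frame) when frames align, which cancels the internal-energy term to
    machine precision; otherwise (and for ``pairing='replica'``) legs
    are differenced as per-replica frame averages.  The replica means of
    dG are mathematically identical either way.
    """
    if pairing not in ("frame", "replica"):
        raise ValueError("pairing must be 'frame' or 'replica'")
    sources = protocol.sources
    comparable = protocol.resolve_comparable(table)

    cx = table.select(ligand_id, "complex", "complex")
    if cx.empty:
        raise ProtocolInputError(f"no complex records for ligand {ligand_id!r}")
    cx_idx = cx.set_index(["replica", "frame"])[list(COMPONENT_COLUMNS)]
    complex_replicas = cx_idx.index.get_level_values(0).unique().sort_values()

    delta = None
    # per-frame path: subtract complex-derived per-replica legs frame-wise
    frame_legs, replica_legs, constants = [], [], []
    for leg, kind in (("receptor", "receptor"), ("ligand", "ligand")):
        src, treatment = sources[leg]
        if treatment == "constant":
            constants.append(receptor_constant_components(table, comparable, source=src))
        elif src == "complex" and pairing == "frame":
            frame_legs.append(kind)
        else:
            replica_legs.append((kind, src))

    per_frame = cx_idx.copy()
    for kind in frame_legs:
        leg_df = table.select(ligand_id, kind, "complex")
        if leg_df.empty:
            raise ProtocolInputError(
                f"no {kind}/complex records for ligand {ligand_id!r}")
        leg_idx = leg_df.set_index(["replica", "frame"])[list(COMPONENT_COLUMNS)]
        if leg_idx.index.equals(per_frame.index) or set(leg_idx.index) >= set(per_frame.index):
            per_frame = per_frame - leg_idx.loc[per_frame.index]
        else:
            # misaligned frames: fall back to per-replica mean for this leg
            replica_legs.append((kind, "complex"))
    delta = per_frame.groupby(level=0).mean()
    delta = delta.loc[complex_replicas]

    for kind, src in replica_legs:
        leg_means = _leg_replica_values(table, ligand_id, kind, src, complex_replicas)
        delta = delta - leg_means
    for const in constants:
        delta = delta - const
    return delta


def _bootstrap_se(values: np.ndarray, n_boot: int, rng: np.random.Generator) -> float:
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    return float(np.std(values[idx].mean(axis=1), ddof=1))


def bind_free_energy(table: EnsembleTable, protocol: ProtocolSpec | str,
                     ligand_id: str, n_boot: int = DEFAULT_N_BOOT,
                     seed: int = 0, pairing: str = "frame") -> ProtocolResult:
    """Per-ligand binding free energy under one protocol.

    Per replica r, dG_r sums the per-replica component differences of
    :func:`_per_replica_deltas`; ``dg_mean`` is the mean over replicas
    and ``dg_se`` the bootstrap standard error from resampling replica
    averages (``n_boot`` resamples, seeded).  With a single replica the
    standard errors are reported as None, never zero.
    """
    if isinstance(protocol, str):
        protocol = ProtocolSpec(protocol)
    delta = _per_replica_deltas(table, protocol, ligand_id, pairing)
    cols = ["e_int", "e_ele", "e_vdw", "g_pol"]
    if protocol.include_nonpolar:
        cols.append("g_nonpol")
    replica_dg = delta[cols].sum(axis=1).to_numpy()
    dg_mean = float(replica_dg.mean())

    n_rep = len(replica_dg)
    rng = np.random.default_rng(seed)
    breakdown: dict[str, ComponentStat] = {}
    if n_rep >= 2:
        idx = rng.integers(0, n_rep, size=(n_boot, n_rep))
        dg_se = float(np.std(replica_dg[idx].mean(axis=1), ddof=1))
        for key, col in _BREAKDOWN.items():
            vals = delta[col].to_numpy()
            breakdown[key] = ComponentStat(float(vals.mean()),
                                           float(np.std(vals[idx].mean(axis=1), ddof=1)))
    else:
        dg_se = None
        for key, col in _BREAKDOWN.items():
            breakdown[key] = ComponentStat(float(delta[col].mean()), None)

    return ProtocolResult(ligand_id=ligand_id, protocol=protocol.name,
                          include_nonpolar=protocol.include_nonpolar,
                          replica_dg=replica_dg, dg_mean=dg_mean, dg_se=dg_se,
                          breakdown=breakdown, n_replicas=n_rep)


def decompose(table: EnsembleTable, protocol: ProtocolSpec | str, ligand_id: str,
              n_boot: int = DEFAULT_N_BOOT, seed: int = 0,
              pairing: str = "frame") -> dict[str, ComponentStat]:
    """Component breakdown (ele, vdw, pol, nonpol, int) of the binding free energy.

    Components are differenced complex - receptor - ligand under the
    protocol's sourcing; means and bootstrap SEs are over replicas.
    """
    result = bind_free_energy(table, protocol, ligand_id,
                              n_boot=n_boot, seed=seed, pairing=pairing)
    return result.breakdown


def run_protocol(table: EnsembleTable, protocol: ProtocolSpec | str,
                 ligand_ids: Sequence[str] | None = None,
                 n_boot: int = DEFAULT_N_BOOT, seed: int = 0,
                 pairing: str = "frame") -> list[ProtocolResult]:
    """Run one protocol for several ligands (default: all in the table)."""
    if isinstance(protocol, str):
        protocol = ProtocolSpec(protocol)
    ligand_ids = list(ligand_ids) if ligand_ids is not None else table.ligand_ids
    return [bind_free_energy(table, protocol, lig, n_boot=n_boot,
                             seed=seed, pairing=pairing) for lig in ligand_ids]


def results_to_frame(results: Sequence[ProtocolResult]) -> pd.DataFrame:
    """Flatten ProtocolResults to a DataFrame (one ligand per row)."""
    rows = []
    for r in results:
        row: dict[str, object] = {"ligand_id": r.ligand_id, "protocol": r.protocol,
                                  "dg_mean": r.dg_mean, "dg_se": r.dg_se,
                                  "n_replicas": r.n_replicas}
        for key, stat in r.breakdown.items():
            row[f"d_{key}"] = stat.mean
            row[f"d_{key}_se"] = stat.se
        rows.append(row)
    return pd.DataFrame(rows)
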