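"""Entropy corrections to ensemble MMPBSA binding free energies.

Three treatments are supported, each reported as a -T*dS term in
kcal/mol so that the corrected estimate is simply

    dG_corrected = dG_MMPBSA + (-T dS)

1. Normal-mode entropies are expensive external computations; they are
   *ingested* from CSV, never computed here.
2. WSAS (weighted solvent-accessible surface area) approximates the
   configurational entropy from per-atom SAS and buried SAS:
   S_WSAS = sum_i w_i * (SAS_i - k * BSAS_i), with atom-type weights
   w_i and a buried-area scale k.  dS on binding is
   S_complex - S_receptor - S_ligand.
3. Variational entropy derives an entropic penalty from fluctuations of
   the receptor-ligand interaction energy E_inter = dE_ele + dE_vdw:

       -T dS_var = k_B T ln < exp(beta * (E_inter - <E_inter>)) >

   which is non-negative by Jensen's inequality and grows with the
   width of the interaction-energy distribution (for a Gaussian of
   standard deviation sigma it equals beta*sigma^2/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import logsumexp

from .energy_io import EnergyComponents, EnsembleTable
from .errors import (ConfigurationError, DuplicateRecordError, TableFormatError,
                     TableParseError, WeightLookupError)
from .protocols import ProtocolResult
from .sasa import DEFAULT_PROBE, AtomSet, bsas, sasa_lee_richards

BOLTZMANN_KCAL = 0.0019872041  # k_B in kcal/(mol K)

#: accepted spellings of the WSAS weight-table unit declaration and the
#: factor converting declared entropy units to kcal/(mol K)
_UNIT_FACTORS = {
    "kcal/(mol k)": 1.0,
    "kcal/(mol*k)": 1.0,
    "kcal/mol/k": 1.0,
    "cal/(mol k)": 1e-3,
    "cal/(mol*k)": 1e-3,
    "cal/mol/k": 1e-3,
}


@dataclass(frozen=True)
class ThermoParams:
    """Temperature and Boltzmann constant; beta = 1/(k_B T)."""

    temperature: float = 300.0
    k_b: float = BOLTZMANN_KCAL

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")

    @property
    def kt(self) -> float:
        return self.k_b * self.temperature

    @property
    def beta(self) -> float:
        return 1.0 / self.kt


@dataclass
class WSASWeightTable:
    """Atom-type weights, buried-area scale k and unit declaration."""

    weights: dict[str, float]
    k: float = 0.8
    units: str | None = None
    default_weight: float | None = None

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be non-negative")

    def weight(self, wsas_type: str) -> float:
        if wsas_type in self.weights:
            return self.weights[wsas_type]
        if self.default_weight is not None:
            return self.default_weight
        raise WeightLookupError(f"no WSAS weight for atom type {wsas_type!r}")

    def unit_factor(self) -> float:
        """Factor converting declared units to kcal/(mol K)."""
        if self.units is None:
            raise ConfigurationError("WSAS weight table lacks a unit declaration")
        key = self.units.strip().lower().replace("·", " ").replace("·", " ")
        try:
            return _UNIT_FACTORS[key]
        except KeyError:
            raise ConfigurationError(f"unrecognised WSAS unit {self.units!r}") from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WSASWeightTable":
        data = yaml.safe_load(Path(path).read_text())
        return cls(weights={str(k): float(v) for k, v in data["weights"].items()},
                   k=float(data.get("k", 0.8)),
                   units=data.get("units"),
                   default_weight=(None if data.get("default_weight") is None
                                   else float(data["default_weight"])))


@dataclass
class EntropyResult:
    """A -T*dS term (kcal/mol) with its method and optional SE."""

    ligand_id: str
    method: str  # nmode | wsas | variational
    minus_t_delta_s: float
    se: float | None = None

    def __post_init__(self) -> None:
        if self.method == "variational" and self.minus_t_delta_s < 0:
            raise ValueError("variational -T*dS must be non-negative")


@dataclass
class CorrectedEstimate:
    """An entropy-corrected binding free energy."""

    ligand_id: str
    method: str
    dg: float
    se: float | None


# ---------------------------------------------------------------------------
# Variational entropy
# ---------------------------------------------------------------------------

def interaction_energy(dc: EnergyComponents) -> float:
    """Receptor-ligand interaction energy of one snapshot difference.

    ``dc`` holds the complex - receptor - ligand component differences;
    the interaction energy is the sum of the electrostatic and van der
    Waals parts.
    """
    value = dc.e_ele + dc.e_vdw
    if not math.isfinite(value):
        raise ValueError("non-finite interaction energy")
    return value


def interaction_energy_series(table: EnsembleTable, ligand_id: str) -> pd.Series:
    """Per-snapshot interaction energies under 1traj sourcing.

    Returns a Series indexed by (replica, frame) of
    d(e_ele) + d(e_vdw), differenced per aligned (replica, frame).
    """
    legs = {}
    for kind in ("complex", "receptor", "ligand"):
        df = table.select(ligand_id, kind, "complex")
        if df.empty:
            raise ValueError(f"no {kind}/complex records for ligand {ligand_id!r}")
        legs[kind] = df.set_index(["replica", "frame"])[["e_ele", "e_vdw"]]
    delta = legs["complex"] - legs["receptor"] - legs["ligand"]
    if delta.isna().any().any():
        raise ValueError(
            f"complex/receptor/ligand frames misaligned for ligand {ligand_id!r}")
    return (delta["e_ele"] + delta["e_vdw"]).sort_index()


def _variational_core(series: np.ndarray, thermo: ThermoParams) -> float:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("interaction-energy series must be 1-D with length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite interaction energies")
    if x.max() == x.min():
        return 0.0  # no fluctuation, exactly zero penalty
    de = x - x.mean()
    # log-mean-exp: shift-by-maximum inside logsumexp, overflow-free
    val = thermo.kt * (logsumexp(thermo.beta * de) - math.log(len(de)))
    return max(0.0, float(val))


def variational_entropy(e_inter_series, thermo: ThermoParams | None = None,
                        grouping: str = "pooled",
                        ligand_id: str = "") -> EntropyResult:
    """Entropic penalty from interaction-energy fluctuations.

    ``grouping='pooled'`` treats the whole series as one ensemble;
    ``'per_replica'`` evaluates each replica separately (the input must
    then be a mapping replica -> series or a Series with a (replica,
    frame) MultiIndex) and reports the replica mean with its standard
    error.  The result is invariant to adding a constant to the series
    and is zero for a constant series.
    """
    thermo = thermo or ThermoParams()
    if grouping == "pooled":
        if isinstance(e_inter_series, Mapping):
            values = np.concatenate([np.asarray(v, dtype=float)
                                     for v in e_inter_series.values()])
        elif isinstance(e_inter_series, pd.Series):
            values = e_inter_series.to_numpy(dtype=float)
        else:
            values = np.asarray(e_inter_series, dtype=float)
        return EntropyResult(ligand_id, "variational",
                             _variational_core(values, thermo), None)
    if grouping == "per_replica":
        if isinstance(e_inter_series, Mapping):
            groups = {k: np.asarray(v, dtype=float)
                      for k, v in e_inter_series.items()}
        elif isinstance(e_inter_series, pd.Series) and e_inter_series.index.nlevels >= 2:
            groups = {rep: g.to_numpy(dtype=float)
                      for rep, g in e_inter_series.groupby(level=0)}
        else:
            raise ValueError("per_replica grouping needs replica-structured input")
        vals = np.array([_variational_core(v, thermo)
                         for _, v in sorted(groups.items())])
        se = float(vals.std(ddof=1) / math.sqrt(len(vals))) if len(vals) >= 2 else None
        return EntropyResult(ligand_id, "variational", float(vals.mean()), se)
    raise ValueError("grouping must be 'pooled' or 'per_replica'")


# ---------------------------------------------------------------------------
# WSAS entropy
# ---------------------------------------------------------------------------

def wsas_score(atoms: AtomSet, weights: WSASWeightTable,
               probe: float = DEFAULT_PROBE, **sasa_kwargs) -> float:
    """S_WSAS = sum_i w_i (SAS_i - k * BSAS_i), in the table's declared units."""
    sas = sasa_lee_richards(atoms, probe=probe, **sasa_kwargs)
    total = 0.0
    for atom, s in zip(atoms.atoms, sas):
        w = weights.weight(atom.wsas_type)
        total += w * (s - weights.k * bsas(atom, float(s), probe=probe))
    return total


def wsas_entropy(complex_atoms: AtomSet, receptor_atoms: AtomSet,
                 ligand_atoms: AtomSet, weights: WSASWeightTable,
                 thermo: ThermoParams | None = None,
                 probe: float = DEFAULT_PROBE, ligand_id: str = "",
                 **sasa_kwargs) -> EntropyResult:
    """-T * dS_WSAS for binding, with dS = S_complex - S_receptor - S_ligand."""
    thermo = thermo or ThermoParams()
    factor = weights.unit_factor()  # raises if units undeclared
    ds = (wsas_score(complex_atoms, weights, probe=probe, **sasa_kwargs)
          - wsas_score(receptor_atoms, weights, probe=probe, **sasa_kwargs)
          - wsas_score(ligand_atoms, weights, probe=probe, **sasa_kwargs))
    return EntropyResult(ligand_id, "wsas",
                         -thermo.temperature * ds * factor, None)


# ---------------------------------------------------------------------------
# Normal-mode ingestion and correction
# ---------------------------------------------------------------------------

def read_nm_entropy(path: str | Path) -> dict[str, EntropyResult]:
    """Read per-ligand precomputed normal-mode -T*dS values from CSV.

    Columns: ligand_id, minus_t_delta_s [, se]; kcal/mol.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    for col in ("ligand_id", "minus_t_delta_s"):
        if col not in raw.columns:
            raise TableFormatError(f"{path.name}: missing required column {col}")
    out: dict[str, EntropyResult] = {}
    for i, row in raw.iterrows():
        lig = str(row["ligand_id"])
        if lig in out:
            raise DuplicateRecordError(f"{path.name}: duplicate ligand {lig!r}")
        try:
            value = float(row["minus_t_delta_s"])
        except ValueError:
            raise TableParseError(
                f"{path.name}: line {i + 2}: cannot parse "
                f"minus_t_delta_s={row['minus_t_delta_s']!r}") from None
        se: float | None = None
        if "se" in raw.columns and str(row["se"]).strip() != "":
            try:
                se = float(row["se"])
            except ValueError:
                raise TableParseError(
                    f"{path.name}: line {i + 2}: cannot parse se={row['se']!r}") from None
        out[lig] = EntropyResult(lig, "nmode", value, se)
    return out


def apply_entropy_correction(result: ProtocolResult,
                             entropy: EntropyResult) -> CorrectedEstimate:
    """Combine dG_MMPBSA with a -T*dS term (SEs added in quadrature)."""
    if entropy.ligand_id and entropy.ligand_id != result.ligand_id:
        raise ValueError(
            f"ligand mismatch: result is {result.ligand_id!r}, "
            f"entropy is {entropy.ligand_id!r}")
    dg = result.dg_mean + entropy.minus_t_delta_s
    if result.dg_se is not None and entropy.se is not None:
        se: float | None = math.hypot(result.dg_se, entropy.se)
    elif result.dg_se is not None:
        se = result.dg_se
    else:
        se = entropy.se
    return CorrectedEstimate(result.ligand_id, entropy.method, dg, se)
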