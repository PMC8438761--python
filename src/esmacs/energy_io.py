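"""Energy-table data model and I/O.

The whole analysis consumes one flat format: a CSV of per-snapshot
MMPBSA energy components keyed by (ligand, system kind, trajectory
source, replica, frame).  ``system_kind`` says which molecular system a
snapshot belongs to (complex, receptor or ligand); ``source`` says which
simulation its coordinates came from — ``complex`` when receptor/ligand
energies are re-evaluated on complex-trajectory frames, ``independent``
when they come from separate receptor/ligand ensembles.

Energies are kcal/mol throughout.  Replica indices are 1-based, frame
indices 0-based.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DuplicateRecordError, TableFormatError, TableParseError

#: Names of the five energy components, in canonical column order.
COMPONENT_COLUMNS = ("e_int", "e_ele", "e_vdw", "g_pol", "g_nonpol")

#: Key columns identifying a snapshot.
KEY_COLUMNS = ("ligand_id", "system_kind", "source", "replica", "frame")

REQUIRED_COLUMNS = KEY_COLUMNS + COMPONENT_COLUMNS

SYSTEM_KINDS = ("complex", "receptor", "ligand")
SOURCES = ("complex", "independent")


@dataclass(frozen=True)
class EnergyComponents:
    """The five per-snapshot MMPBSA energy terms, kcal/mol.

    ``e_int`` is the molecular-mechanics internal (bond/angle/dihedral)
    energy, ``e_ele`` and ``e_vdw`` the MM electrostatic and van der
    Waals terms, ``g_pol`` the polar (Poisson–Boltzmann) and
    ``g_nonpol`` the nonpolar solvation free energies.
    """

    e_int: float
    e_ele: float
    e_vdw: float
    g_pol: float
    g_nonpol: float

    def __post_init__(self) -> None:
        for name in COMPONENT_COLUMNS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite energy component {name}={v!r}")

    def total(self, include_nonpolar: bool = True) -> float:
        """Sum of components; the nonpolar term is optional (see protocols)."""
        t = self.e_int + self.e_ele + self.e_vdw + self.g_pol
        if include_nonpolar:
            t += self.g_nonpol
        return t


@dataclass(frozen=True)
class SnapshotRecord:
    """One snapshot's energy components with its identifying key."""

    ligand_id: str
    system_kind: str
    source: str
    replica_index: int
    frame_index: int
    components: EnergyComponents

    def __post_init__(self) -> None:
        if self.system_kind not in SYSTEM_KINDS:
            raise ValueError(f"unknown system_kind {self.system_kind!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.system_kind == "complex" and self.source != "complex":
            raise ValueError("complex snapshots can only derive from the complex trajectory")
        if self.replica_index < 1:
            raise ValueError("replica indices are 1-based")
        if self.frame_index < 0:
            raise ValueError("frame indices are 0-based and non-negative")

    @property
    def key(self) -> tuple:
        return (self.ligand_id, self.system_kind, self.source,
                self.replica_index, self.frame_index)


class EnsembleTable:
    """Collection of snapshot records, internally a canonical DataFrame.

    Rows are kept sorted by (ligand_id, system_kind, source, replica,
    frame) so every query is deterministic.
    """

    def __init__(self, df: pd.DataFrame | None = None,
                 metadata: Mapping[str, object] | None = None):
        if df is None:
            df = pd.DataFrame(columns=list(REQUIRED_COLUMNS))
        self._df = _canonicalize(df)
        self.metadata: dict = dict(metadata or {})

    # -- construction ------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[SnapshotRecord],
                     metadata: Mapping[str, object] | None = None,
                     strict: bool = True) -> "EnsembleTable":
        rows = []
        for r in records:
            rows.append((r.ligand_id, r.system_kind, r.source,
                         r.replica_index, r.frame_index,
                         *(getattr(r.components, c) for c in COMPONENT_COLUMNS)))
        df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
        _check_duplicates(df, strict=strict)
        return cls(df, metadata)

    # -- views -------------------------------------------------------
    @property
    def dataframe(self) -> pd.DataFrame:
        """A copy of the canonical table."""
        return self._df.copy()

    def records(self) -> list[SnapshotRecord]:
        out = []
        for row in self._df.itertuples(index=False):
            comps = EnergyComponents(row.e_int, row.e_ele, row.e_vdw,
                                     row.g_pol, row.g_nonpol)
            out.append(SnapshotRecord(row.ligand_id, row.system_kind, row.source,
                                      int(row.replica), int(row.frame), comps))
        return out

    @property
    def ligand_ids(self) -> list[str]:
        return sorted(self._df["ligand_id"].unique())

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnsembleTable):
            return NotImplemented
        return self._df.reset_index(drop=True).equals(other._df.reset_index(drop=True))

    def select(self, ligand_id: str, system_kind: str, source: str) -> pd.DataFrame:
        """Rows for one (ligand, kind, source), sorted by replica then frame."""
        m = ((self._df["ligand_id"] == ligand_id)
             & (self._df["system_kind"] == system_kind)
             & (self._df["source"] == source))
        return self._df.loc[m].reset_index(drop=True)

    def replica_frames(self, ligand_id: str, system_kind: str,
                       source: str) -> dict[int, list[int]]:
        """Mapping replica -> sorted frame list for one (ligand, kind, source)."""
        sel = self.select(ligand_id, system_kind, source)
        return {int(r): sorted(int(f) for f in g["frame"])
                for r, g in sel.groupby("replica", sort=True)}

    def extended(self, records: Iterable[SnapshotRecord]) -> "EnsembleTable":
        """A new table with extra records appended (duplicates rejected)."""
        return EnsembleTable.from_records(self.records() + list(records),
                                          metadata=self.metadata)


def _canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    df["ligand_id"] = df["ligand_id"].astype(str)
    df["system_kind"] = df["system_kind"].astype(str)
    df["source"] = df["source"].astype(str)
    df["replica"] = df["replica"].astype(int)
    df["frame"] = df["frame"].astype(int)
    for c in COMPONENT_COLUMNS:
        df[c] = df[c].astype(float)
    bad_kind = ~df["system_kind"].isin(SYSTEM_KINDS)
    if bad_kind.any():
        raise TableFormatError(
            f"unknown system_kind {df.loc[bad_kind, 'system_kind'].iloc[0]!r}")
    bad_src = ~df["source"].isin(SOURCES)
    if bad_src.any():
        raise TableFormatError(f"unknown source {df.loc[bad_src, 'source'].iloc[0]!r}")
    bad_cx = (df["system_kind"] == "complex") & (df["source"] != "complex")
    if bad_cx.any():
        raise TableFormatError("complex rows must have source=complex")
    return df.sort_values(list(KEY_COLUMNS), kind="mergesort").reset_index(drop=True)


def _check_duplicates(df: pd.DataFrame, strict: bool) -> pd.DataFrame:
    dup = df.duplicated(subset=list(KEY_COLUMNS), keep="first")
    if dup.any():
        first = df.loc[dup, list(KEY_COLUMNS)].iloc[0].tolist()
        if strict:
            raise DuplicateRecordError(f"duplicate snapshot key {tuple(first)}")
        warnings.warn(f"dropping duplicate snapshot key {tuple(first)}", stacklevel=3)
        df.drop(index=df.index[dup], inplace=True)
    return df


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_energy_table(path: str | Path, strict: bool = True) -> EnsembleTable:
    """Read an energy-table CSV.

    With ``strict=False`` a missing ``g_nonpol`` column is tolerated
    (filled with 0 and a warning) and duplicate keys keep their first
    occurrence instead of raising.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]

    required = list(REQUIRED_COLUMNS)
    if "g_nonpol" not in raw.columns and not strict:
        warnings.warn(f"{path.name}: column g_nonpol missing; filled with 0",
                      stacklevel=2)
        raw["g_nonpol"] = "0"
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise TableFormatError(
            f"{path.name}: missing required column(s): {', '.join(missing)}")

    for col in ("replica", "frame") + COMPONENT_COLUMNS:
        try:
            # numpy's parser round-trips floats exactly, unlike to_numeric
            raw[col] = raw[col].to_numpy(dtype=float)
        except ValueError:
            for i, cell in enumerate(raw[col]):
                try:
                    float(cell)
                except ValueError:
                    raise TableParseError(
                        f"{path.name}: line {i + 2}: cannot parse "
                        f"{col}={cell!r}") from None

    df = _check_duplicates(raw, strict=strict)
    table = EnsembleTable(df, metadata={"source_path": str(path), "n_rows": len(df)})
    return table


def write_energy_table(table: EnsembleTable, path: str | Path) -> Path:
    """Write a table as CSV with deterministic row order and full precision.

    Energies are written with 17 significant digits so a write/read
    round-trip is exact.
    """
    path = Path(path)
    df = table.dataframe  # already canonically sorted
    df.to_csv(path, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# Protocol input validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationIssue:
    ligand_id: str
    level: str  # "error" | "warning"
    message: str


@dataclass
class ValidationReport:
    """Per-ligand presence/alignment report for a protocol's data needs."""

    protocol: str
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not any(i.level == "error" for i in self.issues)

    def errors_for(self, ligand_id: str) -> list[ValidationIssue]:
        return [i for i in self.issues if i.ligand_id == ligand_id and i.level == "error"]


def validate_for_protocol(table: EnsembleTable, protocol,
                          ligand_ids: Sequence[str] | None = None) -> ValidationReport:
    """Check that every data source a protocol needs is present.

    Presence of required (system_kind, source) pairs is an error when
    missing; frame misalignment between complex-derived legs is reported
    as a warning (the protocols fall back to per-replica means there).
    Adding records can never turn a passing report into a failing one.
    """
    from .protocols import PROTOCOL_SOURCES, ProtocolSpec  # local: avoid cycle

    if not isinstance(protocol, ProtocolSpec):
        protocol = ProtocolSpec(str(protocol))
    ligand_ids = list(ligand_ids) if ligand_ids is not None else table.ligand_ids
    sources = PROTOCOL_SOURCES[protocol.name]
    report = ValidationReport(protocol=protocol.name)

    for lig in ligand_ids:
        legs = {"complex": ("complex", "complex"),
                "receptor": ("receptor", sources["receptor"][0]),
                "ligand": ("ligand", sources["ligand"][0])}
        present: dict[str, dict[int, list[int]]] = {}
        for leg, (kind, src) in legs.items():
            frames = table.replica_frames(lig, kind, src)
            present[leg] = frames
            if not frames:
                report.issues.append(ValidationIssue(
                    lig, "error", f"missing {kind}/{src} records"))
        # frame alignment only meaningful for complex-derived legs
        cx = present["complex"]
        for leg in ("receptor", "ligand"):
            kind, src = legs[leg]
            if src != "complex" or not present[leg] or not cx:
                continue
            for rep, frames in cx.items():
                other = present[leg].get(rep)
                if other is None:
                    report.issues.append(ValidationIssue(
                        lig, "warning",
                        f"{kind}/complex missing replica {rep} present in complex"))
                elif other != frames:
                    report.issues.append(ValidationIssue(
                        lig, "warning",
                        f"{kind}/complex frames misaligned with complex for "
                        f"ligand {lig} replica {rep}"))
    return report
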