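"""Solvent-accessible surface area (SASA) from atomic coordinates and radii.

Two independent kernels are provided.  The primary one is the
Lee–Richards method: each atom's sphere is expanded by the probe radius
and sliced perpendicular to z; in each slice the exposed arc of the
atom's circle (the part not inside any neighbour's expanded sphere) is
found by interval arithmetic on angles, and by Archimedes' hat-box
theorem each band of thickness dz contributes exposed_angle * R * dz of
spherical area.  The cross-check kernel is Shrake–Rupley: a
deterministic Fibonacci lattice of test points on each expanded sphere,
counting points outside all neighbouring expanded spheres.

Buried SAS (BSAS) of an atom is the remainder of its expanded-sphere
area: BSAS_i = 4*pi*(r_i + r_probe)^2 - SAS_i.

Radii are configuration, not truth: a Bondi-style element table ships
as a default and is fully overridable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import RadiusLookupError

DEFAULT_PROBE = 1.4          # Å, water probe
DEFAULT_SLICE_SPACING = 0.25  # Å, Lee–Richards z-resolution
DEFAULT_N_POINTS = 960        # Shrake–Rupley test points per atom

# One-component nonpolar solvation model parameters, kcal/mol units.
SURFACE_TENSION = 0.00542    # gamma, kcal/(mol Å^2)
SURFACE_OFFSET = 0.92        # beta, kcal/mol


@dataclass
class Atom:
    """An atom with coordinates (Å), radius (Å) and a WSAS atom-type key."""

    name: str
    element: str
    coord: np.ndarray
    radius: float
    wsas_type: str = ""

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValueError(f"atom {self.name}: coordinates must be a finite 3-vector")
        if not (self.radius > 0 and math.isfinite(self.radius)):
            raise ValueError(f"atom {self.name}: radius must be positive")
        if not self.wsas_type:
            self.wsas_type = self.element


@dataclass
class AtomSet:
    """Ordered collection of atoms; order is stable and meaningful."""

    atoms: list[Atom]
    label: str = ""

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def __len__(self) -> int:
        return len(self.atoms)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    label: str | None = None) -> "AtomSet":
        """Rigidly transformed copy (rotation applied before translation)."""
        rot = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        tr = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        atoms = [Atom(a.name, a.element, rot @ a.coord + tr, a.radius, a.wsas_type)
                 for a in self.atoms]
        return AtomSet(atoms, label if label is not None else self.label)


@dataclass
class RadiusTable:
    """Mapping atom-type/element -> radius (Å) with a default probe radius."""

    radii: dict[str, float]
    probe_radius: float = DEFAULT_PROBE

    def __post_init__(self) -> None:
        for key, r in self.radii.items():
            if not r > 0:
                raise ValueError(f"radius for {key!r} must be positive")

    def lookup(self, atom_type: str, element: str, atom_name: str = "") -> float:
        """Radius by atom type first, element as fallback."""
        if atom_type in self.radii:
            return self.radii[atom_type]
        if element in self.radii:
            return self.radii[element]
        raise RadiusLookupError(
            f"no radius for atom {atom_name or atom_type!r} "
            f"(type {atom_type!r}, element {element!r})")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RadiusTable":
        data = yaml.safe_load(Path(path).read_text())
        return cls(radii={str(k): float(v) for k, v in data["radii"].items()},
                   probe_radius=float(data.get("probe_radius", DEFAULT_PROBE)))

    @classmethod
    def default(cls) -> "RadiusTable":
        """The packaged Bondi-style element table."""
        ref = resources.files("esmacs").joinpath("data/bondi_radii.yaml")
        data = yaml.safe_load(ref.read_text())
        return cls(radii={str(k): float(v) for k, v in data["radii"].items()},
                   probe_radius=float(data.get("probe_radius", DEFAULT_PROBE)))


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path, radius_table: RadiusTable | None = None,
             include_hydrogens: bool = False, label: str | None = None) -> AtomSet:
    """Read ATOM/HETATM records into an AtomSet with radii assigned.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties keep the first encountered).  Hydrogens are excluded by
    default, as is usual for PDB-derived SASA.
    """
    from Bio.PDB import PDBParser  # deferred: Bio import is slow

    path = Path(path)
    radius_table = radius_table or RadiusTable.default()
    structure = PDBParser(QUIET=True).get_structure(path.stem, str(path))

    atoms: list[Atom] = []
    for residue in structure.get_residues():
        # group altloc variants of the same atom name, keep best occupancy
        by_name: dict[str, list] = {}
        for at in residue.get_unpacked_list():
            by_name.setdefault(at.get_name(), []).append(at)
        for name, variants in by_name.items():
            best = variants[0]
            for v in variants[1:]:
                occ_v = v.get_occupancy() or 0.0
                occ_b = best.get_occupancy() or 0.0
                if occ_v > occ_b:
                    best = v
            element = (best.element or "").strip().upper() or name[0].upper()
            if not include_hydrogens and element in ("H", "D"):
                continue
            radius = radius_table.lookup(element, element, atom_name=name)
            atoms.append(Atom(name=name, element=element,
                              coord=np.array(best.get_coord(), dtype=float),
                              radius=radius, wsas_type=element))
    if not atoms:
        raise ValueError(f"{path.name}: no atoms selected")
    return AtomSet(atoms, label=label if label is not None else path.stem)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Express coordinates in a rotation/translation-invariant frame.

    Both kernels discretise along fixed directions (z-slices, a fixed
    point lattice), so their small discretisation error would otherwise
    depend on the orientation of the input.  Rotating into the
    principal axes of the centred coordinates makes the result a
    function of the internal geometry only.
    """
    centred = coords - coords.mean(axis=0)
    if len(coords) < 2:
        return centred
    cov = centred.T @ centred
    _, vecs = np.linalg.eigh(cov)  # ascending; slicing axis = widest spread
    proj = centred @ vecs
    # resolve eigenvector sign ambiguity from the third moment so the
    # frame is a deterministic function of the geometry
    for k in range(proj.shape[1]):
        if np.sum(proj[:, k] ** 3) < 0.0:
            proj[:, k] *= -1.0
    return proj


def _expanded(atoms: AtomSet, probe: float) -> tuple[np.ndarray, np.ndarray]:
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    if len(atoms) == 0:
        raise ValueError("cannot compute SASA of an empty atom set")
    coords = atoms.coords
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    return _canonical_frame(coords), atoms.radii + probe


def _burial_flags(coords: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Atoms fully inside another expanded sphere (coincident equal-radius
    pairs bury the higher index by convention)."""
    n = len(R)
    buried = np.zeros(n, dtype=bool)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if d[i, j] < 1e-12 and abs(R[i] - R[j]) < 1e-12:
                if i > j:
                    buried[i] = True
            elif d[i, j] + R[i] <= R[j] + 1e-12:
                buried[i] = True
    return buried


def _exposed_angle(cx: float, cy: float, rho_i: float,
                   occluders: list[tuple[float, float, float]]) -> float:
    """Exposed angle (radians) of a circle of radius rho_i centred at
    (cx, cy) given occluding circles (x, y, rho)."""
    intervals: list[tuple[float, float]] = []
    for (ox, oy, rho_j) in occluders:
        dx, dy = ox - cx, oy - cy
        dist = math.hypot(dx, dy)
        if dist >= rho_i + rho_j:
            continue
        if dist + rho_i <= rho_j:
            return 0.0  # circle fully inside occluder
        if dist + rho_j <= rho_i or rho_j <= 0.0:
            continue  # occluder inside, does not reach the perimeter
        if dist < 1e-300:
            continue
        cos_alpha = (dist * dist + rho_i * rho_i - rho_j * rho_j) / (2.0 * dist * rho_i)
        alpha = math.acos(min(1.0, max(-1.0, cos_alpha)))
        theta = math.atan2(dy, dx)
        intervals.append((theta - alpha, theta + alpha))
    if not intervals:
        return 2.0 * math.pi
    # normalise to [0, 2pi), split wrap-around intervals, merge
    two_pi = 2.0 * math.pi
    segs: list[tuple[float, float]] = []
    for lo, hi in intervals:
        width = hi - lo
        start = lo % two_pi
        end = start + width
        if end <= two_pi:
            segs.append((start, end))
        else:
            segs.append((start, two_pi))
            segs.append((0.0, end - two_pi))
    segs.sort()
    covered = 0.0
    cur_lo, cur_hi = segs[0]
    for lo, hi in segs[1:]:
        if lo > cur_hi:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    covered += cur_hi - cur_lo
    return max(0.0, two_pi - covered)


def sasa_lee_richards(atoms: AtomSet, probe: float = DEFAULT_PROBE,
                      slice_spacing: float = DEFAULT_SLICE_SPACING) -> np.ndarray:
    """Per-atom SASA (Å²) by z-slicing (Lee–Richards).

    Each atom's expanded sphere is cut into bands of thickness at most
    ``slice_spacing`` (bands exactly tile the sphere, so an isolated
    sphere is reproduced to round-off); the exposed angle is evaluated
    at each band's mid-plane.
    """
    if slice_spacing <= 0:
        raise ValueError("slice_spacing must be positive")
    coords, R = _expanded(atoms, probe)
    n = len(R)
    buried = _burial_flags(coords, R)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)

    areas = np.zeros(n)
    for i in range(n):
        if buried[i]:
            continue
        Ri = R[i]
        neighbours = [j for j in range(n)
                      if j != i and not buried[j]
                      and d2[i, j] < (Ri + R[j]) ** 2]
        n_bands = max(1, math.ceil(2.0 * Ri / slice_spacing))
        dz = 2.0 * Ri / n_bands
        # the exposed angle has square-root behaviour where neighbour
        # circles appear/disappear, so each band is averaged over a few
        # sub-planes rather than sampled once at its midpoint
        n_sub = 10
        area = 0.0
        for k in range(n_bands):
            band_exposed = 0.0
            for s in range(n_sub):
                z_loc = -Ri + (k + (s + 0.5) / n_sub) * dz
                rho_i = math.sqrt(max(0.0, Ri * Ri - z_loc * z_loc))
                z_abs = coords[i, 2] + z_loc
                occluders = []
                for j in neighbours:
                    dzj = z_abs - coords[j, 2]
                    rj2 = R[j] * R[j] - dzj * dzj
                    if rj2 <= 0.0:
                        continue
                    occluders.append((coords[j, 0], coords[j, 1], math.sqrt(rj2)))
                if rho_i == 0.0:
                    # pole point: exposed iff not inside any occluder
                    band_exposed += 0.0 if any(
                        math.hypot(coords[i, 0] - ox, coords[i, 1] - oy) < rho
                        for ox, oy, rho in occluders) else 2.0 * math.pi
                else:
                    band_exposed += _exposed_angle(coords[i, 0], coords[i, 1],
                                                   rho_i, occluders)
            area += (band_exposed / n_sub) * Ri * dz
        areas[i] = area
    return areas


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic near-uniform unit vectors (golden-angle spiral)."""
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((rho * np.cos(phi), rho * np.sin(phi), z))


def sasa_shrake_rupley(atoms: AtomSet, probe: float = DEFAULT_PROBE,
                       n_points: int = DEFAULT_N_POINTS) -> np.ndarray:
    """Per-atom SASA (Å²) by deterministic test points (Shrake–Rupley)."""
    if n_points < 32:
        raise ValueError("n_points must be at least 32")
    coords, R = _expanded(atoms, probe)
    n = len(R)
    buried = _burial_flags(coords, R)
    unit = _fibonacci_sphere(n_points)
    d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)

    areas = np.zeros(n)
    for i in range(n):
        if buried[i]:
            continue
        pts = coords[i] + R[i] * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i or buried[j] or d2[i, j] >= (R[i] + R[j]) ** 2:
                continue
            dist2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= dist2 >= R[j] * R[j]
        areas[i] = 4.0 * math.pi * R[i] ** 2 * accessible.mean()
    return areas


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def bsas(atom: Atom, sas: float, probe: float = DEFAULT_PROBE,
         tolerance: float = 1e-6) -> float:
    """Buried SAS: expanded-sphere area minus SAS, clipped at zero."""
    sphere = 4.0 * math.pi * (atom.radius + probe) ** 2
    if sas < 0 or sas > sphere * (1.0 + tolerance) + tolerance:
        raise ValueError(
            f"SAS {sas:.4f} outside [0, {sphere:.4f}] for atom {atom.name}")
    return max(0.0, sphere - sas)


def nonpolar_solvation(total_sasa: float, gamma: float = SURFACE_TENSION,
                       beta: float = SURFACE_OFFSET) -> float:
    """One-component nonpolar solvation term gamma*SASA + beta, kcal/mol."""
    if total_sasa < 0 or not math.isfinite(total_sasa):
        raise ValueError("total SASA must be finite and non-negative")
    return gamma * total_sasa + beta
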