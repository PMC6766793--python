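"""Trajectory, voxel-grid and table I/O.

In-memory containers used throughout the package:

* :class:`Trajectory` — an atom table (:class:`AtomRecord`) plus a dense
  ``(n_frames, n_atoms, 3)`` coordinate array in Å.
* :class:`GridSpec` / :class:`ScalarField` — a regular orthogonal voxel grid
  and a per-voxel scalar, stored flat in OpenDX order (z fastest-varying).

File formats: multi-model PDB (via biotite), plain XYZ, OpenDX scalar grids
(via GridDataFormats), and TSV tables (via pandas). Coordinates are always
Å and times always ps; there is no unit auto-detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from gridData import Grid as _DXGrid

from . import constants as C

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "GridSpec",
    "ScalarField",
    "TrajectoryParseError",
    "GridFormatError",
    "read_trajectory",
    "write_trajectory",
    "read_dx_grid",
    "write_dx_grid",
    "write_table",
    "read_table",
    "assign_roles",
]


class TrajectoryParseError(ValueError):
    """Raised when a trajectory file violates the format contract."""


class GridFormatError(ValueError):
    """Raised for unsupported or inconsistent voxel-grid files."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AtomRecord:
    """One atom of the (constant) topology with analysis role flags."""

    index: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain: str = "A"
    is_backbone: bool = False
    is_water_oxygen: bool = False
    is_ligand: bool = False
    hbond_role: str = "none"  # donor-heavy | acceptor | both | none
    is_apolar: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.index} ({self.name}): empty element")
        if self.hbond_role not in ("donor-heavy", "acceptor", "both", "none"):
            raise ValueError(f"invalid hbond_role {self.hbond_role!r}")
        if self.is_water_oxygen and self.is_ligand:
            raise ValueError(
                f"atom {self.index}: water-oxygen atoms cannot be ligand atoms"
            )


@dataclass(frozen=True)
class Frame:
    """A single snapshot: ``(n_atoms, 3)`` coordinates in Å."""

    coords: np.ndarray
    frame_index: int
    time_ps: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"frame {self.frame_index}: non-finite coordinates")


@dataclass
class Trajectory:
    """Ordered frames over a constant atom table.

    ``coords`` has shape ``(n_frames, n_atoms, 3)``; per-frame views are
    available through :meth:`frame` and iteration.
    """

    atoms: list[AtomRecord]
    coords: np.ndarray
    frame_interval_ps: float = 4.0
    time0_ps: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"coordinate rows ({self.coords.shape[1]}) != atoms ({len(self.atoms)})"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def times_ps(self) -> np.ndarray:
        return self.time0_ps + self.frame_interval_ps * np.arange(self.n_frames)

    def frame(self, i: int) -> Frame:
        return Frame(self.coords[i], i, float(self.times_ps()[i]))

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class GridSpec:
    """Regular orthogonal voxel grid: corner ``origin``, cubic ``spacing``.

    A point belongs to voxel ``i`` iff
    ``origin + i*spacing <= x < origin + (i+1)*spacing`` (half-open), so
    boundary points are never double-counted.
    """

    origin: tuple[float, float, float]
    spacing: float = C.DEFAULT_GRID_SPACING_A
    dims: tuple[int, int, int] = (1, 1, 1)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must be >= 1")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    @property
    def voxel_volume(self) -> float:
        return self.spacing ** 3

    def linear_index(self, ijk: np.ndarray) -> np.ndarray:
        """Map ``(..., 3)`` voxel indices to flat DX order (z fastest)."""
        ijk = np.asarray(ijk, dtype=int)
        nx, ny, nz = self.dims
        return (ijk[..., 0] * ny + ijk[..., 1]) * nz + ijk[..., 2]

    def unravel(self, flat: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`linear_index`; returns ``(..., 3)`` indices."""
        flat = np.asarray(flat, dtype=int)
        nx, ny, nz = self.dims
        i, rem = np.divmod(flat, ny * nz)
        j, k = np.divmod(rem, nz)
        return np.stack([i, j, k], axis=-1)

    def point_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """``(..., 3)`` Å points -> voxel indices (may fall outside dims)."""
        xyz = np.asarray(xyz, dtype=float)
        return np.floor((xyz - np.asarray(self.origin)) / self.spacing).astype(int)

    def contains(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=int)
        dims = np.asarray(self.dims)
        return np.all((ijk >= 0) & (ijk < dims), axis=-1)

    def voxel_center(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return np.asarray(self.origin) + (ijk + 0.5) * self.spacing


@dataclass
class ScalarField:
    """Per-voxel scalar values, flat in DX order (z fastest-varying)."""

    grid: GridSpec
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.grid.n_voxels:
            raise GridFormatError(
                f"expected {self.grid.n_voxels} values for dims {self.grid.dims}, "
                f"got {self.values.size}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite grid values")

    def as_3d(self) -> np.ndarray:
        return self.values.reshape(self.grid.dims)

    def with_values(self, values: np.ndarray, units: str | None = None) -> "ScalarField":
        return ScalarField(self.grid, values, self.units if units is None else units)


# --------------------------------------------------------------------------
# role assignment
# --------------------------------------------------------------------------

_BACKBONE_NAMES = {"CA", "C", "O", "N"}

DEFAULT_ROLE_CONFIG: dict = {
    "ligand_resnames": [],
    "water_resnames": list(C.WATER_RESNAMES),
    "donor_elements": ["N", "O"],
    "acceptor_elements": ["N", "O", "S"],
    "apolar_elements": ["C", "S"],
}


def assign_roles(
    atoms: Sequence[AtomRecord],
    coords0: np.ndarray | None = None,
    config: dict | None = None,
) -> list[AtomRecord]:
    """Assign backbone/water/ligand/H-bond/apolar roles to bare atom records.

    Donor-heavy assignment requires a covalently attached hydrogen, found by
    distance (< 1.25 Å, same residue) in ``coords0`` (first frame). Without
    coordinates, every donor-element heavy atom is treated as a potential
    donor. Rules are overridable via ``config`` (see DEFAULT_ROLE_CONFIG).
    """
    cfg = dict(DEFAULT_ROLE_CONFIG)
    if config:
        cfg.update(config)
    ligand_res = {r.upper() for r in cfg["ligand_resnames"]}
    water_res = {r.upper() for r in cfg["water_resnames"]}
    donors = {e.upper() for e in cfg["donor_elements"]}
    acceptors = {e.upper() for e in cfg["acceptor_elements"]}
    apolar = {e.upper() for e in cfg["apolar_elements"]}

    has_h = _attached_hydrogen_mask(atoms, coords0, donors)

    out: list[AtomRecord] = []
    for a, h in zip(atoms, has_h):
        el = a.element.upper()
        res = a.residue_name.upper()
        is_water = res in water_res
        is_ligand = (res in ligand_res) and not is_water
        is_bb = a.name.upper() in _BACKBONE_NAMES and res in C.AMINO_ACIDS
        is_don = el in donors and h
        is_acc = el in acceptors and el != "H"
        role = (
            "both" if (is_don and is_acc)
            else "donor-heavy" if is_don
            else "acceptor" if is_acc
            else "none"
        )
        out.append(replace(
            a,
            is_backbone=is_bb,
            is_water_oxygen=is_water and el == "O",
            is_ligand=is_ligand,
            hbond_role=role if el != "H" else "none",
            is_apolar=el in apolar and not is_water,
        ))
    return out


def _attached_hydrogen_mask(
    atoms: Sequence[AtomRecord],
    coords0: np.ndarray | None,
    donor_elements: set[str],
) -> np.ndarray:
    """True where a donor-element heavy atom has a covalent H neighbour."""
    n = len(atoms)
    elements = np.array([a.element.upper() for a in atoms])
    h_idx = np.flatnonzero(elements == "H")
    # without coordinates, or in a hydrogen-free structure (e.g. crystal
    # coordinates), every donor-element heavy atom is a potential donor
    if coords0 is None or h_idx.size == 0:
        return np.isin(elements, sorted(donor_elements))
    coords0 = np.asarray(coords0, dtype=float)
    resids = np.array([(a.chain, a.residue_id) for a in atoms], dtype=object)
    mask = np.zeros(n, dtype=bool)
    cand = np.flatnonzero(np.isin(elements, sorted(donor_elements)))
    if cand.size == 0:
        return mask
    d = np.linalg.norm(coords0[cand][:, None] - coords0[h_idx][None], axis=-1)
    same_res = np.array(
        [[tuple(resids[c]) == tuple(resids[h]) for h in h_idx] for c in cand]
    )
    mask[cand] = np.any((d < C.DONOR_H_ATTACH_A) & same_res, axis=1)
    return mask


# --------------------------------------------------------------------------
# trajectory I/O
# --------------------------------------------------------------------------

def read_trajectory(
    path: str | Path,
    selection_config: dict | None = None,
    frame_interval_ps: float = 4.0,
) -> Trajectory:
    """Read a multi-model PDB or XYZ file into a :class:`Trajectory`.

    Role flags are assigned from ``selection_config`` (see
    :func:`assign_roles`). Every model must contain the same atom count;
    otherwise a :class:`TrajectoryParseError` names the offending model.
    """
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        atoms, coords = _read_xyz(path)
    else:
        atoms, coords = _read_pdb(path)
    atoms = assign_roles(atoms, coords[0], selection_config)
    return Trajectory(atoms, coords, frame_interval_ps=frame_interval_ps)


def _read_pdb(path: Path) -> tuple[list[AtomRecord], np.ndarray]:
    from biotite.structure.io import pdb as _pdb

    _check_model_counts(path)
    pdb_file = _pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)  # AtomArrayStack
    atoms: list[AtomRecord] = []
    for i in range(stack.array_length()):
        element = str(stack.element[i]).strip()
        name = str(stack.atom_name[i]).strip()
        if not element:
            element = _infer_element(name)
            warnings.warn(
                f"atom {i} ({name}): missing element, inferred {element!r}"
            )
        atoms.append(AtomRecord(
            index=i,
            name=name,
            element=element,
            residue_name=str(stack.res_name[i]).strip(),
            residue_id=int(stack.res_id[i]),
            chain=str(stack.chain_id[i]).strip() or "A",
        ))
    return atoms, np.asarray(stack.coord, dtype=float)


def _check_model_counts(path: Path) -> None:
    """Pre-scan MODEL blocks so atom-count mismatches name the model."""
    counts: list[tuple[int, int]] = []  # (model serial, n_atoms)
    current: int | None = None
    n = 0
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                current = int(line[6:].split()[0]) if line[6:].split() else len(counts) + 1
                n = 0
            elif rec in ("ATOM", "HETATM"):
                n += 1
            elif rec == "ENDMDL":
                counts.append((current if current is not None else len(counts) + 1, n))
                current, n = None, 0
    if current is not None or (not counts and n):
        counts.append((current if current is not None else 1, n))
    if len({c for _, c in counts}) > 1:
        ref = counts[0][1]
        bad = next((m, c) for m, c in counts if c != ref)
        raise TrajectoryParseError(
            f"{path}: MODEL {bad[0]} has {bad[1]} atoms, expected {ref}"
        )


def _infer_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if stripped[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE", "CA"):
        return stripped[:2].capitalize()
    return stripped[:1].upper() if stripped else "X"


def _read_xyz(path: Path) -> tuple[list[AtomRecord], np.ndarray]:
    frames: list[np.ndarray] = []
    symbols: list[str] | None = None
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    pos = 0
    model = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        model += 1
        try:
            n = int(lines[pos].split()[0])
        except ValueError as exc:
            raise TrajectoryParseError(f"{path}: bad atom count at line {pos + 1}") from exc
        block = lines[pos + 2 : pos + 2 + n]
        if len(block) < n:
            raise TrajectoryParseError(f"{path}: truncated model {model}")
        syms, xyz = [], []
        for ln in block:
            parts = ln.split()
            syms.append(parts[0])
            xyz.append([float(x) for x in parts[1:4]])
        if symbols is None:
            symbols = syms
        elif len(syms) != len(symbols):
            raise TrajectoryParseError(
                f"{path}: model {model} has {len(syms)} atoms, expected {len(symbols)}"
            )
        frames.append(np.array(xyz))
        pos += 2 + n
    if symbols is None:
        raise TrajectoryParseError(f"{path}: no atoms found")
    atoms = [
        AtomRecord(index=i, name=s, element=s.capitalize(), residue_name="UNK",
                   residue_id=1)
        for i, s in enumerate(symbols)
    ]
    return atoms, np.stack(frames)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as multi-model PDB (or XYZ if path ends in .xyz)."""
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        with open(path, "w") as fh:
            for fr in traj:
                fh.write(f"{traj.n_atoms}\nframe {fr.frame_index} t={fr.time_ps} ps\n")
                for a, (x, y, z) in zip(traj.atoms, fr.coords):
                    fh.write(f"{a.element} {x:.6f} {y:.6f} {z:.6f}\n")
        return

    import biotite.structure as struc
    from biotite.structure.io import pdb as _pdb

    stack = struc.AtomArrayStack(traj.n_frames, traj.n_atoms)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    stack.atom_name = np.array([a.name for a in traj.atoms])
    stack.res_name = np.array([a.residue_name for a in traj.atoms])
    stack.res_id = np.array([a.residue_id for a in traj.atoms])
    stack.chain_id = np.array([a.chain for a in traj.atoms])
    stack.element = np.array([a.element for a in traj.atoms])
    stack.set_annotation(
        "hetero",
        np.array([a.residue_name not in C.AMINO_ACIDS for a in traj.atoms]),
    )
    pdb_file = _pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def write_frame_pdb(traj: Trajectory, frame_index: int, path: str | Path) -> None:
    """Write a single frame as a one-model PDB."""
    single = Trajectory(
        traj.atoms, traj.coords[frame_index : frame_index + 1],
        frame_interval_ps=traj.frame_interval_ps,
    )
    write_trajectory(single, path)


# --------------------------------------------------------------------------
# OpenDX grids
# --------------------------------------------------------------------------

def read_dx_grid(path: str | Path) -> ScalarField:
    """Read an OpenDX regular scalar grid.

    Only orthogonal, isotropic (cubic-voxel) grids are supported; anything
    else raises :class:`GridFormatError`.
    """
    g = _DXGrid(str(path))
    delta = np.asarray(g.delta, dtype=float)
    if delta.ndim == 2:
        if not np.allclose(delta, np.diag(np.diagonal(delta))):
            raise GridFormatError(f"{path}: non-orthogonal grid deltas")
        delta = np.diagonal(delta).copy()
    if not np.allclose(delta, delta[0], rtol=1e-9, atol=1e-12):
        raise GridFormatError(f"{path}: anisotropic grid spacing {delta}")
    dims = tuple(int(d) for d in g.grid.shape)
    # gridData's origin is the center of voxel (0,0,0); ours is its corner
    spacing = float(delta[0])
    origin = tuple(np.asarray(g.origin, dtype=float) - spacing / 2.0)
    spec = GridSpec(origin=origin, spacing=spacing, dims=dims)
    return ScalarField(spec, np.asarray(g.grid, dtype=float).ravel(order="C"))


def write_dx_grid(field: ScalarField, path: str | Path) -> None:
    """Write a :class:`ScalarField` as an OpenDX scalar grid."""
    spec = field.grid
    origin = np.asarray(spec.origin) + spec.spacing / 2.0  # voxel-center origin
    g = _DXGrid(field.as_3d(), origin=origin, delta=spec.spacing)
    g.export(str(path), typequote="")


# --------------------------------------------------------------------------
# tables
# --------------------------------------------------------------------------

def write_table(
    records: Iterable, path: str | Path, columns: Sequence[str] | None = None
) -> None:
    """Write records (dicts or dataclasses sharing one schema) as TSV.

    ``columns`` supplies the header when ``records`` is empty (header-only
    file); otherwise the schema of the first record fixes the column order.
    """
    rows = []
    for r in records:
        if hasattr(r, "__dataclass_fields__"):
            from dataclasses import asdict
            rows.append(asdict(r))
        elif isinstance(r, dict):
            rows.append(dict(r))
        else:
            raise TypeError(f"unsupported record type {type(r)!r}")
    if rows:
        schema = list(rows[0].keys())
        for i, r in enumerate(rows[1:], start=1):
            if list(r.keys()) != schema:
                raise ValueError(f"record {i} schema {list(r)} != {schema}")
        df = pd.DataFrame(rows, columns=schema)
    else:
        df = pd.DataFrame(columns=list(columns) if columns else [])
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
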