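"""Synthetic trajectories and fields with known ground truth.

Every downstream stage (FEL estimation, hydration-site classification,
contact detection) is validated against data generated here, so the
generators are first-class, deterministic-under-seed code:

* :func:`make_fel_trajectory` — frames whose ligand collective variables
  (r1, r2) are i.i.d. draws from the Boltzmann density exp(−G/k_BT) of an
  analytic multi-Gaussian-well surface G. Sampling happens in CV space and
  is then embedded in 3D (ligand center placed at distance r1 from the
  reference center, at angle r2 from the reference→protein-center axis, in
  a fixed plane), so the planted surface is exactly the binned density the
  histogram estimator sees.
* :func:`make_water_trajectory` — water-oxygen positions whose per-frame
  per-voxel counts are Poisson with mean density × voxel volume; hotspot
  voxels carry g_O × bulk density over a 0.0329 Å⁻³ background.
* :func:`make_hydration_fields` — deterministic per-voxel energy/entropy
  fields constructed so the planted ΔG_solv targets are reproduced exactly
  by the free-energy assembly.
* :func:`make_contact_fixture` — a single frame with planted direct
  hydrogen bonds, single-water bridges and hydrophobic pairs at controlled
  distances, plus decoy atoms kept > 5 Å from every planted participant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .gist_post import GistConstants, GistFieldSet, eww_reference
from .io_formats import AtomRecord, GridSpec, ScalarField, Trajectory, assign_roles

__all__ = [
    "FelSyntheticSpec",
    "TrueSurface",
    "HydrationSyntheticSpec",
    "WaterEnsemble",
    "ContactFixtureSpec",
    "PlantedContact",
    "make_fel_trajectory",
    "make_water_trajectory",
    "make_hydration_fields",
    "make_contact_fixture",
]


# --------------------------------------------------------------------------
# FEL synthetic trajectories
# --------------------------------------------------------------------------

@dataclass
class FelSyntheticSpec:
    """Multi-basin CV-space sampling specification.

    Each basin i is an isotropic Gaussian well at ``basin_centers[i]``
    (r1 in Å, r2 in degrees) with depth ``basin_depths_kcal[i]`` (kcal/mol,
    deeper = more populated) and width ``basin_widths[i]`` (standard
    deviation in CV units).
    """

    basin_centers: list
    basin_depths_kcal: list
    basin_widths: list
    n_frames: int = 10000
    temperature_K: float = C.DEFAULT_TEMPERATURE_K
    seed: int = 0
    #: Gaussian positional noise (Å) on the protein scaffold atoms; zero by
    #: default so the planted CVs are realized exactly.
    protein_jitter_A: float = 0.0

    def __post_init__(self) -> None:
        k = len(self.basin_centers)
        if not (len(self.basin_depths_kcal) == len(self.basin_widths) == k):
            raise ValueError("basin lists must have equal length")
        if k == 0:
            raise ValueError("need at least one basin")
        if any(w <= 0 for w in self.basin_widths):
            raise ValueError("basin widths must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        for r1, r2 in self.basin_centers:
            if r1 < 0 or not (0 <= r2 <= 180):
                raise ValueError(
                    f"basin center ({r1}, {r2}) outside representable geometry "
                    "(r1 >= 0, r2 in [0, 180])"
                )


@dataclass
class TrueSurface:
    """The analytic surface underlying a synthetic FEL trajectory.

    The sampling density is a Gaussian mixture p(r1, r2) with component
    weights proportional to exp(depth/k_BT)·σ², so equal-depth, equal-width
    basins are equally occupied. ``delta_g`` evaluates
    −k_BT ln p relative to the deepest basin center.
    """

    centers: np.ndarray     # (k, 2)
    widths: np.ndarray      # (k,)
    weights: np.ndarray     # (k,), sum 1 — basin occupancy fractions
    temperature_K: float

    def pdf(self, r1, r2) -> np.ndarray:
        r1 = np.asarray(r1, float)[..., None]
        r2 = np.asarray(r2, float)[..., None]
        s2 = self.widths**2
        z = ((r1 - self.centers[:, 0]) ** 2 + (r2 - self.centers[:, 1]) ** 2) / (2 * s2)
        comp = np.exp(-z) / (2 * np.pi * s2)
        return comp @ self.weights

    def delta_g(self, r1, r2) -> np.ndarray:
        kt = C.KB_KCAL * self.temperature_K
        p = self.pdf(r1, r2)
        p_ref = float(np.max(self.pdf(self.centers[:, 0], self.centers[:, 1])))
        with np.errstate(divide="ignore"):
            return -kt * np.log(p / p_ref)


def _surface_from_spec(spec: FelSyntheticSpec) -> TrueSurface:
    kt = C.KB_KCAL * spec.temperature_K
    depths = np.asarray(spec.basin_depths_kcal, float)
    widths = np.asarray(spec.basin_widths, float)
    # component mass: Boltzmann weight of the well times its 2D Gaussian volume
    w = np.exp((depths - depths.max()) / kt) * widths**2
    return TrueSurface(
        centers=np.asarray(spec.basin_centers, float),
        widths=widths,
        weights=w / w.sum(),
        temperature_K=spec.temperature_K,
    )


def _sample_cvs(spec: FelSyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw (n, 2) CV pairs from the mixture, rejecting out-of-range draws
    (r1 < 0 or r2 outside [0, 180])."""
    surf = _surface_from_spec(spec)
    n = spec.n_frames
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = n - filled
        comp = rng.choice(len(surf.weights), size=m, p=surf.weights)
        draws = surf.centers[comp] + rng.standard_normal((m, 2)) * surf.widths[comp, None]
        ok = (draws[:, 0] >= 0) & (draws[:, 1] >= 0) & (draws[:, 1] <= 180)
        take = draws[ok]
        out[filled : filled + take.shape[0]] = take
        filled += take.shape[0]
    return out


_PROTEIN_CENTER = np.array([0.0, 0.0, -10.0])


def _scaffold_atoms() -> list[AtomRecord]:
    """Static protein scaffold: a reference residue at the origin plus four
    atoms arranged so the full protein geometric center is (0, 0, −10)."""
    records = [AtomRecord(0, "CA", "C", "GLU", 378)]
    for i in range(4):
        records.append(AtomRecord(1 + i, "CA", "C", "GLY", 10 + i))
    records.append(AtomRecord(5, "C1", "C", "LIG", 500))
    return assign_roles(records, None, {"ligand_resnames": ["LIG"]})


def _scaffold_coords() -> np.ndarray:
    """(6, 3) template: 5 protein atoms + 1 ligand placeholder."""
    coords = np.zeros((6, 3))
    # four atoms averaging (with the origin atom) to the protein center
    offsets = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0]], float)
    coords[1:5] = 1.25 * _PROTEIN_CENTER + offsets
    return coords


def make_fel_trajectory(spec: FelSyntheticSpec) -> tuple[Trajectory, TrueSurface]:
    """Trajectory whose ligand CVs sample the planted Boltzmann density.

    The reference-residue center sits at the origin and the protein center
    at (0, 0, −10); the ligand center is placed at
    ``r1 · (sin r2, 0, −cos r2)`` so that the distance and three-center
    angle reproduce each drawn CV pair exactly.
    """
    rng = np.random.default_rng(spec.seed)
    cvs = _sample_cvs(spec, rng)
    template = _scaffold_coords()
    coords = np.broadcast_to(template, (spec.n_frames, 6, 3)).copy()
    theta = np.radians(cvs[:, 1])
    coords[:, 5, 0] = cvs[:, 0] * np.sin(theta)
    coords[:, 5, 2] = -cvs[:, 0] * np.cos(theta)
    if spec.protein_jitter_A > 0:
        coords[:, :5] += rng.standard_normal((spec.n_frames, 5, 3)) * spec.protein_jitter_A
    traj = Trajectory(_scaffold_atoms(), coords)
    return traj, _surface_from_spec(spec)


# --------------------------------------------------------------------------
# hydration synthetics
# --------------------------------------------------------------------------

@dataclass
class HydrationSyntheticSpec:
    """Planted-hotspot water grid specification.

    ``hotspots`` entries are ``(voxel, g_O_target, dG_solv_target)`` where
    ``voxel`` is a flat index or an (i, j, k) triple.
    """

    grid: GridSpec
    bulk_density_per_A3: float = C.BULK_WATER_DENSITY_PER_A3
    hotspots: list = field(default_factory=list)
    n_frames: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        flat = []
        for voxel, g_o, dg in self.hotspots:
            if g_o < 0:
                raise ValueError("g_O targets must be >= 0")
            if isinstance(voxel, (tuple, list, np.ndarray)):
                if not self.grid.contains(np.asarray(voxel)):
                    raise ValueError(f"hotspot voxel {voxel} outside grid")
                voxel = int(self.grid.linear_index(np.asarray(voxel)))
            else:
                voxel = int(voxel)
                if not 0 <= voxel < self.grid.n_voxels:
                    raise ValueError(f"hotspot voxel {voxel} outside grid")
            flat.append((voxel, float(g_o), float(dg)))
        self.hotspots = flat


@dataclass
class WaterEnsemble:
    """Ragged water-oxygen frames: one (n_i, 3) array per frame.

    Per-voxel Poisson counts make the per-frame totals vary, so this is a
    dedicated container rather than a fixed-topology Trajectory;
    ``bin_water_density`` accepts it directly.
    """

    frames_xyz: list
    grid: GridSpec

    @property
    def n_frames(self) -> int:
        return len(self.frames_xyz)


def _target_densities(spec: HydrationSyntheticSpec) -> np.ndarray:
    rho = np.full(spec.grid.n_voxels, spec.bulk_density_per_A3)
    for voxel, g_o, _ in spec.hotspots:
        rho[voxel] = g_o * spec.bulk_density_per_A3
    return rho


def make_water_trajectory(spec: HydrationSyntheticSpec) -> WaterEnsemble:
    """Water-oxygen frames with per-voxel Poisson occupancy.

    Counts in voxel v are Poisson with mean ρ_v · spacing³ per frame, where
    ρ_v is the bulk density except at hotspot voxels (g_O × bulk); positions
    are uniform within each voxel.
    """
    if spec.n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    lam = _target_densities(spec) * grid.voxel_volume
    corners = grid.voxel_center(grid.unravel(np.arange(grid.n_voxels))) - grid.spacing / 2
    frames = []
    for _ in range(spec.n_frames):
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0:
            frames.append(np.empty((0, 3)))
            continue
        vox = np.repeat(np.arange(grid.n_voxels), counts)
        xyz = corners[vox] + rng.random((total, 3)) * grid.spacing
        frames.append(xyz)
    return WaterEnsemble(frames, grid)


def make_hydration_fields(
    spec: HydrationSyntheticSpec, constants: GistConstants | None = None
) -> GistFieldSet:
    """Deterministic per-voxel fields reproducing the planted ΔG targets.

    Background voxels get g(O) = 1 and a raw water–water energy equal to
    the bulk reference (so ΔE_ww and ΔG_solv are exactly 0); hotspot voxels
    additionally carry their ΔG target in the solute–water term. Contains
    no randomness.
    """
    constants = constants or GistConstants(bulk_density_per_A3=spec.bulk_density_per_A3)
    grid = spec.grid
    g_o = np.ones(grid.n_voxels)
    e_sw = np.zeros(grid.n_voxels)
    for voxel, g_o_t, dg_t in spec.hotspots:
        g_o[voxel] = g_o_t
        e_sw[voxel] = dg_t
    g_field = ScalarField(grid, g_o, "g(O)")
    return GistFieldSet(
        grid=grid,
        g_O=g_field,
        E_sw=ScalarField(grid, e_sw, "kcal/mol"),
        E_ww_raw=eww_reference(g_field, constants),
        TdS_trans=ScalarField(grid, np.zeros(grid.n_voxels), "kcal/mol"),
        TdS_orient=ScalarField(grid, np.zeros(grid.n_voxels), "kcal/mol"),
    )


# --------------------------------------------------------------------------
# contact fixtures
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedContact:
    """One planted ligand–protein contact.

    ``type`` is direct-hbond, water-bridge or hydrophobic. For hydrogen
    bonds ``d_HA``/``d_DA`` set the hydrogen–acceptor and donor–acceptor
    distances (for water bridges, of both legs); for hydrophobic contacts
    ``d_CC`` is the apolar pair distance.
    """

    type: str
    d_HA: float = 1.95
    d_DA: float = 2.90
    d_CC: float = 3.50

    def __post_init__(self) -> None:
        if self.type not in ("direct-hbond", "water-bridge", "hydrophobic"):
            raise ValueError(f"unknown contact type {self.type!r}")
        if min(self.d_HA, self.d_DA, self.d_CC) <= 0:
            raise ValueError("distances must be positive")


@dataclass
class ContactFixtureSpec:
    planted: list
    decoy_atoms: int = 0
    seed: int = 0


_UNIT_SPACING = 15.0   # Å between planted units; cutoffs are all < 4 Å
_DH = 1.0              # covalent donor-hydrogen distance, Å


def _hbond_unit(origin: np.ndarray, d_ha: float, d_da: float, unit: int):
    """Protein donor N–H plus ligand acceptor O at exact (d_HA, d_DA)."""
    cos_t = (_DH**2 + d_da**2 - d_ha**2) / (2 * _DH * d_da)
    if not -1 <= cos_t <= 1:
        raise ValueError(
            f"d_HA={d_ha}, d_DA={d_da} incompatible with a {_DH} Å D-H bond"
        )
    sin_t = np.sqrt(1 - cos_t**2)
    atoms = [
        ("N", "N", "SER", 100 + unit, False),
        ("HN", "H", "SER", 100 + unit, False),
        ("O1", "O", "LIG", 500, True),
    ]
    coords = [
        origin,
        origin + np.array([cos_t, sin_t, 0.0]) * _DH,
        origin + np.array([d_da, 0.0, 0.0]),
    ]
    return atoms, coords


def _bridge_unit(origin: np.ndarray, d_ha: float, d_da: float, unit: int):
    """Water donating one H-bond to a ligand acceptor and one to a protein
    acceptor; the ligand-protein distance (2·d_DA) exceeds the direct cutoff
    as long as d_DA > 1.675 Å."""
    atoms = [
        ("O", "O", "HOH", 700 + unit, False),
        ("H1", "H", "HOH", 700 + unit, False),
        ("H2", "H", "HOH", 700 + unit, False),
        ("O2", "O", "LIG", 500, True),
        ("OD1", "O", "ASP", 200 + unit, False),
    ]
    h_off = d_da - d_ha  # hydrogen on the donor-acceptor line
    coords = [
        origin,
        origin + np.array([-h_off, 0.0, 0.0]),
        origin + np.array([h_off, 0.0, 0.0]),
        origin + np.array([-d_da, 0.0, 0.0]),
        origin + np.array([d_da, 0.0, 0.0]),
    ]
    return atoms, coords


def _hydrophobic_unit(origin: np.ndarray, d_cc: float, unit: int):
    atoms = [
        ("CB", "C", "ALA", 300 + unit, False),
        ("C2", "C", "LIG", 500, True),
    ]
    coords = [origin, origin + np.array([d_cc, 0.0, 0.0])]
    return atoms, coords


def make_contact_fixture(spec: ContactFixtureSpec) -> Trajectory:
    """Single-frame trajectory realizing each planted contact exactly.

    Planted units are spaced 15 Å apart so they cannot interact; decoy
    protein atoms (apolar C) are placed at least 5 Å — in fact > 20 Å —
    from every planted participant.
    """
    rng = np.random.default_rng(spec.seed)
    atoms_meta: list[tuple] = []
    coords: list[np.ndarray] = []
    for u, planted in enumerate(spec.planted):
        if not isinstance(planted, PlantedContact):
            planted = PlantedContact(*planted) if isinstance(planted, tuple) else \
                PlantedContact(**planted)
        origin = np.array([u * _UNIT_SPACING, 0.0, 0.0])
        if planted.type == "direct-hbond":
            a, c = _hbond_unit(origin, planted.d_HA, planted.d_DA, u)
        elif planted.type == "water-bridge":
            if planted.d_DA <= C.HBOND_MAX_DA_A / 2:
                raise ValueError("water-bridge d_DA too short: legs would touch")
            a, c = _bridge_unit(origin, planted.d_HA, planted.d_DA, u)
        else:
            a, c = _hydrophobic_unit(origin, planted.d_CC, u)
        atoms_meta.extend(a)
        coords.extend(c)
    for i in range(spec.decoy_atoms):
        atoms_meta.append((f"CD{i}", "C", "GLY", 900 + i, False))
        coords.append(np.array([0.0, 0.0, 30.0]) + rng.uniform(-4, 4, 3)
                      + np.array([rng.uniform(0, _UNIT_SPACING * max(1, len(spec.planted))), 0, 0]))
    records = [
        AtomRecord(i, name, el, res, rid)
        for i, (name, el, res, rid, _) in enumerate(atoms_meta)
    ]
    xyz = np.asarray(coords)[None]  # one frame
    records = assign_roles(records, xyz[0], {"ligand_resnames": ["LIG"]})
    return Trajectory(records, xyz, frame_interval_ps=4.0)
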