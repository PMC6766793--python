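"""Per-voxel hydration thermodynamics post-processing (GIST-style).

Consumes per-voxel solute–water energy, water–water energy and
(temperature-multiplied) translational/orientational entropy fields, plus a
water-oxygen occupancy field g(O), and assembles the per-voxel transfer
free energy relative to bulk:

    ΔG_solv = ΔE_sw + ΔE_ww − TΔS_trans − TΔS_orient

where ΔE_ww is the raw water–water energy minus the occupancy-scaled bulk
reference E_ww(Ref) = eww_bulk · ρ_bulk · g(O) per voxel (−0.3136·g(O)
kcal/mol for TIP3P). Voxels that both retain water strongly (g(O) ≥ 10
multiples of bulk) and carry |ΔG_solv| ≥ 3 kcal/mol are classified as
hydration sites, favorable (ΔG ≤ −3) or unfavorable (ΔG ≥ +3). A conformer
ensemble of fields or scalars can be averaged with probability weights.

Entropy fields are taken as TΔS in kcal/mol; input fields are per-voxel
totals. Cpptraj-style density-weighted fields (kcal/mol/Å³ per voxel) can
be converted on ingestion with ``density_weighted=True``, which multiplies
by the voxel volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as C
from .io_formats import GridSpec, ScalarField, Trajectory

__all__ = [
    "GistConstants",
    "GistFieldSet",
    "HydrationSite",
    "ConformerEnsemble",
    "bin_water_density",
    "eww_reference",
    "combine_free_energy",
    "classify_sites",
    "conformer_average",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GistConstants:
    """Bulk-water reference values (TIP3P defaults)."""

    bulk_density_per_A3: float = C.BULK_WATER_DENSITY_PER_A3
    eww_bulk_kcal: float = C.EWW_BULK_KCAL
    temperature_K: float = C.DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.bulk_density_per_A3 <= 0:
            raise ValueError("bulk density must be positive")

    @property
    def eww_ref_coefficient(self) -> float:
        """kcal/mol of bulk water–water reference per unit g(O) per voxel.

        Computed, never hard-coded: eww_bulk × ρ_bulk = −9.533 × 0.0329.
        """
        return self.eww_bulk_kcal * self.bulk_density_per_A3


@dataclass
class GistFieldSet:
    """All per-voxel fields on one shared grid."""

    grid: GridSpec
    g_O: ScalarField
    E_sw: ScalarField | None = None
    E_ww_raw: ScalarField | None = None
    TdS_trans: ScalarField | None = None
    TdS_orient: ScalarField | None = None
    dG_solv: ScalarField | None = None

    def __post_init__(self) -> None:
        for name in ("g_O", "E_sw", "E_ww_raw", "TdS_trans", "TdS_orient", "dG_solv"):
            f = getattr(self, name)
            if f is not None and f.grid != self.grid:
                raise ValueError(f"field {name} is on a different grid")
        if np.any(self.g_O.values < 0):
            raise ValueError("g(O) must be non-negative")


@dataclass(frozen=True)
class HydrationSite:
    """A classified voxel: retained water with strongly non-bulk ΔG."""

    voxel: tuple[int, int, int]
    center_A: tuple[float, float, float]
    g_O: float
    dG_solv: float
    klass: str  # "favorable" | "unfavorable"


@dataclass
class ConformerEnsemble:
    """Solvation free energies of solute conformers with weights p(q)."""

    members: list
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.members) != self.weights.size:
            raise ValueError("members and weights must have equal length")
        if np.any(self.weights < 0):
            raise ValueError("conformer weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {self.weights.sum()}, expected 1")


# --------------------------------------------------------------------------

def bin_water_density(
    traj,
    grid: GridSpec,
    constants: GistConstants = GistConstants(),
) -> ScalarField:
    """Average per-frame water-oxygen number density per voxel, in
    multiples of the bulk density:

        g(O)[v] = count(v) / (n_frames · spacing³ · ρ_bulk)

    ``traj`` may be a :class:`~felgist.io_formats.Trajectory` (water-oxygen
    flagged atoms are binned) or any object with per-frame ``(n_i, 3)``
    oxygen coordinate arrays under ``.frames_xyz``. Oxygens outside the
    grid are ignored; their count is logged.
    """
    frames = _water_frames(traj)
    n_frames = len(frames)
    if n_frames == 0:
        raise ValueError("trajectory has no frames")
    counts = np.zeros(grid.n_voxels, dtype=np.int64)
    outside = 0
    for xyz in frames:
        if xyz.shape[0] == 0:
            continue
        ijk = grid.point_to_voxel(xyz)
        inside = grid.contains(ijk)
        outside += int(np.size(inside) - np.count_nonzero(inside))
        flat = grid.linear_index(ijk[inside])
        np.add.at(counts, flat, 1)
    if outside:
        logger.info("bin_water_density: %d oxygen positions outside grid", outside)
    denom = n_frames * grid.voxel_volume * constants.bulk_density_per_A3
    return ScalarField(grid, counts / denom, units="g(O)")


def _water_frames(traj) -> list[np.ndarray]:
    if hasattr(traj, "frames_xyz"):
        return [np.asarray(f, dtype=float) for f in traj.frames_xyz]
    if isinstance(traj, Trajectory):
        mask = np.array([a.is_water_oxygen for a in traj.atoms])
        if not mask.any():
            raise ValueError("trajectory has no flagged water-oxygen atoms")
        return [traj.coords[i][mask] for i in range(traj.n_frames)]
    raise TypeError(f"unsupported water container {type(traj)!r}")


def eww_reference(
    g_O: ScalarField, constants: GistConstants = GistConstants()
) -> ScalarField:
    """Occupancy-scaled bulk water–water reference energy per voxel:
    E_ww(Ref) = eww_bulk · ρ_bulk · g(O)  (−0.3136·g(O) kcal/mol for TIP3P).
    """
    return g_O.with_values(constants.eww_ref_coefficient * g_O.values, "kcal/mol")


def combine_free_energy(
    fields: GistFieldSet,
    constants: GistConstants = GistConstants(),
    density_weighted: bool = False,
) -> GistFieldSet:
    """Assemble ΔG_solv per voxel with the bulk reference subtracted.

    ΔE_ww = E_ww_raw − E_ww(Ref);
    ΔG_solv = ΔE_sw + ΔE_ww − TΔS_trans − TΔS_orient.
    With ``density_weighted=True`` the energy/entropy inputs are interpreted
    as kcal/mol/Å³ and multiplied by the voxel volume first.
    """
    for name in ("E_sw", "E_ww_raw", "TdS_trans", "TdS_orient"):
        if getattr(fields, name) is None:
            raise ValueError(f"field {name} missing")
    scale = fields.grid.voxel_volume if density_weighted else 1.0
    esw = fields.E_sw.values * scale
    eww = fields.E_ww_raw.values * scale - eww_reference(fields.g_O, constants).values
    tds = (fields.TdS_trans.values + fields.TdS_orient.values) * scale
    dg = esw + eww - tds
    return replace(fields, dG_solv=ScalarField(fields.grid, dg, "kcal/mol"))


def classify_sites(
    fields: GistFieldSet,
    g_O_min: float = C.SITE_G_O_MIN,
    dG_abs_min: float = C.SITE_DG_ABS_MIN,
) -> list[HydrationSite]:
    """Voxels with g(O) ≥ 10 and |ΔG_solv| ≥ 3 kcal/mol (both inclusive),
    labelled favorable (ΔG ≤ −3) or unfavorable (ΔG ≥ +3), sorted by
    |ΔG_solv| descending.
    """
    if fields.dG_solv is None:
        raise ValueError("dG_solv not computed; call combine_free_energy first")
    g = fields.g_O.values
    dg = fields.dG_solv.values
    keep = np.flatnonzero((g >= g_O_min) & (np.abs(dg) >= dG_abs_min))
    sites = [
        HydrationSite(
            voxel=tuple(fields.grid.unravel(v)),
            center_A=tuple(fields.grid.voxel_center(fields.grid.unravel(v))),
            g_O=float(g[v]),
            dG_solv=float(dg[v]),
            klass="favorable" if dg[v] <= -dG_abs_min else "unfavorable",
        )
        for v in keep
    ]
    sites.sort(key=lambda s: -abs(s.dG_solv))
    return sites


def conformer_average(ensemble: ConformerEnsemble):
    """Probability-weighted mean over conformers: ΔG_solv ≈ Σ ΔG_solv(q)·p(q).

    Members may be scalars or :class:`ScalarField`s on a common grid
    (averaged voxel-wise).
    """
    members, w = ensemble.members, ensemble.weights
    if isinstance(members[0], ScalarField):
        grid = members[0].grid
        for m in members[1:]:
            if m.grid != grid:
                raise ValueError("conformer fields on different grids")
        stacked = np.stack([m.values for m in members])
        return ScalarField(grid, np.einsum("q,qv->v", w, stacked),
                           members[0].units)
    vals = np.asarray(members, dtype=float)
    return float(np.dot(w, vals))
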