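"""Collective variables, Boltzmann-inversion free-energy surfaces, basins,
and representative-frame (decoy) extraction.

The two collective variables describe where a ligand sits relative to the
catalytic site: ``r1`` is the Cartesian distance between the geometric
centers of the ligand and a reference residue; ``r2`` is the angle (degrees)
at the reference-residue center between the rays toward the ligand center
and toward the whole-protein center. The free-energy surface is the raw
histogram inversion ΔG(r1, r2) = −k_B T ln P(r1, r2), shifted so the global
minimum over populated bins is zero; empty bins stay undefined (masked)
rather than receiving a pseudo-count, because the inversion is undefined at
P = 0 and imputation would fabricate barrier heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import constants as C
from .io_formats import Trajectory
from .selections import Selection, SelectionError

__all__ = [
    "CVSeries",
    "FreeEnergySurface",
    "Basin",
    "Decoy",
    "geometric_center",
    "compute_cvs",
    "fel_from_cvs",
    "find_basins",
    "extract_decoys",
]


@dataclass
class CVSeries:
    """Per-frame collective-variable pairs.

    ``defined`` is False where the angle is geometrically degenerate
    (coincident centers); such frames are excluded from histogramming.
    """

    r1: np.ndarray          # Å
    r2: np.ndarray          # degrees in [0, 180] where defined
    frame_indices: np.ndarray
    defined: np.ndarray
    ligand_selection: str = ""
    reference_selection: str = ""

    def __post_init__(self) -> None:
        self.r1 = np.asarray(self.r1, dtype=float)
        self.r2 = np.asarray(self.r2, dtype=float)
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        self.defined = np.asarray(self.defined, dtype=bool)
        n = self.r1.size
        if not (self.r2.size == self.frame_indices.size == self.defined.size == n):
            raise ValueError("CV arrays must have equal length")
        if np.any(self.r1 < 0):
            raise ValueError("r1 must be non-negative")
        ok = self.defined
        if np.any((self.r2[ok] < 0) | (self.r2[ok] > 180)):
            raise ValueError("defined r2 must lie in [0, 180] degrees")


@dataclass
class FreeEnergySurface:
    """2D binned probability and relative free energy over (r1, r2)."""

    edges_r1: np.ndarray
    edges_r2: np.ndarray
    counts: np.ndarray            # (b1, b2) ints
    P: np.ndarray                 # normalized over populated bins
    deltaG: np.ndarray            # kcal/mol, NaN on empty bins, min 0
    temperature_K: float
    empty_mask: np.ndarray        # True where counts == 0
    kb: float = C.KB_KCAL

    @property
    def centers_r1(self) -> np.ndarray:
        return 0.5 * (self.edges_r1[:-1] + self.edges_r1[1:])

    @property
    def centers_r2(self) -> np.ndarray:
        return 0.5 * (self.edges_r2[:-1] + self.edges_r2[1:])

    def bin_of(self, r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
        """(n, 2) bin indices consistent with the histogramming convention
        (half-open bins, top edge closed)."""
        i = _digitize(np.asarray(r1, float), self.edges_r1)
        j = _digitize(np.asarray(r2, float), self.edges_r2)
        return np.stack([i, j], axis=-1)


@dataclass
class Basin:
    """A connected set of low-free-energy bins."""

    id: int
    member_bins: set
    minimum_bin: tuple
    deltaG_min: float


@dataclass(frozen=True)
class Decoy:
    """A representative frame for one basin."""

    basin_id: int
    frame_index: int
    r1: float
    r2: float


# --------------------------------------------------------------------------

def geometric_center(
    traj: Trajectory, sel: Selection, frame: int | None = None
) -> np.ndarray:
    """Unweighted mean of the selected coordinates.

    With ``frame=None`` returns centers for all frames, shape
    ``(n_frames, 3)``; otherwise a single 3-vector.
    """
    idx = sel.indices(traj.atoms)
    if idx.size == 0:
        raise SelectionError(f"selection {sel.expression!r} matches no atoms")
    if frame is None:
        return traj.coords[:, idx].mean(axis=1)
    return traj.coords[frame, idx].mean(axis=0)


def compute_cvs(
    traj: Trajectory,
    ligand_sel: Selection,
    reference_sel: Selection,
    protein_sel: Selection | None = None,
) -> CVSeries:
    """Distance and three-center angle per frame.

    r1 = |L − R|; r2 = angle at vertex R between rays R→L and R→C, where L,
    R, C are the ligand, reference-residue and protein geometric centers.
    The protein selection defaults to all non-ligand, non-water atoms.
    Frames with coincident centers get ``defined=False`` instead of failing.
    """
    if protein_sel is None:
        protein_sel = Selection("protein")
    L = geometric_center(traj, ligand_sel)
    R = geometric_center(traj, reference_sel)
    P = geometric_center(traj, protein_sel)

    u = L - R
    v = P - R
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    r1 = nu
    defined = (nu > 0) & (nv > 0)
    cosang = np.zeros(traj.n_frames)
    np.divide(
        np.einsum("ij,ij->i", u, v), nu * nv,
        out=cosang, where=defined,
    )
    r2 = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    r2[~defined] = np.nan
    return CVSeries(
        r1=r1, r2=r2, frame_indices=np.arange(traj.n_frames), defined=defined,
        ligand_selection=ligand_sel.expression,
        reference_selection=reference_sel.expression,
    )


def _digitize(x: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Half-open bins with the top edge closed (np.histogram convention)."""
    i = np.searchsorted(edges, x, side="right") - 1
    i[x == edges[-1]] = len(edges) - 2
    return i


def fel_from_cvs(
    cvs: CVSeries,
    n_bins: tuple[int, int] = (64, 64),
    temperature_K: float = C.DEFAULT_TEMPERATURE_K,
    edges: tuple[np.ndarray, np.ndarray] | None = None,
) -> FreeEnergySurface:
    """Boltzmann inversion of the 2D CV histogram.

    Bins span [min, max] of each defined CV unless explicit ``edges`` are
    given. ΔG is shifted so the minimum over populated bins is zero.
    """
    b1, b2 = n_bins
    if b1 < 2 or b2 < 2:
        raise ValueError("need at least 2 bins in each dimension")
    ok = cvs.defined
    if not np.any(ok):
        raise ValueError("no defined CV pairs to histogram")
    r1, r2 = cvs.r1[ok], cvs.r2[ok]
    if edges is None:
        counts, e1, e2 = np.histogram2d(r1, r2, bins=(b1, b2))
    else:
        e1, e2 = edges
        counts, _, _ = np.histogram2d(r1, r2, bins=(e1, e2))
    counts = counts.astype(int)
    total = counts.sum()
    P = counts / total
    empty = counts == 0
    with np.errstate(divide="ignore"):
        deltaG = -C.KB_KCAL * temperature_K * np.log(np.where(empty, 1.0, P))
    deltaG[empty] = np.nan
    deltaG -= np.nanmin(deltaG)
    return FreeEnergySurface(
        edges_r1=e1, edges_r2=e2, counts=counts, P=P, deltaG=deltaG,
        temperature_K=temperature_K, empty_mask=empty,
    )


# 8-connectivity: diagonal neighbours belong to the same basin
_CONN8 = np.ones((3, 3), dtype=int)


def find_basins(fes: FreeEnergySurface, max_deltaG: float = 2.0) -> list[Basin]:
    """Segment bins with ΔG ≤ threshold into 8-connected basins.

    Basins are ordered by their minimum ΔG ascending and re-numbered from 1.
    An empty list (no bin below threshold) is a valid result.
    """
    low = np.zeros_like(fes.deltaG, dtype=bool)
    populated = ~fes.empty_mask
    low[populated] = fes.deltaG[populated] <= max_deltaG
    labels, n = ndimage.label(low, structure=_CONN8)
    basins: list[Basin] = []
    for lab in range(1, n + 1):
        members = np.argwhere(labels == lab)
        dgs = fes.deltaG[members[:, 0], members[:, 1]]
        k = int(np.argmin(dgs))
        basins.append(Basin(
            id=0,
            member_bins={tuple(m) for m in members},
            minimum_bin=tuple(members[k]),
            deltaG_min=float(dgs[k]),
        ))
    basins.sort(key=lambda b: b.deltaG_min)
    for i, b in enumerate(basins, start=1):
        b.id = i
    return basins


def extract_decoys(
    fes: FreeEnergySurface, cvs: CVSeries, basins: list[Basin]
) -> list[Decoy]:
    """One representative frame per basin.

    The basin's most populated bin is located; among frames falling in that
    bin the frame whose (r1, r2) lies nearest the bin center is returned
    (Euclidean distance in bin-width-normalized CV units, ties broken by
    lowest frame index).
    """
    if not basins:
        raise ValueError("no basins to extract decoys from")
    ok = cvs.defined
    bins = fes.bin_of(cvs.r1[ok], cvs.r2[ok])
    frames = cvs.frame_indices[ok]
    r1, r2 = cvs.r1[ok], cvs.r2[ok]
    w1 = fes.edges_r1[1] - fes.edges_r1[0]
    w2 = fes.edges_r2[1] - fes.edges_r2[0]
    decoys: list[Decoy] = []
    for basin in basins:
        members = sorted(basin.member_bins)
        occ = [fes.counts[i, j] for i, j in members]
        bi, bj = members[int(np.argmax(occ))]
        in_bin = np.flatnonzero((bins[:, 0] == bi) & (bins[:, 1] == bj))
        assert in_bin.size > 0, "densest basin bin holds no frames"
        c1 = 0.5 * (fes.edges_r1[bi] + fes.edges_r1[bi + 1])
        c2 = 0.5 * (fes.edges_r2[bj] + fes.edges_r2[bj + 1])
        d2 = ((r1[in_bin] - c1) / w1) ** 2 + ((r2[in_bin] - c2) / w2) ** 2
        # argmin returns the first minimum; in_bin is frame-ordered, so ties
        # resolve to the lowest frame index
        best = in_bin[int(np.argmin(d2))]
        decoys.append(Decoy(
            basin_id=basin.id, frame_index=int(frames[best]),
            r1=float(r1[best]), r2=float(r2[best]),
        ))
    return decoys
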