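"""Protein–ligand contact typing across a trajectory.

Three contact types with purely distance-based criteria:

* direct hydrogen bond — donor heavy atom D with covalent H, acceptor A;
  reported iff d(H, A) ≤ 2.7 Å and d(D, A) ≤ 3.35 Å, one atom on the
  ligand and one on the protein. No angular criterion is applied.
* water bridge — a water molecule forming direct hydrogen bonds (same
  criteria) with at least one ligand atom and one protein atom in the same
  frame; one event per (ligand atom, protein atom, water) triple.
* hydrophobic — apolar–apolar pairs with 2.90 Å ≤ d ≤ 3.90 Å.

Periodic boundaries are not applied: the analysis region (an active site)
is assumed far smaller than the simulation box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants as C
from .io_formats import Trajectory
from .selections import Selection

__all__ = [
    "ContactEvent",
    "ContactSummary",
    "detect_hbonds",
    "detect_water_bridges",
    "detect_hydrophobic",
    "detect_all",
    "contact_occupancy",
]

DIRECT_HBOND = "direct-hbond"
WATER_BRIDGE = "water-bridge"
HYDROPHOBIC = "hydrophobic"


@dataclass(frozen=True)
class ContactEvent:
    frame_index: int
    type: str
    ligand_atom: int
    protein_atom: int
    bridge_water: int | None = None   # residue id of the bridging water
    d_HA: float | None = None
    d_DA: float | None = None
    d_CC: float | None = None


@dataclass
class ContactSummary:
    """Fraction of frames with ≥1 event, per (protein residue, type)."""

    n_frames: int
    occupancy: dict  # (residue_id, residue_name, type) -> fraction

    def as_records(self) -> list[dict]:
        return [
            {"residue_id": rid, "residue_name": rname, "type": typ,
             "occupancy": frac}
            for (rid, rname, typ), frac in sorted(self.occupancy.items())
        ]


class _FrameView:
    """Precomputed index groups and H attachments for one topology."""

    def __init__(self, traj: Trajectory):
        atoms = traj.atoms
        self.atoms = atoms
        elements = np.array([a.element.upper() for a in atoms])
        water = np.array(
            [a.residue_name.upper() in C.WATER_RESNAMES for a in atoms]
        )
        self.ligand = np.flatnonzero([a.is_ligand for a in atoms])
        self.protein = np.flatnonzero(
            [not a.is_ligand and not w for a, w in zip(atoms, water)]
        )
        self.water_atoms = np.flatnonzero(water)
        self.hydrogens = np.flatnonzero(elements == "H")
        role = np.array([a.hbond_role for a in atoms])
        self.donors = np.flatnonzero(np.isin(role, ["donor-heavy", "both"]))
        self.acceptors = np.flatnonzero(np.isin(role, ["acceptor", "both"]))
        self.apolar = np.flatnonzero([a.is_apolar for a in atoms])
        self.resid = np.array([a.residue_id for a in atoms])
        self.chain = np.array([a.chain for a in atoms])

    def attached_h(self, coords: np.ndarray) -> dict[int, np.ndarray]:
        """Map donor heavy atom -> indices of covalently attached hydrogens."""
        out: dict[int, np.ndarray] = {}
        if self.hydrogens.size == 0:
            return out
        hxyz = coords[self.hydrogens]
        for d in self.donors:
            dist = np.linalg.norm(hxyz - coords[d], axis=1)
            same = (self.resid[self.hydrogens] == self.resid[d]) & (
                self.chain[self.hydrogens] == self.chain[d]
            )
            hs = self.hydrogens[(dist < C.DONOR_H_ATTACH_A) & same]
            if hs.size:
                out[int(d)] = hs
        return out


def _direct_hbond_pairs(
    view: _FrameView,
    coords: np.ndarray,
    donors_from: np.ndarray,
    acceptors_from: np.ndarray,
    attached: dict[int, np.ndarray],
    fallback: bool,
) -> list[tuple[int, int, float | None, float]]:
    """(donor, acceptor, d_HA, d_DA) tuples meeting the cutoffs."""
    out = []
    donors = np.intersect1d(view.donors, donors_from)
    acceptors = np.intersect1d(view.acceptors, acceptors_from)
    if donors.size == 0 or acceptors.size == 0:
        return out
    dda = np.linalg.norm(
        coords[donors][:, None] - coords[acceptors][None], axis=-1
    )
    for di, d in enumerate(donors):
        hs = attached.get(int(d))
        for ai, a in enumerate(acceptors):
            if a == d or dda[di, ai] > C.HBOND_MAX_DA_A:
                continue
            if hs is not None and hs.size:
                dha = np.linalg.norm(coords[hs] - coords[a], axis=1)
                k = int(np.argmin(dha))
                if dha[k] <= C.HBOND_MAX_HA_A:
                    out.append((int(d), int(a), float(dha[k]), float(dda[di, ai])))
            elif fallback:
                out.append((int(d), int(a), None, float(dda[di, ai])))
    return out


def _require_hydrogens(view: _FrameView, fallback: bool) -> None:
    if view.hydrogens.size == 0 and view.donors.size > 0 and not fallback:
        raise ValueError(
            "structure has donor atoms but no hydrogens; enable "
            "donor_heavy_fallback to use the donor-acceptor cutoff alone"
        )


def detect_hbonds(
    traj: Trajectory,
    frame_index: int,
    donor_heavy_fallback: bool = False,
    _view: _FrameView | None = None,
) -> list[ContactEvent]:
    """Direct ligand–protein hydrogen bonds in one frame.

    One event per donor→acceptor pair. With ``donor_heavy_fallback`` (for
    hydrogen-free structures) the H–A criterion is skipped and only
    d(D, A) ≤ 3.35 Å is required.
    """
    view = _view or _FrameView(traj)
    _require_hydrogens(view, donor_heavy_fallback)
    coords = traj.coords[frame_index]
    attached = view.attached_h(coords)
    events: dict[tuple[int, int], ContactEvent] = {}
    for donors_from, acceptors_from, lig_is_donor in (
        (view.ligand, view.protein, True),
        (view.protein, view.ligand, False),
    ):
        for d, a, dha, dda in _direct_hbond_pairs(
            view, coords, donors_from, acceptors_from, attached,
            donor_heavy_fallback,
        ):
            lig, prot = (d, a) if lig_is_donor else (a, d)
            # one event per ligand-protein pair even if both atoms can donate
            events.setdefault((lig, prot), ContactEvent(
                frame_index=frame_index, type=DIRECT_HBOND,
                ligand_atom=lig, protein_atom=prot, d_HA=dha, d_DA=dda,
            ))
    return list(events.values())


def detect_water_bridges(
    traj: Trajectory,
    frame_index: int,
    donor_heavy_fallback: bool = False,
    _view: _FrameView | None = None,
) -> list[ContactEvent]:
    """Single-water-mediated ligand–protein hydrogen bonds in one frame."""
    view = _view or _FrameView(traj)
    _require_hydrogens(view, donor_heavy_fallback)
    coords = traj.coords[frame_index]
    attached = view.attached_h(coords)

    def water_partners(group: np.ndarray) -> dict[int, set[int]]:
        """water residue id -> set of partner atoms in `group`."""
        partners: dict[int, set[int]] = {}
        pairs = _direct_hbond_pairs(
            view, coords, view.water_atoms, group, attached, donor_heavy_fallback
        ) + _direct_hbond_pairs(
            view, coords, group, view.water_atoms, attached, donor_heavy_fallback
        )
        for d, a, _, _ in pairs:
            w, x = (d, a) if d in view.water_atoms else (a, d)
            partners.setdefault(int(view.resid[w]), set()).add(int(x))
        return partners

    lig_p = water_partners(view.ligand)
    prot_p = water_partners(view.protein)
    events = []
    for wres in sorted(set(lig_p) & set(prot_p)):
        for la in sorted(lig_p[wres]):
            for pa in sorted(prot_p[wres]):
                events.append(ContactEvent(
                    frame_index=frame_index, type=WATER_BRIDGE,
                    ligand_atom=la, protein_atom=pa, bridge_water=wres,
                ))
    return events


def detect_hydrophobic(
    traj: Trajectory,
    frame_index: int,
    _view: _FrameView | None = None,
) -> list[ContactEvent]:
    """Apolar ligand–protein pairs within the 2.90–3.90 Å window."""
    view = _view or _FrameView(traj)
    coords = traj.coords[frame_index]
    lig = np.intersect1d(view.ligand, view.apolar)
    prot = np.intersect1d(view.protein, view.apolar)
    if lig.size == 0 or prot.size == 0:
        return []
    d = np.linalg.norm(coords[lig][:, None] - coords[prot][None], axis=-1)
    li, pi = np.nonzero((d >= C.HYDROPHOBIC_MIN_A) & (d <= C.HYDROPHOBIC_MAX_A))
    return [
        ContactEvent(
            frame_index=frame_index, type=HYDROPHOBIC,
            ligand_atom=int(lig[i]), protein_atom=int(prot[j]),
            d_CC=float(d[i, j]),
        )
        for i, j in zip(li, pi)
    ]


def detect_all(
    traj: Trajectory,
    frame_index: int,
    donor_heavy_fallback: bool = False,
    _view: _FrameView | None = None,
) -> list[ContactEvent]:
    view = _view or _FrameView(traj)
    return (
        detect_hbonds(traj, frame_index, donor_heavy_fallback, _view=view)
        + detect_water_bridges(traj, frame_index, donor_heavy_fallback, _view=view)
        + detect_hydrophobic(traj, frame_index, _view=view)
    )


def contact_occupancy(
    traj: Trajectory, donor_heavy_fallback: bool = False
) -> ContactSummary:
    """Per protein residue and contact type, the fraction of frames with at
    least one event. Invariant under frame reordering.
    """
    if traj.n_frames < 1:
        raise ValueError("need at least one frame")
    view = _FrameView(traj)
    resname = {a.index: a.residue_name for a in traj.atoms}
    seen: dict[tuple, set[int]] = {}
    for f in range(traj.n_frames):
        for ev in detect_all(traj, f, donor_heavy_fallback, _view=view):
            rid = int(view.resid[ev.protein_atom])
            key = (rid, resname[ev.protein_atom], ev.type)
            seen.setdefault(key, set()).add(f)
    occ = {k: len(frames) / traj.n_frames for k, frames in seen.items()}
    return ContactSummary(n_frames=traj.n_frames, occupancy=occ)
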