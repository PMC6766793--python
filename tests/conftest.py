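"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive every criterion with plain Python
loops and explicit arithmetic so they share no code path with the
vectorized implementations they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from felgist.constants import (
    DONOR_H_ATTACH_A,
    HBOND_MAX_DA_A,
    HBOND_MAX_HA_A,
    HYDROPHOBIC_MAX_A,
    HYDROPHOBIC_MIN_A,
    WATER_RESNAMES,
)
from felgist.io_formats import AtomRecord, Trajectory, assign_roles


# --------------------------------------------------------------------------
# contact oracles (pure-python nested loops)
# --------------------------------------------------------------------------

def _dist(a, b) -> float:
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def _groups(traj: Trajectory):
    lig, prot, water = [], [], []
    for a in traj.atoms:
        if a.residue_name.upper() in WATER_RESNAMES:
            water.append(a.index)
        elif a.is_ligand:
            lig.append(a.index)
        else:
            prot.append(a.index)
    return lig, prot, water


def _oracle_attached_h(traj: Trajectory, coords) -> dict[int, list[int]]:
    out: dict[int, list[int]] = {}
    for d in traj.atoms:
        if d.hbond_role not in ("donor-heavy", "both"):
            continue
        hs = [
            h.index
            for h in traj.atoms
            if h.element.upper() == "H"
            and h.residue_id == d.residue_id
            and h.chain == d.chain
            and _dist(coords[h.index], coords[d.index]) < DONOR_H_ATTACH_A
        ]
        if hs:
            out[d.index] = hs
    return out


def _oracle_direct_pairs(traj, coords, group_a, group_b, attached):
    """All (donor in a, acceptor in b) pairs meeting the H-bond criteria."""
    pairs = []
    for d in group_a:
        if traj.atoms[d].hbond_role not in ("donor-heavy", "both"):
            continue
        hs = attached.get(d, [])
        if not hs:
            continue
        for a in group_b:
            if a == d or traj.atoms[a].hbond_role not in ("acceptor", "both"):
                continue
            if _dist(coords[d], coords[a]) > HBOND_MAX_DA_A:
                continue
            if min(_dist(coords[h], coords[a]) for h in hs) <= HBOND_MAX_HA_A:
                pairs.append((d, a))
    return pairs


def oracle_hbonds(traj: Trajectory, frame: int) -> set[tuple[int, int]]:
    """Direct ligand-protein H-bond pairs as (ligand_atom, protein_atom)."""
    coords = traj.coords[frame]
    lig, prot, _ = _groups(traj)
    attached = _oracle_attached_h(traj, coords)
    out = set()
    for d, a in _oracle_direct_pairs(traj, coords, lig, prot, attached):
        out.add((d, a))
    for d, a in _oracle_direct_pairs(traj, coords, prot, lig, attached):
        out.add((a, d))
    return out


def oracle_water_bridges(traj: Trajectory, frame: int) -> set[tuple[int, int, int]]:
    """(ligand_atom, protein_atom, water_resid) bridge triples."""
    coords = traj.coords[frame]
    lig, prot, water = _groups(traj)
    attached = _oracle_attached_h(traj, coords)
    by_res: dict[int, list[int]] = {}
    for w in water:
        by_res.setdefault(traj.atoms[w].residue_id, []).append(w)
    out = set()
    for wres, watoms in by_res.items():
        lig_partners = set()
        prot_partners = set()
        for group, partners in ((lig, lig_partners), (prot, prot_partners)):
            for d, a in _oracle_direct_pairs(traj, coords, watoms, group, attached):
                partners.add(a)
            for d, a in _oracle_direct_pairs(traj, coords, group, watoms, attached):
                partners.add(d)
        for la in lig_partners:
            for pa in prot_partners:
                out.add((la, pa, wres))
    return out


def oracle_hydrophobic(traj: Trajectory, frame: int) -> set[tuple[int, int]]:
    coords = traj.coords[frame]
    lig, prot, _ = _groups(traj)
    out = set()
    for i in lig:
        if not traj.atoms[i].is_apolar:
            continue
        for j in prot:
            if not traj.atoms[j].is_apolar:
                continue
            if HYDROPHOBIC_MIN_A <= _dist(coords[i], coords[j]) <= HYDROPHOBIC_MAX_A:
                out.add((i, j))
    return out


# --------------------------------------------------------------------------
# randomized contact fixtures
# --------------------------------------------------------------------------

def random_contact_trajectory(rng: np.random.Generator, box: float = 9.0) -> Trajectory:
    """A dense random frame mixing ligand, protein and water atoms.

    Roughly a third of the heavy atoms are ligand, a third protein (some
    with a covalent hydrogen), and the rest waters (O + 2 H); the small box
    makes every contact type occur often. Total atom count stays <= 200.
    """
    records: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    idx = 0

    def add(name, element, res, rid, xyz):
        nonlocal idx
        records.append(AtomRecord(idx, name, element, res, rid))
        coords.append(np.asarray(xyz, dtype=float))
        idx += 1

    n_lig = int(rng.integers(5, 15))
    for i in range(n_lig):
        el = rng.choice(["C", "O", "N"], p=[0.5, 0.3, 0.2])
        add(f"L{i}", el, "LIG", 500, rng.uniform(0, box, 3))
        if el in ("O", "N") and rng.random() < 0.5:
            add(f"HL{i}", "H", "LIG", 500,
                coords[-1] + _random_unit(rng) * rng.uniform(0.95, 1.05))
    n_prot = int(rng.integers(10, 30))
    for i in range(n_prot):
        el = rng.choice(["C", "O", "N", "S"], p=[0.45, 0.25, 0.25, 0.05])
        rid = 100 + i
        add(f"P{i}", el, "ALA", rid, rng.uniform(0, box, 3))
        if el in ("O", "N") and rng.random() < 0.5:
            add(f"HP{i}", "H", "ALA", rid,
                coords[-1] + _random_unit(rng) * rng.uniform(0.95, 1.05))
    n_wat = int(rng.integers(5, 20))
    for i in range(n_wat):
        rid = 700 + i
        o = rng.uniform(0, box, 3)
        add("O", "O", "HOH", rid, o)
        for k in range(2):
            add(f"H{k + 1}", "H", "HOH", rid,
                o + _random_unit(rng) * 0.96)

    xyz = np.asarray(coords)[None]
    atoms = assign_roles(records, xyz[0], {"ligand_resnames": ["LIG"]})
    return Trajectory(atoms, xyz)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
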