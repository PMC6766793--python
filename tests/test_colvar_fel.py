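"""Collective variables, Boltzmann inversion, basins and decoys."""

import numpy as np
import pytest

from felgist.colvar_fel import (
    CVSeries,
    compute_cvs,
    extract_decoys,
    fel_from_cvs,
    find_basins,
    geometric_center,
)
from felgist.io_formats import AtomRecord, Trajectory
from felgist.selections import Selection, SelectionError
from felgist.synthetic_data import FelSyntheticSpec, make_fel_trajectory

KT300_LN2 = 0.41322747573364904  # 0.0019872041 * 300 * ln 2, frozen


def _point_traj(points, resnames=None):
    """One frame with one atom per point; atom i has resid i+1."""
    n = len(points)
    resnames = resnames or ["ALA"] * n
    atoms = [
        AtomRecord(i, f"X{i}", "C", resnames[i], i + 1,
                   is_ligand=resnames[i] == "LIG")
        for i in range(n)
    ]
    return Trajectory(atoms, np.asarray(points, dtype=float)[None])


class TestGeometricCenter:
    def test_single_atom_identity(self):
        traj = _point_traj([[1, 2, 3]])
        assert np.allclose(geometric_center(traj, Selection("resid 1"), 0),
                           [1, 2, 3])

    def test_midpoint(self):
        traj = _point_traj([[0, 0, 0], [2, 0, 0]])
        assert np.allclose(
            geometric_center(traj, Selection("resid 1-2"), 0), [1, 0, 0])

    def test_matches_bruteforce_mean(self, rng):
        pts = rng.uniform(-10, 10, (7, 3))
        traj = _point_traj(pts)
        expected = [sum(p[d] for p in pts) / 7 for d in range(3)]
        got = geometric_center(traj, Selection("resid 1-7"), 0)
        assert np.allclose(got, expected, atol=1e-12)

    def test_empty_selection_errors(self):
        traj = _point_traj([[0, 0, 0]])
        with pytest.raises(SelectionError):
            geometric_center(traj, Selection("resname XXX"), 0)


class TestComputeCvs:
    def test_collinear_opposite(self):
        # ligand opposite the protein core across the reference center
        traj = _point_traj(
            [[0, 0, 5], [0, 0, 0], [0, 0, -10]],
            resnames=["LIG", "GLU", "GLY"],
        )
        cvs = compute_cvs(traj, Selection("ligand"), Selection("resid 2"),
                          protein_sel=Selection("resid 3"))
        assert cvs.r1[0] == pytest.approx(5.0)
        assert cvs.r2[0] == pytest.approx(180.0)

    def test_coincident_centers_flagged_undefined(self):
        traj = _point_traj(
            [[0, 0, 0], [0, 0, 0], [0, 0, -10]],
            resnames=["LIG", "GLU", "GLY"],
        )
        cvs = compute_cvs(traj, Selection("ligand"), Selection("resid 2"),
                          protein_sel=Selection("resid 3"))
        assert cvs.r1[0] == 0.0
        assert not cvs.defined[0]

    def test_matches_trigonometry_oracle(self, rng):
        for _ in range(20):
            L, R, P = rng.uniform(-8, 8, (3, 3))
            traj = _point_traj([L, R, P], resnames=["LIG", "GLU", "GLY"])
            cvs = compute_cvs(traj, Selection("ligand"), Selection("resid 2"),
                              protein_sel=Selection("resid 3"))
            u, v = L - R, P - R
            r1 = np.sqrt(np.dot(u, u))
            r2 = np.degrees(np.arccos(
                np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))))
            assert cvs.r1[0] == pytest.approx(r1, abs=1e-9)
            assert cvs.r2[0] == pytest.approx(r2, abs=1e-9)


def _cvs_from_arrays(r1, r2):
    n = len(r1)
    return CVSeries(np.asarray(r1, float), np.asarray(r2, float),
                    np.arange(n), np.ones(n, bool))


class TestFelFromCvs:
    def test_uniform_counts_give_flat_landscape(self):
        # one sample exactly at each of 3x3 bin centers
        g1, g2 = np.meshgrid(np.arange(3) + 0.5, np.arange(3) * 10 + 5)
        cvs = _cvs_from_arrays(g1.ravel(), g2.ravel())
        fes = fel_from_cvs(cvs, n_bins=(3, 3))
        assert np.allclose(fes.deltaG, 0.0)
        assert not fes.empty_mask.any()

    def test_two_bin_closed_form(self):
        r1 = np.concatenate([np.full(100, 0.25), np.full(50, 0.75)])
        r2 = np.full(150, 90.0)
        r2[:2] = [89.0, 91.0]  # spread r2 so both its bins are populated
        cvs = _cvs_from_arrays(r1, np.sort(r2))
        fes = fel_from_cvs(cvs, n_bins=(2, 2), temperature_K=300.0)
        margin = np.nansum(np.where(fes.empty_mask, np.nan, fes.counts), axis=1)
        assert list(margin) == [100, 50]
        dg_r1 = -0.0019872041 * 300 * np.log(
            fes.counts.sum(axis=1) / fes.counts.sum())
        assert dg_r1[1] - dg_r1[0] == pytest.approx(KT300_LN2, abs=1e-9)

    def test_probability_conserved_and_min_zero(self, rng):
        cvs = _cvs_from_arrays(rng.uniform(0, 10, 500), rng.uniform(0, 180, 500))
        fes = fel_from_cvs(cvs, n_bins=(8, 8))
        assert fes.P.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.nanmin(fes.deltaG) == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(fes.deltaG[fes.empty_mask]).all()

    def test_count_scale_invariance(self, rng):
        r1 = rng.uniform(0, 10, 300)
        r2 = rng.uniform(0, 180, 300)
        fes1 = fel_from_cvs(_cvs_from_arrays(r1, r2), n_bins=(6, 6))
        fes3 = fel_from_cvs(
            _cvs_from_arrays(np.tile(r1, 3), np.tile(r2, 3)), n_bins=(6, 6))
        ok = ~fes1.empty_mask
        assert np.allclose(fes1.deltaG[ok], fes3.deltaG[ok], atol=1e-12)

    def test_temperature_linearity(self, rng):
        r1 = rng.uniform(0, 10, 400)
        r2 = rng.uniform(0, 180, 400)
        f300 = fel_from_cvs(_cvs_from_arrays(r1, r2), (6, 6), temperature_K=300)
        f600 = fel_from_cvs(_cvs_from_arrays(r1, r2), (6, 6), temperature_K=600)
        ok = ~f300.empty_mask
        assert np.allclose(f600.deltaG[ok], 2 * f300.deltaG[ok], atol=1e-12)

    def test_rejects_single_bin(self):
        cvs = _cvs_from_arrays([1, 2], [10, 20])
        with pytest.raises(ValueError):
            fel_from_cvs(cvs, n_bins=(1, 4))


class TestRecovery:
    def test_two_well_surface_recovered(self):
        spec = FelSyntheticSpec(
            basin_centers=[[5.0, 60.0], [12.0, 130.0]],
            basin_depths_kcal=[0.0, 0.5],
            basin_widths=[2.0, 2.0],
            n_frames=50000, seed=11,
        )
        traj, surface = make_fel_trajectory(spec)
        cvs = compute_cvs(traj, Selection("ligand"), Selection("resid 378"))
        fes = fel_from_cvs(cvs, n_bins=(64, 64))
        ii, jj = np.nonzero(fes.counts >= 50)
        est = fes.deltaG[ii, jj]
        true = surface.delta_g(fes.centers_r1[ii], fes.centers_r2[jj])
        est = est - est.min()
        true = true - true.min()
        rmse = float(np.sqrt(np.mean((est - true) ** 2)))
        assert rmse < 0.15

    def test_rmse_decreases_with_sampling(self):
        # evaluate all runs on one fixed bin set (low true ΔG, populated in
        # every run) so the error measure is comparable across sample sizes
        surfaces = []
        for n in (5000, 20000, 80000):
            spec = FelSyntheticSpec(
                basin_centers=[[5.0, 60.0], [12.0, 130.0]],
                basin_depths_kcal=[0.0, 0.5],
                basin_widths=[2.0, 2.0],
                n_frames=n, seed=17,
            )
            traj, surface = make_fel_trajectory(spec)
            cvs = compute_cvs(traj, Selection("ligand"), Selection("resid 378"))
            fes = fel_from_cvs(
                cvs, n_bins=(48, 48),
                edges=(np.linspace(0, 19, 49), np.linspace(40, 160, 49)))
            surfaces.append((fes, surface))
        c1 = surfaces[0][0].centers_r1
        c2 = surfaces[0][0].centers_r2
        true_grid = surfaces[0][1].delta_g(c1[:, None], c2[None, :])
        mask = (true_grid <= 2.0)
        for fes, _ in surfaces:
            mask &= fes.counts > 0
        true = true_grid[mask]
        rmses = []
        for fes, _ in surfaces:
            est = fes.deltaG[mask]
            rmses.append(float(np.sqrt(np.mean(
                (est - est.min() - (true - true.min())) ** 2))))
        assert rmses[0] > rmses[1] > rmses[2]


def _surface_fes(deltaG):
    """Wrap an explicit ΔG array (NaN = empty) as a FreeEnergySurface."""
    from felgist.colvar_fel import FreeEnergySurface

    deltaG = np.asarray(deltaG, dtype=float)
    b1, b2 = deltaG.shape
    counts = np.where(np.isnan(deltaG), 0, 100).astype(int)
    return FreeEnergySurface(
        edges_r1=np.arange(b1 + 1, dtype=float),
        edges_r2=np.arange(b2 + 1, dtype=float),
        counts=counts, P=counts / counts.sum(), deltaG=deltaG,
        temperature_K=300.0, empty_mask=counts == 0,
    )


class TestBasins:
    def test_single_well(self):
        dg = np.full((5, 5), 5.0)
        dg[2, 2] = 0.0
        dg[2, 3] = 0.5
        basins = find_basins(_surface_fes(dg), max_deltaG=1.0)
        assert len(basins) == 1
        assert basins[0].minimum_bin == (2, 2)
        assert basins[0].member_bins == {(2, 2), (2, 3)}

    def test_two_wells_separated_by_barrier(self):
        dg = np.full((7, 7), 4.0)
        dg[1, 1] = 0.0
        dg[5, 5] = 0.3
        basins = find_basins(_surface_fes(dg), max_deltaG=2.0)
        assert len(basins) == 2
        assert basins[0].deltaG_min == 0.0  # ordered by depth
        assert basins[1].minimum_bin == (5, 5)

    def test_diagonal_bins_are_connected(self):
        dg = np.full((4, 4), 4.0)
        dg[0, 0] = 0.0
        dg[1, 1] = 0.5
        assert len(find_basins(_surface_fes(dg), max_deltaG=1.0)) == 1

    def test_threshold_below_everything_gives_empty(self):
        dg = np.full((3, 3), 1.0)
        dg[0, 0] = 0.5
        assert find_basins(_surface_fes(dg), max_deltaG=0.4) == []

    def test_vanishing_threshold_isolates_global_minimum(self):
        dg = np.full((5, 5), 3.0)
        dg[3, 1] = 0.0
        basins = find_basins(_surface_fes(dg), max_deltaG=1e-9)
        assert len(basins) == 1
        assert basins[0].member_bins == {(3, 1)}


class TestDecoys:
    def test_single_frame_in_densest_bin(self):
        cvs = _cvs_from_arrays([0.5, 3.5], [0.5, 3.5])
        fes = fel_from_cvs(cvs, n_bins=(4, 4))
        basins = find_basins(fes, max_deltaG=1.0)
        decoys = extract_decoys(fes, cvs, basins)
        assert {d.frame_index for d in decoys} == {0, 1}

    def test_tie_broken_by_lowest_frame_index(self):
        # two frames symmetric about the bin center of the only populated bin
        cvs = _cvs_from_arrays([0.4, 0.6, 5.0], [0.4, 0.6, 5.0])
        fes = fel_from_cvs(
            cvs, n_bins=(2, 2),
            edges=(np.array([0.0, 1.0, 10.0]), np.array([0.0, 1.0, 10.0])))
        basins = find_basins(fes, max_deltaG=0.1)
        decoys = extract_decoys(fes, cvs, basins)
        assert decoys[0].frame_index == 0

    def test_matches_exhaustive_nearest_frame_search(self, rng):
        r1 = rng.uniform(0, 10, 400)
        r2 = rng.uniform(0, 180, 400)
        cvs = _cvs_from_arrays(r1, r2)
        fes = fel_from_cvs(cvs, n_bins=(5, 5))
        basins = find_basins(fes, max_deltaG=10.0)
        for d in extract_decoys(fes, cvs, basins):
            basin = next(b for b in basins if b.id == d.basin_id)
            occ = {bin_: fes.counts[bin_] for bin_ in basin.member_bins}
            bi, bj = min(occ, key=lambda b: (-occ[b], b))
            c1 = (fes.edges_r1[bi] + fes.edges_r1[bi + 1]) / 2
            c2 = (fes.edges_r2[bj] + fes.edges_r2[bj + 1]) / 2
            w1 = fes.edges_r1[1] - fes.edges_r1[0]
            w2 = fes.edges_r2[1] - fes.edges_r2[0]
            best, best_d = None, np.inf
            for f in range(400):
                bins = fes.bin_of(np.array([r1[f]]), np.array([r2[f]]))[0]
                if (bins[0], bins[1]) != (bi, bj):
                    continue
                dist = ((r1[f] - c1) / w1) ** 2 + ((r2[f] - c2) / w2) ** 2
                if dist < best_d - 1e-15:
                    best, best_d = f, dist
            assert d.frame_index == best
            # the decoy's CVs fall inside the basin's densest bin
            db = fes.bin_of(np.array([d.r1]), np.array([d.r2]))[0]
            assert (db[0], db[1]) == (bi, bj)
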