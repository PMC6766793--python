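# felgist

Post-processing toolkit for protein–ligand molecular-dynamics trajectories,
built around the analyses used to study product release in glucose-tolerant
β-glucosidases: where does the sugar sit relative to the catalytic site, how
is the active-site water organized, and which contacts hold the ligand in
place.

It is aimed at computational structural biologists who already have
trajectories (multi-model PDB / XYZ) or per-voxel solvation grids (OpenDX)
and want reproducible, testable post-processing rather than one-off scripts.

## What it computes

**Free-energy landscape (FEL).** Two collective variables per frame:
r₁, the distance between the geometric centers of the ligand and a reference
residue in the catalytic site, and r₂, the angle at the reference center
between the directions to the ligand and to the whole-protein center. The
relative free energy over the 2D histogram is the Boltzmann inversion

    ΔG(r₁, r₂) = −k_B T ln P(r₁, r₂),

shifted so the global minimum is zero; empty bins stay undefined. Minima are
segmented into basins (8-connected bins under a ΔG ceiling) and one
representative frame ("decoy") is extracted per basin from its most
populated bin.

**Hydration sites (GIST post-processing).** Given per-voxel fields — water
occupancy g(O) in multiples of the bulk density (0.0329 molecules/Å³ for
TIP3P), solute–water energy ΔE_sw, raw water–water energy E_ww, and
temperature-multiplied entropies TΔS_trans, TΔS_orient — the per-voxel
transfer free energy relative to bulk is

    ΔG_solv = ΔE_sw + (E_ww − E_ww(Ref)) − TΔS_trans − TΔS_orient,
    E_ww(Ref) = (−9.533 kcal/mol) · (0.0329 Å⁻³) · g(O) = −0.3136 · g(O) kcal/mol.

Voxels with g(O) ≥ 10 and |ΔG_solv| ≥ 3 kcal/mol are classified as
favorable (≤ −3) or unfavorable (≥ +3) hydration sites. Water-oxygen
density binning onto 0.5 Å grids and conformer-weighted averaging
ΔG_solv ≈ Σ_q ΔG_solv(q) p(q) are included.

**Contacts.** Direct hydrogen bonds (d(H,A) ≤ 2.7 Å and d(D,A) ≤ 3.35 Å),
single-water bridges (a water H-bonded to both ligand and protein in the
same frame), and hydrophobic contacts (apolar pairs at 2.90–3.90 Å), with
per-residue occupancy fractions across the trajectory.

**Trajectory statistics.** All-frames-against-all-frames backbone RMSD with
pairwise optimal superposition (Kabsch), and covariance-matrix PCA after
alignment to the iteratively refined average structure — including ligand
PCA aligned on the protein backbone, which retains the ligand's
translational/rotational motion inside the site.

**Synthetic data.** Generators with exact ground truth (a Boltzmann sampler
for multi-basin CV surfaces, Poisson water hotspots over bulk, analytic
hydration fields, planted contact geometries) validate every stage.

## Worked example

```sh
felgist demo --seed 1 --out demo/
```

runs the whole pipeline on synthetic inputs and prints:

```
demo seed=1
fel: 2 basins, decoys at frames [14032, 12260]
gist: 2 hydration sites (1 unfavorable); binned mean g(O)=1.059
contacts: direct-hbond=1, water-bridge=1, hydrophobic=1
stats: max pairwise backbone rmsd 0.283 A; ligand PC1 variance fraction 0.701
```

Reading the output: the two-well synthetic surface is recovered as exactly
two FEL basins and one representative frame is pulled from each well's most
populated bin; the two planted hydration hotspots are both classified (the
+3.5 kcal/mol one as unfavorable, i.e. water the protein would rather
exclude), and binning the Poisson bulk water returns g(O) ≈ 1 as it must
for unperturbed solvent; the three planted contact geometries are each
detected exactly once; and the ligand's first principal component carries
~70% of its variance, reflecting its dominant drift direction inside the
site. Tables (`fel.tsv`, `decoys.tsv`, `sites.tsv`, `contacts.tsv`) and
grids (`gO.dx`) are written next to `report.txt`.

The same stages are available on your own data, e.g.:

```sh
felgist fel --traj traj.pdb --ligand "resname GLC" --reference "resid 378" \
        --bins 64 64 --temp 300 --out fel.tsv
felgist gist --go gO.dx --esw esw.dx --eww eww.dx \
        --tds-trans t.dx --tds-orient o.dx --out sites.tsv
felgist contacts --traj traj.pdb --ligand-resnames GLC \
        --out events.tsv --summary occupancy.tsv
```

## Scope

The package post-processes trajectories and fields; it does not run MD,
estimate entropies from raw coordinates, or solve the Poisson–Boltzmann
equation. See `docs/methods.md` for the model details, parameter defaults
and known limitations.
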