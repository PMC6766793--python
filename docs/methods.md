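# Methods

This note documents the models implemented in `felgist`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the package's numerical conventions.

## Collective variables and the free-energy landscape

For each frame, r₁ is the Cartesian distance between the unweighted
geometric centers of the ligand selection and a reference-residue
selection; r₂ is the angle, in degrees, at the reference-residue center
between the rays toward the ligand center and toward the geometric center
of the whole protein (all non-ligand, non-water atoms). The angle vertex is
a genuine modelling choice — the three centers define three candidate
vertices — and we place it at the reference residue so that r₂ measures
whether the ligand lies toward or away from the protein core relative to
the catalytic cleft; the protein selection is configurable if a different
convention is wanted. Frames with coincident centers are flagged undefined
and excluded from histogramming rather than failing the run.

The landscape is the raw histogram inversion ΔG = −k_B T ln P with
k_B = 0.0019872041 kcal·mol⁻¹·K⁻¹ and T defaulting to 300 K. Binning is
half-open with the top edge closed over the sampled range (64 × 64 bins by
default — enough to resolve multi-well structure at 10⁴–10⁵ frames without
starving bins). Consequences of the raw inversion that the code preserves
deliberately:

* ΔG is relative: the minimum over populated bins is shifted to zero.
* Empty bins are masked, never imputed. ln 0 is undefined, and any
  pseudo-count would fabricate barrier heights exactly where the data say
  nothing.
* Multiplying all counts by a constant leaves ΔG unchanged, and ΔG scales
  linearly in T for fixed counts; both are asserted in tests.

Basins are 8-connected components of bins with ΔG at or below a ceiling
(default 2 kcal/mol — wells, not barrier tops), ordered by their minimum.
Per basin, the representative frame is chosen in its most populated bin as
the frame whose CV pair is nearest the bin center in bin-width-normalized
units, ties resolved to the lowest frame index. Normalizing by bin width
keeps the Å-valued distance and degree-valued angle commensurable.

## Hydration thermodynamics

The per-voxel transfer free energy of water relative to bulk is assembled
as

    ΔG_solv = ΔE_sw + ΔE_ww − TΔS_trans − TΔS_orient

on a cubic grid (default spacing 0.5 Å, voxel volume 0.125 Å³). The
reference state is pure TIP3P water: the solute–water energy and both
entropies reference to zero, while the water–water term references to the
bulk pairwise interaction energy of −9.533 kcal/mol scaled by how strongly
the voxel retains water:

    E_ww(Ref) = (−9.533 kcal/mol) × (0.0329 Å⁻³) × g(O) = −0.3136 · g(O) kcal/mol.

The −0.3136 coefficient is always recomputed from the two reference
constants, never hard-coded; a test asserts the product agrees with the
documented 4-significant-figure value. The printed equality treats the
voxel as the unit of volume; whether an additional voxel-volume factor
belongs in the coefficient is a dialect question the implementation
resolves by following the equality exactly and exposing a
`density_weighted` flag for fields supplied in kcal/mol/Å³ (multiplied by
0.125 Å³ on ingestion). Entropy inputs are taken as TΔS in kcal/mol,
i.e. already temperature-multiplied.

g(O) is the average per-frame number density of water-oxygen centers per
voxel divided by the bulk density 0.0329 molecules/Å³. Voxel membership is
half-open (a point on a face belongs to the upper voxel), so boundary
oxygens are never double-counted; oxygens outside the analysis grid are
ignored with a logged count, since the grid covers the active site only.

Hydration sites require g(O) ≥ 10 (strongly retained water) and
|ΔG_solv| ≥ 3 kcal/mol, both inclusive as documented; sites are labelled
favorable (≤ −3) or unfavorable (≥ +3) and sorted by |ΔG_solv| descending.
Conformer averaging is the probability-weighted sum Σ ΔG_solv(q)·p(q),
voxel-wise for fields, with weights validated to be non-negative and sum
to 1 within 1e-9.

## Contacts

All criteria are distance-only: hydrogen bonds require d(H, A) ≤ 2.7 Å and
d(D, A) ≤ 3.35 Å; hydrophobic contacts are apolar–apolar pairs within
2.90–3.90 Å. The absence of an angular hydrogen-bond criterion is a
documented limitation, not an oversight. A water bridge is a single water
forming direct hydrogen bonds with at least one ligand atom and one
protein atom in the same frame, reported per
(ligand atom, protein atom, water) triple.

Role assignment defaults: N/O heavy atoms with a covalently attached
hydrogen (within 1.25 Å, same residue) are donors, N/O/S are acceptors,
C/S are apolar; all overridable. In hydrogen-free structures (crystal
coordinates) every N/O is treated as a potential donor, and an optional
donor-heavy fallback applies the D–A cutoff alone; it is off by default
because MD frames carry hydrogens. One event is reported per
ligand–protein pair even when both partners could donate. Periodic
boundaries are not applied: the analysis region is assumed far smaller
than the simulation box. Occupancy is the fraction of frames with at least
one event per (protein residue, contact type), invariant under frame
reordering.

## Trajectory statistics

Superposition is the least-squares rigid fit restricted to proper
rotations, uniform-weighted (appropriate for backbone-only selections,
where masses are nearly equal anyway); fewer than three atoms or collinear
selections are rejected. The 2D-RMSD matrix uses an independent best fit
per frame pair — the common tool behavior and the conservative reading of
"all frames against all frames"; it is symmetric with a zero diagonal by
construction. PCA aligns every frame to the average structure, recomputing
the average until it moves less than 1e-6 Å (error after 100 iterations),
then diagonalizes the covariance (ddof = 1) of the analysis selection's 3N
coordinates. Backbone means atoms named CA, C, O, N in amino-acid
residues. For ligand PCA the alignment selection is the protein backbone,
so the leading components include the ligand's translation and rotation
inside the site — that is the signal of interest, not an artifact.

## Synthetic data: what it emulates and what it does not

`make_fel_trajectory` samples CV pairs i.i.d. from the Boltzmann density
exp(−G/k_B T) of an analytic multi-Gaussian-well surface (component mass ∝
exp(depth/k_B T) × σ², so equal wells are equally occupied), then embeds
each pair exactly in 3D: the reference center at the origin, the protein
center at (0, 0, −10) Å, the ligand center at r₁·(sin r₂, 0, −cos r₂).
Sampling in CV space first guarantees that the planted surface is exactly
the binned density the estimator sees — the histogram inversion is a raw
density estimate, so this is the correct target for a recovery test.
Draws outside the representable range (r₁ < 0, r₂ ∉ [0, 180]°) are
rejected and redrawn; with the default well placements the rejected mass
is negligible. What this does not emulate: autocorrelated dynamics,
barrier crossings in time, protein flexibility (beyond optional Gaussian
jitter on the scaffold), or the 3D Jacobian of a real distance-angle
embedding. Passing recovery tests therefore demonstrate estimator
correctness, not sampling convergence of real MD.

`make_water_trajectory` draws per-voxel per-frame counts from a Poisson
law with mean ρ·(0.125 Å³) — ρ the bulk 0.0329 Å⁻³ except at hotspot
voxels, where it is g_O × bulk — and scatters oxygens uniformly within
each voxel. Because Poisson totals vary per frame, the output is a ragged
`WaterEnsemble` rather than a fixed-topology `Trajectory`. Real water is
spatially correlated (excluded volume, hydrogen-bond structure); Poisson
water tests only the binning and normalization arithmetic.

`make_hydration_fields` is deterministic: background voxels carry g(O)=1
with the raw water–water energy set exactly to the bulk reference (so
ΔG_solv = 0), and each hotspot's ΔG target is placed in the solute–water
term. Recovery is therefore exact by construction, which is precisely what
makes it a bookkeeping test of the assembly and classification, not of
force-field physics.

`make_contact_fixture` plants each contact unit 15 Å from its neighbours
(cutoffs are all < 4 Å) with analytic geometry realizing the requested
distances exactly, and places decoy apolar atoms > 20 Å away (the contract
requires > 5 Å).

All generators are deterministic under a fixed seed and emit their ground
truth in machine-readable form.

## Problem sizes and runtime

The validation suite uses 50,000 frames for FEL recovery (bin-wise RMSE on
bins with ≥ 50 counts, measured at ~0.06 kcal/mol against a 0.15 bound),
2,000 frames on a 12³ grid for density self-consistency (mean g(O) within
2% of 1), 50 randomized ≤ 200-atom frames for the contact oracle
comparison, and 40–200 frame trajectories for the statistics identities.
These sizes give comfortable statistical margins while keeping the full
suite and the acceptance script each under a few seconds on one CPU.

## Known limitations

* No reweighting of biased sampling (WHAM/MBAR) and no kinetics between
  basins; the FEL is a raw histogram inversion.
* Entropy and energy fields are consumed, never estimated; the package
  assumes upstream GIST-style output.
* Distance-only contact criteria; no π-stacking or CH–π classification.
* No periodic-boundary handling in distances.
* PDB/XYZ text trajectories only; binary formats (DCD/NetCDF) and mmCIF
  are out of scope.
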