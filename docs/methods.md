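# Methods

This note records the model, the numerical conventions, and the design
decisions behind the package, in the spirit of a software methods section.

## Model

CoMSIA-type 3D-QSAR replaces the probe-energy fields of CoMFA with similarity
indices: smooth, cutoff-free Gaussian sums evaluated on a lattice shared by
all molecules. For a molecule with sources (c_i, w_i) the field value at grid
point q is Σ_i w_i·exp(−α‖q−c_i‖²). Because every field is a linear
functional of unit Gaussians, fields are additive in sources, strictly
decreasing in distance from an isolated source, and strictly decreasing in α
at any non-source point — all of which are enforced as property tests.

Five fields are computed per molecule. Steric sources are all atoms weighted
by vdW radius cubed; electrostatic sources carry signed Gasteiger charges;
hydrophobic sources carry signed Crippen atomic logP contributions. Donor and
acceptor fields use unit-weight pseudoatoms representing idealized H-bond
partner positions: donors along each X–H bond ray, acceptors along lone-pair
directions derived from VSEPR geometry (sp²-with-one-neighbor: two in-plane
directions at ±120° from the bond; sp³: directions completing the
tetrahedron; sp, saturated-coordination and geometry-degenerate cases fall
back to a single anti-bond direction, with a warning collected in the run's
warnings file). Fields are reported as raw similarity sums under an implicit
+1 probe; no probe-sign flip is applied. PLS is invariant to that convention
up to the sign of the coefficients, and contour interpretation follows the
sign of coefficient × column SD.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| grid spacing | 1.0 | Å | lattice resolution; cost grows as spacing⁻³ |
| grid padding | 4.0 | Å | margin beyond the snapped atomic extremes |
| attenuation α | 0.3 | Å⁻² | Gaussian decay; larger = more local fields |
| pseudoatom distance | 1.9 | Å | heavy-atom → H-bond partner site |
| clash factor | 0.7 | — | pseudoatom rejected within 0.7·vdW of a non-parent atom |
| top fraction | 0.05 | — | contour percentile per tail |
| max components | min(10, n−2) | — | LOOCV search range |
| column filter | off | field units | drop columns with range < threshold |

The spacing/padding/α defaults are the standard parameterization of the
corticosteroid benchmark study design this package targets.

## Grid conventions

Atomic coordinates are snapped to the lattice (rounding each component to the
nearest multiple of the spacing, half-way cases away from zero), the snapped
extremes are padded, and dims = ceil(range/spacing) + 1 per axis so both
padded extremes are lattice points. Points are enumerated x-fastest; the
ordering is bookkeeping only and PLS statistics are invariant to any
consistent reordering. Snapping applies to the atom-centered S/E/H sources
(`snap=False` preserves raw coordinates for sensitivity analysis). H-bond
pseudoatom geometry is always computed from raw coordinates: with a 1 Å grid,
snapping an ~1 Å X–H bond can collapse the hydrogen onto its heavy atom and
destroy the ray direction, and the raw-geometry choice keeps the pseudoatom
exactly at the nominal distance from its parent atom. The grid is built over
training and held-out molecules jointly, so every row shares one frame.

Hydrogens are made explicit (with coordinates) before annotation: the charge
model and donor geometry need them. Whether nonpolar hydrogens contribute to
the S/E/H fields is configurable (`include_hydrogens`, default on). The
donor placement ambiguity — site at 1.9 Å from the heavy atom versus 1.9 Å
beyond the hydrogen — is resolved in favor of the former by default, with
`donor_beyond_h` switching to the latter; neither is asserted as canonical.

Van der Waals radii come from a fixed Bondi-style table shipped with the
package, and the H-bond donor/acceptor SMARTS sets are explicit, documented
defaults (donor: N/O/S bearing H; acceptor: neutral O, and neutral
non-amide N), overridable through a role-prefixed pattern file — so results
do not drift with toolkit versions or hidden pattern libraries.

## Preprocessing

Field blocks are standardized with ONE mean and ONE population variance per
field, pooled over that field's kept columns and all scaling rows. This
block scaling equalizes the fields' overall magnitudes without flattening the
spatial contrast inside a field (per-column standardization, available via
`per_column_scaling`, would weight every grid point equally and erase that
contrast). The per-column SD of the scaled data is stored: it is the weight
that converts PLS coefficients into contour maps and field contributions.

Scaling and filter statistics are computed over the combined rows whenever
test/prediction rows are supplied (keeping one consistent feature space), and
over training rows alone otherwise. Column centering and activity centering
always use training rows only, so no held-out activity information can leak
into the model. Low-range column filtering is off by default.

## PLS and statistics

The latent-variable decomposition is scikit-learn's NIPALS `PLSRegression`
(`scale=False` on the preprocessed matrix); this package owns the protocol
around it. LOOCV refits the PLS decomposition per fold but reuses the
preprocessing statistics computed once on the full training matrix — the
centering is part of data preparation, not of the cross-validated model; a
`strict_refit` mode re-centers per fold for comparison. Conventions:

- q²(k) = 1 − PRESS(k)/Σ(y−ȳ)², S_PRESS(k) = √(PRESS/(n−k−1));
- component count k* = argmax q², ties broken toward smaller k (parsimony);
- r²_train = 1 − SSE/SSY, S = √(SSE/(n−k−1));
- r²_pred = 1 − Σ(y_test−ŷ)²/Σ(y_test−ȳ_train)² (training-mean denominator,
  the predictive-r² convention), S_test with the (n_test−k−1) denominator
  when positive, else RMSE;
- field contribution(f) = Σ_{j∈f}|b_j·s_j| / Σ_j|b_j·s_j|, which sums to 1
  and is invariant to rescaling a field block with a compensating coefficient
  change.

Test residuals are not re-centered. LOOCV equivalence with an independent
per-fold refit is asserted to 1e-10 on small systems.

## Contour maps

Kept-column coefficients times stored column SDs are scattered back to their
grid points (filtered columns hold zero). High/low levels are quantiles of
the NONZERO map values (the empty-space zeros would otherwise collapse the
thresholds), by default the 95th/5th percentile — 5 % per tail; a total-5 %
reading is available by passing half the fraction. Marching cubes
(scikit-image) extracts the isosurfaces; vertices are mapped to Å via
origin + index·spacing. A closed-form check is built in: thresholding a unit
Gaussian bump at half maximum must recover a sphere of radius √(ln 2/α)
within one grid spacing. Meshes export as OBJ and legacy-ASCII VTK polydata;
coefficient volumes export as Gaussian cube files.

## Alignment

For SMILES input, molecules are aligned on their maximum common substructure:
the first molecule (or a user-named one) is embedded from the fixed seed and
UFF-minimized (200-iteration rounds until the energy change is below 1e-6 or
10 rounds, then flagged); every other molecule is embedded with its MCS atoms
restrained to the template's MCS coordinates, minimized, rigidly refit onto
the core, and its residual core RMSD reported. The minimizer and convergence
criterion are package defaults, not claims about any reference
implementation. MCS matching is strict (elements + bond orders, rings to
rings) by default.

## Synthetic data generator

`generate_fixture` emulates the shape of a congeneric QSAR series: a
cyclohexane scaffold with a single substitution site drawn from 35 fragments
crossed over size and polarity, embedded and aligned on the shared ring from
one seed, with activity 6.0 + 1.2·t + N(0, noise_sd) where t is the
standardized score of the molecules on the leading principal component of the
chosen field's grid columns — an exactly linear function of one field that
follows its dominant spatial variation and is therefore recoverable by
cross-validated PLS. The truth record stores the planted field and the
top-loading grid points for recovery tests.

What the fixture does NOT emulate: multi-site substitution patterns,
conformational flexibility of real ligand series, activity cliffs,
experimental error structure beyond i.i.d. Gaussian noise, and the
scaffold diversity of real benchmark sets. Passing the recovery tests
therefore demonstrates the correctness of the machinery (fields →
preprocessing → PLS → contributions), not predictive performance on real
chemistry.

A note on the noiseless limit: even with noise_sd = 0, the LOO q² of the
fixture plateaus around 0.98 rather than reaching 1. With far more columns
than molecules the held-out row's exact linear relation is underdetermined
from the remaining rows, leaving a small irreducible extrapolation error;
the tests assert the computed level (≥ 0.95), not an idealized one.

## Problem sizes used in the test suite

The bundled tests run the full pipeline on 8–25 molecule fixtures with
~20×20×20 lattices (≈ 40 000 columns over five fields), 20 seeded recovery
replicates, and a 200-replicate pure-noise null for the q² sign check. These
sizes exercise every code path with comfortable statistical margins.

## Reproducing published benchmark statistics

The classic corticosteroid benchmark (21 training / 10 test steroids, pKi
for corticosteroid-binding globulin) is the standard validation set for this
method family. The activity table ships with the package
(`comsia.datasets.load_steroid_activity_table`); the pre-aligned 3D
structures are distributed by third parties and are not redistributed here.
To reproduce published PLS statistics: obtain the pre-aligned SDF files, add
the activity tag per record (or merge from the bundled table), and run
`comsia run --train ... --test ... --activity-tag pKi --fields SEH --spacing 1
--padding 4 --alpha 0.3`. Published q² values for this benchmark vary by
roughly ±0.1 across alignment and implementation variants; agreement should
be judged at that tolerance, and this comparison is an optional integration
exercise, not part of the automated test suite.

## Known limitations

- Gasteiger charges and UFF minimization are fast, classical approximations;
  no charge-model or force-field alternatives are wired in.
- One conformer per molecule; no conformational averaging of fields.
- The acceptor lone-pair count per hybridization follows idealized VSEPR
  geometry; true H-bond geometry is softer than that.
- SDF input is limited to MDL V2000 with 3D coordinates; no MOL2/V3000,
  no tautomer or protonation-state enumeration.
- SAMPLS-style covariance-matrix PLS, bootstrapping, progressive scrambling
  and region focusing are out of scope.
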