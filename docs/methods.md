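# Methods

This note records the models, conventions and numerical choices behind
`samconf`, and what the synthetic data do and do not establish about real
measurements.

## Distance restraints from ROESY intensities

The conversion assumes the isolated-spin-pair approximation: cross-peak
intensity proportional to r⁻⁶ at a single mixing time, with spin diffusion
and differential local dynamics neglected. Calibration is internal, against
the ribose H1′–H2′ pair (defaults r_ref = 2.90 Å, Δr_ref = 0.2 Å). The
reference intensity has no default: if the reference peak is absent from a
user's table the conversion is underdetermined and `Calibration` must be
given `i_ref` explicitly.

Uncertainty is first-order propagation over independent errors in r_ref,
I_ref and I:

Δr² = ((I_ref/I)^{1/6} Δr_ref)² + ((1/6) I_ref^{−5/6} I^{−1/6} r_ref ΔI_ref)²
    + ((1/6) I_ref^{1/6} r_ref I^{−7/6} ΔI)²

The implementation is checked against a central-finite-difference oracle at
1e−6 relative tolerance, and the analytic limit Δr/Δr_ref = r/r_ref when
both intensity errors vanish. Intensities carry no unit; only ratios enter.
Distances are stored at full precision; two-decimal rounding is
presentation-only, matching the precision of published restraint tables.
The packaged experimental table does not record the per-peak intensity
errors that produced its printed uncertainties, so only the
Δr_ref-dominated term of those uncertainties can be reproduced from first
principles; the package does not guess the missing ΔI values.

## Descriptors and classification

χ is the signed O4′-C1′-N9-C8 dihedral (right-handed IUPAC convention,
range (−180°, 180°]); θ is the planar SD-O4′-N9 angle. Windows are closed
intervals (syn [−150, −100], anti₁ [−30, 30], anti₂ [50, 100], bent θ
[80, 125], knotted-MT-like [80, 125]×[−20, 60]); the intermediate window
(−100, −50) is open so its endpoints stay with their named neighbours.
Published descriptions of these windows say "between" and "around" without
fixing boundary membership; inclusivity here is a documented convention and
every window is configurable through `ClassificationRules`. Values in no χ
window classify as "other". Two open points are resolved as follows: no
numeric window for "extended" exists, so everything outside the bent θ
window counts as extended; and whether near-±180° values should count as
syn is unstated, so by default they do not (they fall in "other").

Superposition is least-squares (Kabsch via SVD with a determinant
correction against improper rotations). `heavy_atom_rmsd` superposes on the
same 27-atom subset it reports over: SAM's full heavy-atom inventory
(15 C, 6 N, 5 O, 1 S), shipped as `SAM_HEAVY_ATOMS`. The pairwise matrix
uses a batched formulation (RMSD from singular values of per-pair
cross-covariances) verified in tests against the per-pair path; agreement
is limited to ~1e−7 Å by square-root cancellation near zero, which is far
below any physically meaningful difference at a 1.25 Å clustering cutoff.

Interproton distances treat two labels as multi-proton pseudo-atoms: the
S-methyl (three equivalent protons) and Hβ (the two CB methylene protons,
which share one chemical shift). Their effective distance is the
r⁻⁶-average over member pairs, d_eff = (mean_k d_k⁻⁶)^{−1/6}, the quantity
an NOE intensity actually reports; a geometric-centroid alternative is
available via `mode="centroid"`. The Hγ/Hγ′ assignment to the two CG
protons is an arbitrary but fixed convention — the experiment does not
resolve which diastereotopic proton is which, and the choice only affects
synthetic data, consistently.

## Clustering

GROMOS neighbour-count clustering: repeatedly take the conformer with the
most neighbours within the cutoff as a medoid, remove it and its
neighbours. Ties in neighbour count break to the lowest ensemble index, so
results are deterministic. Medoids are actual ensemble members, not
averaged structures. Defaults: cutoff 1.25 Å, subset the 27 heavy atoms;
both configurable. The specific variant of the clustering tool that
produced published cluster counts is not recorded anywhere authoritative;
the neighbour-count scheme is the documented default assumption.

## Population fit

For populations v over a cluster subset, the predicted restraint distance
is the population-weighted r⁻⁶ mean d_cl = (Σ vᵢxᵢ⁻⁶ / Σ vᵢ)^{−1/6}. A
commonly typeset variant of this expression (weight-inverse denominator,
no −1/6 root) is dimensionally inconsistent and cannot return Ångströms;
`r6_average(..., printed_form=True)` evaluates that literal form for
comparison but is never used by the fit.

The search enumerates every cluster subset of size 1..max_k crossed with
every strictly positive composition of 100% on the grid (default step 10%,
configurable down to 1%). Zero-weight members are excluded because they
duplicate smaller subsets. The candidate count is
Σ_k C(n,k)·C(100/step−1, k−1); for 90 clusters, K = 4, step 10% that is
~2.1×10⁸ candidates — the closed-form counter `count_candidates` lets users
estimate cost before running, and `fit(refine_step_pct=...)` adds an
optional coarse-to-fine pass (finer composition grid restricted to the
winning subset); exhaustive search is the default and the reference
behaviour. Ties break to the smallest subset size, then lexicographically
smallest subset, then lexicographically smallest composition.

Weighted RMSD uses wᵢ = eᵢ⁻², so restraints with zero uncertainty are
rejected rather than silently given infinite weight.

## Synthetic data

The generator emulates a solution ensemble of SAM as a mixture over
discrete conformational states, not as a physical simulation. The template
conformer is built once from an atom-mapped molecular graph by
distance-geometry embedding (fixed seed) plus MMFF relaxation, giving ideal
bond lengths and angles; conformers are derived from it by driving the
glycosidic torsion and four methionine-chain torsions, moving all atoms
distal to each rotated bond rigidly. A conformer is rejected (and redrawn)
if any pair of atoms ≥ 3 bonds apart comes closer than 0.8× the sum of
covalent radii.

The default water mixture has four states whose weights follow the
population structure resolved for free SAM in solution — 80% syn / 20%
anti₁ about the glycosidic angle and 70% extended / 20% bent-away /
10% bent-close for the methionine chain, the prevailing state being
syn-extended at 50%. The chain-torsion targets per state were chosen once
by scanning the template's clash-free torsion space so that each state
lands in its intended θ class and all four are mutually > 1.6 Å heavy-atom
RMSD (geometrically distinct at the 1.25 Å cutoff): extended
γ(O4′-C4′-C5′-SD) = 100° (θ ≈ 149°), bent-away γ = −120° (θ ≈ 108°),
bent-close γ = −55° with C4′-C5′-SD-CG = 90° and C5′-SD-CG-CB = −60°
(θ ≈ 90°). χ is drawn per conformer from a wrapped normal (default spread
0°, i.e. idealized states; configurable).

ROESY simulation inverts the calibration relation: I = I_ref (r_ref/d)⁶
where d is the r⁻⁶ average of the per-state mean-geometry distances at the
true mixture weights. Noise is multiplicative lognormal on intensities
(exp(σz), z ~ N(0,1)) because NOE intensities are positive and their errors
scale with signal; the per-peak intensity error is set to the lognormal
standard deviation I·sqrt(exp(σ²)−1). The accompanying noise-free restraint
table keeps the calibration-propagated uncertainty (Δr = (d/r_ref)·Δr_ref)
rather than zero, so it is directly usable as a weighted-fit target.

What passing the synthetic closure tests shows: the conversion, clustering
and fit invert the generator exactly when the truth lies on the search grid
and states are geometrically distinct. What it does not show: robustness to
continuous conformational exchange (real ensembles are not four rigid
states), spin diffusion, anisotropic tumbling, or force-field realism —
none of which the generator models.

Synthetic protein–ligand complexes are deliberately minimal: glycine
backbone fragments placed within 5 Å of the adenine moiety on two sides
("compact", mimicking an enclosed adenine pocket) or parked near the
methionine chain leaving adenine exposed ("open"). They are labelled
synthetic in their headers and exist to exercise the contact survey, not to
resemble real binding sites.

## Structure survey

Ligand extraction reads PDB/mmCIF through gemmi, one conformer per SAM/SAH
instance per model (first model by default), altlocs resolved to highest
occupancy with ties to the earliest. Contacts use heavy atoms only by
default — crystal structures usually lack hydrogens, and whether published
5 Å binding-site definitions included hydrogens is generally unstated;
`include_hydrogens=True` switches this. A residue contact records the
minimum distance, the ligand moiety achieving it (adenine / ribose /
methionine partition, with linkage atoms assigned to their ring side and
C5′ kept with the ribose), and whether the closest protein atom is backbone
(N, CA, C, O). Waters and non-amino-acid heterogens are excluded. Residue
numbering is taken verbatim from the file.

Group labels (e.g. knotted vs unknotted) are user-supplied metadata —
detecting backbone topology is out of scope. A label file for eight
well-studied knotted methyltransferase entries ships as an example.

## Problem sizes

Default test and acceptance runs use ensembles of 200–2000 conformers and
4-cluster fits at a 10% grid; the noise-robustness check averages 100
simulation seeds per noise level over σ ∈ {0, 0.02, 0.05, 0.1}. These sizes
exercise every code path, including the batched pairwise-RMSD machinery, at
a few seconds to ~10 s per stage.

## Known limitations

* The fit assumes fast exchange (a single population-averaged distance per
  restraint) and rigid cluster medoids; no reweighting of intra-cluster
  spread.
* The exhaustive grid scales combinatorially; very large cluster sets at
  fine grids require the user to coarsen or pre-filter.
* Protons missing from input structures can be rebuilt with
  `build_protons`, which copies template proton positions through a rigid
  superposition of the local heavy-atom neighbourhood; this assumes ideal
  covalent geometry and is flagged in the conformer's provenance. Rotameric
  hydroxyl protons rebuilt this way carry the template's rotamer, not the
  crystal's.
* The epimeric forms of SAM are not distinguished; the restraint table
  refers to the dominant epimer.
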