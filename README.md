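# samconf

Conformational analysis of S-adenosylmethionine (SAM), the near-universal
methyl-donor cofactor. SAM is flexible: its adenine can sit *syn* or *anti*
about the glycosidic bond, and its methionine chain can be *extended* or
*bent* back towards the nucleoside. Different protein families — most
strikingly the trefoil-knotted SPOUT methyltransferases versus Rossmann-fold
enzymes — select very different regions of this conformational space.
`samconf` is a toolkit for quantifying that space from two kinds of data:
ROESY NMR cross-peaks of free SAM in solution, and conformer ensembles
(MD snapshots or ligand instances pulled from protein structures).

It is aimed at structural bioinformaticians and NMR spectroscopists who want
a tested, scriptable version of the standard workflow: calibrated
intensity-to-distance conversion, conformer clustering, and population
deconvolution of an exchanging ensemble against distance restraints.

## The model

**Distances from intensities.** In the isolated-spin-pair approximation a
ROESY cross-peak intensity scales as r⁻⁶, so with the ribose H1′–H2′ pair as
internal reference (r_ref = 2.90 Å, Δr_ref = 0.2 Å),

    r = (I_ref / I)^(1/6) · r_ref

with first-order error propagation over the independent uncertainties
Δr_ref, ΔI_ref and ΔI. The package ships the 39-restraint experimental
table for free SAM at 25 °C.

**Descriptors.** Each conformer is summarised by the glycosidic dihedral
χ = ∠(O4′-C1′-N9-C8) and the bend angle θ = ∠(SD-O4′-N9). Classification
windows: syn χ ∈ [−150°, −100°], anti₁ χ ∈ [−30°, 30°], anti₂ χ ∈ [50°, 100°],
intermediate χ ∈ (−100°, −50°); bent θ ∈ [80°, 125°] (else extended); and the
2-D "knotted-MT-like" window θ ∈ [80°, 125°] × χ ∈ [−20°, 60°].

**Clustering and population fit.** Ensembles are clustered by heavy-atom
RMSD (GROMOS neighbour-count algorithm, 1.25 Å cutoff on SAM's 27 heavy
atoms). A small mixture of cluster medoids is then fitted to the NMR
restraints: for populations v over a cluster subset the predicted distance
per restraint is the r⁻⁶ ensemble average

    d_cl = ( Σᵢ vᵢ xᵢ⁻⁶ / Σᵢ vᵢ )^(−1/6)

and agreement is scored by the error-weighted RMSD with weights wᵢ = eᵢ⁻²:

    wRMSD = sqrt( Σᵢ wᵢ (d_cl,i − d_NMR,i)² / Σᵢ wᵢ ).

The fit exhaustively enumerates every subset of up to K clusters and every
strictly positive population composition on a percentage grid, and returns
the global minimum (`PopulationFitModel.fit()` → `PopulationFitResults`).

A synthetic-data module generates everything needed to exercise the
pipeline offline: an idealized SAM template, torsion-sampled mixtures with
known populations, ROESY intensities with lognormal noise, and miniature
protein–ligand complexes for the binding-site contact survey.

## Worked example

Generate a 500-conformer ensemble from the default four-state water mixture
(50% syn-extended, 20% anti₁-extended, 20% syn-bent-away, 10%
syn-bent-close), simulate noise-free ROESY peaks from it, convert them back
to distances, cluster and fit:

```python
import samconf as sc

spec = sc.SyntheticSpec.water_default(n_conformers=500, seed=17)
bundle = sc.generate_bundle(spec)
table = sc.peaks_to_restraints(bundle.cross_peaks, bundle.calibration)
model = sc.PopulationFitModel.from_ensemble(bundle.ensemble, table, cutoff=1.25)
res = model.fit(max_k=4, step_pct=10)
print(res.summary())
```

prints

```
Population fit of cluster medoids to NMR distance restraints
  clusters available: 4
  restraints fitted:  39
  weighted RMSD:      0.0000 A
  selected clusters (population %):
    synth-00001               50.0
    synth-00002               20.0
    synth-00000               20.0
    synth-00013               10.0
  runners-up (wRMSD, subset):
    0.1002  [synth-00001,synth-00000,synth-00013]
    0.1368  [synth-00002,synth-00000,synth-00013]
    0.3728  [synth-00001,synth-00002,synth-00000]
```

The four clusters found at the 1.25 Å cutoff are exactly the four generating
states, and the fitted populations (50/20/20/10%) recover the ground truth
with essentially zero weighted RMSD — the closure property the whole
pipeline is built around. The runner-up list shows how much fit quality is
lost when any one state is dropped (~0.1–0.37 Å).

The same steps are available from the shell:

```sh
samconf simulate --n 500 --seed 17 -o bundle/
samconf distances --peaks bundle/cross_peaks.tsv --iref 1.0 -o restraints.tsv
samconf cluster --in bundle/ensemble.pdb --all-models -o clusters.json
samconf fit --conformers bundle/ensemble.pdb --all-models \
            --restraints bundle/noise_free_distances.tsv -o fit.json
samconf descriptors --in bundle/ensemble.pdb --all-models -o descriptors.tsv
samconf survey --structures complexes/ --labels groups.tsv -o survey/
```

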