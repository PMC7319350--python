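"""Synthetic SAM data: template structure, conformer ensembles, ROESY peaks.

Everything the pipeline consumes can be generated here without downloads:

* an idealized SAM conformer with canonical atom names (27 heavy atoms plus
  all protons), built once from the molecular graph with a distance-geometry
  embedding followed by a force-field relaxation;
* torsion-sampled conformer ensembles drawn from a mixture of conformational
  states (glycosidic syn/anti x methionine-chain extended/bent) with known
  weights — a stand-in for a solution MD trajectory with a ground truth
  attached;
* noisy ROESY cross-peak tables generated from a ground-truth mixture by
  inverting the intensity-distance relation I = I_ref (r_ref/d)^6, with
  multiplicative lognormal intensity noise (NOE intensities are positive
  and their errors scale with the signal);
* small synthetic protein-ligand complexes with a compact or open binding
  site, for exercising the contact survey.

All generation is deterministic given the spec and seed.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, SamconfError
from .geometry import (
    Conformer,
    ConformerEnsemble,
    AtomRecord,
    SAM_HEAVY_ATOMS,
)
from .restraints import (
    Calibration,
    CrossPeak,
    DistanceRestraint,
    RestraintTable,
    load_reference_distances,
)

__all__ = [
    "MixtureComponent",
    "SyntheticSpec",
    "GroundTruthBundle",
    "build_template",
    "template_bonds",
    "set_torsions",
    "water_mixture_components",
    "sample_ensemble",
    "simulate_roesy",
    "generate_bundle",
    "build_synthetic_complex",
    "write_bundle",
    "CHI_TORSION",
    "GAMMA_TORSION",
]

# Atom-mapped SMILES of SAM; map numbers carry the canonical atom names so
# the graph-to-name assignment is exact, not inferred.
_SAM_SMILES = (
    "[CH3:1][S+:2]([CH2:3][CH2:4][C@@H:5]([C:7](=[O:8])[O-:9])[NH2:6])"
    "[CH2:10][C@@H:11]1[C@H:26]([C@H:24]([C@@H:13]([O:12]1)"
    "[n:14]2[cH:15][n:16][c:17]3[c:18]([n:20][cH:21][n:22][c:23]32)[NH2:19])"
    "[OH:25])[OH:27]"
)
_MAP_NAMES = {
    1: "CE", 2: "SD", 3: "CG", 4: "CB", 5: "CA", 6: "N", 7: "C", 8: "O",
    9: "OXT", 10: "C5'", 11: "C4'", 12: "O4'", 13: "C1'", 14: "N9", 15: "C8",
    16: "N7", 17: "C5", 18: "C6", 19: "N6", 20: "N1", 21: "C2", 22: "N3",
    23: "C4", 24: "C2'", 25: "O2'", 26: "C3'", 27: "O3'",
}

# Hydrogen names per parent heavy atom, assigned in RDKit neighbour order.
_H_NAMES = {
    "CE": ("HE1", "HE2", "HE3"),
    "CG": ("HG2", "HG3"),
    "CB": ("HB2", "HB3"),
    "CA": ("HA",),
    "N": ("HN1", "HN2"),
    "C5'": ("H5'", "H5''"),
    "C4'": ("H4'",),
    "C3'": ("H3'",),
    "C2'": ("H2'",),
    "C1'": ("H1'",),
    "O2'": ("HO2'",),
    "O3'": ("HO3'",),
    "C8": ("H8",),
    "C2": ("H2",),
    "N6": ("H61", "H62"),
}

#: Atom-name quadruple of the glycosidic torsion (rotating the base).
CHI_TORSION: tuple[str, str, str, str] = ("O4'", "C1'", "N9", "C8")
#: Exocyclic torsion that swings the sulfur: the main bent/extended control.
GAMMA_TORSION: tuple[str, str, str, str] = ("O4'", "C4'", "C5'", "SD")

_COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
}
_CLASH_FACTOR = 0.8
_MAX_RESAMPLE = 20


@functools.lru_cache(maxsize=1)
def _template_mol():
    """Embedded, force-field-relaxed RDKit molecule with named atoms."""
    from rdkit import Chem, RDLogger
    from rdkit.Chem import AllChem

    RDLogger.DisableLog("rdApp.*")  # sulfonium atom-typing chatter
    try:
        mol = Chem.MolFromSmiles(_SAM_SMILES)
        assert mol is not None
        mol = Chem.AddHs(mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = 20
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise SamconfError("template embedding failed")
        try:
            AllChem.MMFFOptimizeMolecule(mol)
        except Exception:  # pragma: no cover - force-field availability fallback
            AllChem.UFFOptimizeMolecule(mol)
    finally:
        RDLogger.EnableLog("rdApp.warning")
        RDLogger.EnableLog("rdApp.error")

    names: dict[int, str] = {}
    for atom in mol.GetAtoms():
        m = atom.GetAtomMapNum()
        if m:
            names[atom.GetIdx()] = _MAP_NAMES[m]
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 1:
            continue
        parent = atom.GetNeighbors()[0]
        pname = names[parent.GetIdx()]
        used = sum(
            1
            for other in parent.GetNeighbors()
            if other.GetAtomicNum() == 1 and other.GetIdx() < atom.GetIdx()
        )
        names[atom.GetIdx()] = _H_NAMES[pname][used]
    return mol, names


def _mol_to_conformer(mol, names: Mapping[int, str], conf_id: str, source: str) -> Conformer:
    pos = mol.GetConformer().GetPositions()
    atoms = [
        AtomRecord(
            name=names[a.GetIdx()],
            element=a.GetSymbol(),
            xyz=tuple(pos[a.GetIdx()]),
        )
        for a in mol.GetAtoms()
    ]
    return Conformer(id=conf_id, atoms=atoms, source=source)


def build_template() -> Conformer:
    """The idealized SAM conformer (27 heavy atoms + all protons)."""
    mol, names = _template_mol()
    return _mol_to_conformer(mol, names, "SAM-template", "samconf idealized template")


def template_bonds() -> list[tuple[str, str]]:
    """Covalent bonds of the template as canonical atom-name pairs."""
    mol, names = _template_mol()
    return [
        (names[b.GetBeginAtomIdx()], names[b.GetEndAtomIdx()]) for b in mol.GetBonds()
    ]


@functools.lru_cache(maxsize=1)
def _nonbonded_pairs() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index pairs separated by >= 3 bonds, with clash thresholds."""
    from rdkit import Chem

    mol, names = _template_mol()
    n = mol.GetNumAtoms()
    dmat = Chem.GetDistanceMatrix(mol)
    iu, ju = np.triu_indices(n, k=1)
    mask = dmat[iu, ju] >= 3
    iu, ju = iu[mask], ju[mask]
    radii = np.array(
        [_COVALENT_RADII[a.GetSymbol()] for a in mol.GetAtoms()], dtype=float
    )
    thresh = _CLASH_FACTOR * (radii[iu] + radii[ju])
    return iu, ju, thresh


def _has_clash(positions: np.ndarray) -> bool:
    iu, ju, thresh = _nonbonded_pairs()
    d = np.linalg.norm(positions[iu] - positions[ju], axis=1)
    return bool((d < thresh).any())


def _name_to_idx() -> dict[str, int]:
    _, names = _template_mol()
    return {v: k for k, v in names.items()}


def set_torsions(
    torsions: Mapping[tuple[str, str, str, str], float],
    conf_id: str = "SAM",
    source: str = "torsion-driven template",
    check_clash: bool = True,
) -> Conformer:
    """Template conformer with the given torsions (degrees) applied.

    Atoms distal to each rotated bond move rigidly; the molecular graph
    supplies connectivity.  A steric clash (non-bonded pair closer than 0.8x
    the covalent-radius sum) raises :class:`~samconf.errors.SamconfError`
    when ``check_clash`` is set.
    """
    from rdkit import Chem
    from rdkit.Chem import rdMolTransforms

    base, names = _template_mol()
    idx = _name_to_idx()
    mol = Chem.Mol(base)
    conf = mol.GetConformer()
    for quad, value in torsions.items():
        ids = [idx[n] for n in quad]
        rdMolTransforms.SetDihedralDeg(conf, *ids, float(value))
    if check_clash and _has_clash(conf.GetPositions()):
        raise SamconfError(f"conformer {conf_id}: steric clash after torsion driving")
    return _mol_to_conformer(mol, names, conf_id, source)


# ---------------------------------------------------------------------------
# mixture specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MixtureComponent:
    """One conformational state of the mixture.

    ``chi`` is drawn from a wrapped normal around ``chi_mean`` (degrees);
    the methionine-chain torsions are set to the fixed targets in
    ``chain_torsions``.
    """

    name: str
    weight: float
    chi_mean: float
    chi_std: float = 0.0
    chain_torsions: tuple[tuple[tuple[str, str, str, str], float], ...] = ()

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise InvalidInputError(f"component {self.name}: weight must be >= 0")
        if self.chi_std < 0:
            raise InvalidInputError(f"component {self.name}: chi_std must be >= 0")

    def torsion_targets(self, chi: float) -> dict[tuple[str, str, str, str], float]:
        t = {CHI_TORSION: chi}
        t.update(dict(self.chain_torsions))
        return t


def water_mixture_components(chi_std: float = 0.0) -> list[MixtureComponent]:
    """The default four-state mixture emulating SAM free in water.

    Weights mirror the population structure resolved for the solution
    ensemble: 80% syn / 20% anti1 about the glycosidic angle, with the
    methionine chain extended in 70% and bent in 30% (20% bent away from the
    ribose hydroxyls, 10% bent towards them).  The chain-torsion targets are
    idealized values chosen so the four states are geometrically distinct
    (pairwise heavy-atom RMSD above the 1.25 Å clustering cutoff) and land
    in the intended bent/extended theta windows.
    """
    extended = ((GAMMA_TORSION, 100.0), (("C4'", "C5'", "SD", "CG"), 180.0),
                (("C5'", "SD", "CG", "CB"), 180.0), (("SD", "CG", "CB", "CA"), 180.0))
    bent_away = ((GAMMA_TORSION, -120.0), (("C4'", "C5'", "SD", "CG"), 180.0),
                 (("C5'", "SD", "CG", "CB"), 180.0), (("SD", "CG", "CB", "CA"), -60.0))
    bent_close = ((GAMMA_TORSION, -55.0), (("C4'", "C5'", "SD", "CG"), 90.0),
                  (("C5'", "SD", "CG", "CB"), -60.0), (("SD", "CG", "CB", "CA"), 180.0))
    return [
        MixtureComponent("syn-extended", 0.50, -120.0, chi_std, extended),
        MixtureComponent("anti1-extended", 0.20, 0.0, chi_std, extended),
        MixtureComponent("syn-bent-away", 0.20, -120.0, chi_std, bent_away),
        MixtureComponent("syn-bent-close", 0.10, -120.0, chi_std, bent_close),
    ]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a ground-truth ensemble plus synthetic ROESY data."""

    components: tuple[MixtureComponent, ...]
    n_conformers: int = 2000
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise InvalidInputError("component weights must sum to 1")
        if self.n_conformers < 1:
            raise InvalidInputError("n_conformers must be >= 1")
        if self.noise_sigma < 0:
            raise InvalidInputError("noise_sigma must be >= 0")

    @classmethod
    def water_default(
        cls,
        n_conformers: int = 2000,
        chi_std: float = 0.0,
        noise_sigma: float = 0.0,
        seed: int = 0,
    ) -> "SyntheticSpec":
        return cls(
            components=tuple(water_mixture_components(chi_std)),
            n_conformers=n_conformers,
            noise_sigma=noise_sigma,
            seed=seed,
        )


@dataclass
class GroundTruthBundle:
    """A synthetic ensemble with full knowledge of how it was generated."""

    spec: SyntheticSpec
    ensemble: ConformerEnsemble
    component_labels: list[str]
    true_populations: dict[str, float]
    realized_fractions: dict[str, float]
    component_templates: dict[str, Conformer]
    noise_free_table: RestraintTable | None = None
    cross_peaks: list[CrossPeak] | None = None
    calibration: Calibration | None = None


def _wrap_angle(a: float) -> float:
    a = (a + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def sample_ensemble(spec: SyntheticSpec) -> GroundTruthBundle:
    """Draw a conformer ensemble from the mixture (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    comp_names = [c.name for c in spec.components]
    weights = np.array([c.weight for c in spec.components])
    choices = rng.choice(len(spec.components), size=spec.n_conformers, p=weights)

    conformers: list[Conformer] = []
    labels: list[str] = []
    for i, ci in enumerate(choices):
        comp = spec.components[ci]
        conf = None
        for _attempt in range(_MAX_RESAMPLE):
            chi = _wrap_angle(rng.normal(comp.chi_mean, comp.chi_std)) if comp.chi_std > 0 else comp.chi_mean
            try:
                conf = set_torsions(
                    comp.torsion_targets(chi),
                    conf_id=f"synth-{i:05d}",
                    source=f"synthetic component {comp.name}",
                )
                break
            except SamconfError:
                if comp.chi_std == 0:
                    raise
                continue
        if conf is None:
            raise SamconfError(
                f"component {comp.name}: could not draw a clash-free conformer"
            )
        conformers.append(conf)
        labels.append(comp.name)

    counts = {name: labels.count(name) for name in comp_names}
    templates = {
        c.name: set_torsions(
            c.torsion_targets(c.chi_mean),
            conf_id=f"component-{c.name}",
            source=f"synthetic component {c.name} (mean geometry)",
        )
        for c in spec.components
    }
    return GroundTruthBundle(
        spec=spec,
        ensemble=ConformerEnsemble(conformers),
        component_labels=labels,
        true_populations={c.name: c.weight for c in spec.components},
        realized_fractions={k: v / spec.n_conformers for k, v in counts.items()},
        component_templates=templates,
    )


def simulate_roesy(
    bundle: GroundTruthBundle,
    calibration: Calibration | None = None,
    noise_sigma: float | None = None,
    seed: int | None = None,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> GroundTruthBundle:
    """Return a copy of the bundle with synthetic ROESY cross-peaks attached.

    For every proton pair the noise-free effective distance d is the r^-6
    average of the per-component mean-geometry distances at the true
    populations; the intensity is I = I_ref (r_ref/d)^6 times multiplicative
    lognormal noise exp(sigma * z).  The per-peak intensity error is set to
    the lognormal standard deviation I * sqrt(exp(sigma^2) - 1).
    """
    from .geometry import interproton_distance
    from .population import r6_average

    cal = calibration or Calibration(i_ref=1.0, di_ref=0.0)
    sigma = bundle.spec.noise_sigma if noise_sigma is None else noise_sigma
    rng = np.random.default_rng(bundle.spec.seed + 1 if seed is None else seed)
    if pairs is None:
        pairs = load_reference_distances().pairs

    comp_names = list(bundle.true_populations)
    pops = np.array([bundle.true_populations[n] for n in comp_names])
    x = np.array(
        [
            [interproton_distance(bundle.component_templates[n], p) for p in pairs]
            for n in comp_names
        ]
    )
    d_true = r6_average(x, pops)

    from .restraints import propagate_distance_error

    peaks: list[CrossPeak] = []
    restraints: list[DistanceRestraint] = []
    for pair, d in zip(pairs, d_true):
        intensity = cal.i_ref * (cal.r_ref / d) ** 6
        if sigma > 0:
            intensity *= math.exp(sigma * rng.standard_normal())
        di = intensity * math.sqrt(math.expm1(sigma**2)) if sigma > 0 else 0.0
        peak = CrossPeak(pair=pair, intensity=intensity, intensity_error=di)
        peaks.append(peak)
        # the noise-free distance keeps the calibration-propagated uncertainty
        # so it can serve directly as a restraint table (weights need e_i > 0)
        noiseless = CrossPeak(pair=pair, intensity=cal.i_ref * (cal.r_ref / d) ** 6)
        restraints.append(
            DistanceRestraint(
                pair=pair, r=float(d), dr=propagate_distance_error(noiseless, cal)
            )
        )

    return replace(
        bundle,
        noise_free_table=RestraintTable(restraints),
        cross_peaks=peaks,
        calibration=cal,
    )


def generate_bundle(spec: SyntheticSpec, calibration: Calibration | None = None) -> GroundTruthBundle:
    """sample_ensemble + simulate_roesy in one step."""
    return simulate_roesy(sample_ensemble(spec), calibration)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _conformer_pdb_lines(
    conf: Conformer, chain: str, resname: str, resnum: int, start_serial: int = 1,
    het: bool = True,
) -> list[str]:
    lines = []
    record = "HETATM" if het else "ATOM  "
    for serial, atom in enumerate(conf.atoms, start=start_serial):
        x, y, z = atom.xyz
        name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
        lines.append(
            f"{record}{serial:>5d} {name:<4.4s} {resname:<3s} {chain}{resnum:>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {atom.element:>2s}"
        )
    return lines


def write_ensemble_pdb(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-MODEL PDB of SAM HETATM records."""
    lines: list[str] = []
    for i, conf in enumerate(ensemble, start=1):
        lines.append(f"MODEL     {i:>4d}")
        lines.extend(_conformer_pdb_lines(conf, "A", "SAM", 1))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_bundle(bundle: GroundTruthBundle, directory: str | Path) -> None:
    """Serialize a bundle as a directory of text artifacts.

    Contents: ``ensemble.pdb`` (multi-MODEL), ``labels.tsv`` (component per
    conformer), ``noise_free_distances.tsv``, ``cross_peaks.tsv`` and a JSON
    manifest with the spec and populations.
    """
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_ensemble_pdb(bundle.ensemble, directory / "ensemble.pdb")
    pd.DataFrame(
        {"conformer_id": bundle.ensemble.ids, "component": bundle.component_labels}
    ).to_csv(directory / "labels.tsv", sep="\t", index=False)
    if bundle.noise_free_table is not None:
        from .restraints import write_restraint_table

        write_restraint_table(
            bundle.noise_free_table, directory / "noise_free_distances.tsv"
        )
    if bundle.cross_peaks is not None:
        pd.DataFrame(
            {
                "Atom1": [p.pair[0] for p in bundle.cross_peaks],
                "Atom2": [p.pair[1] for p in bundle.cross_peaks],
                "Intensity": [p.intensity for p in bundle.cross_peaks],
                "IntensityError": [p.intensity_error for p in bundle.cross_peaks],
            }
        ).to_csv(directory / "cross_peaks.tsv", sep="\t", index=False)
    manifest = {
        "seed": bundle.spec.seed,
        "n_conformers": bundle.spec.n_conformers,
        "noise_sigma": bundle.spec.noise_sigma,
        "true_populations": bundle.true_populations,
        "realized_fractions": bundle.realized_fractions,
        "components": [
            {
                "name": c.name,
                "weight": c.weight,
                "chi_mean": c.chi_mean,
                "chi_std": c.chi_std,
                "chain_torsions": [
                    {"atoms": list(q), "value_deg": v} for q, v in c.chain_torsions
                ],
            }
            for c in bundle.spec.components
        ],
    }
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=2), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# synthetic protein-ligand complexes
# ---------------------------------------------------------------------------

_ADENINE_ATOMS = ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4")

# rigid glycine backbone fragment (N, CA, C, O) in a local frame, Å
_GLY_FRAGMENT = np.array(
    [
        [0.000, 0.000, 0.000],   # N
        [1.458, 0.000, 0.000],   # CA
        [2.009, 1.420, 0.000],   # C
        [3.232, 1.536, 0.000],   # O
    ]
)


def _place_fragment(anchor: np.ndarray, direction: np.ndarray, distance: float) -> np.ndarray:
    """Place the glycine fragment with its CA at anchor + distance*direction."""
    direction = direction / np.linalg.norm(direction)
    # build an orthonormal frame with x along the direction
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(ref, direction)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    y = np.cross(direction, ref)
    y /= np.linalg.norm(y)
    z = np.cross(direction, y)
    rot = np.column_stack([direction, y, z])
    centre = anchor + distance * direction
    return (_GLY_FRAGMENT - _GLY_FRAGMENT[1]) @ rot.T + centre


def build_synthetic_complex(
    site_style: str = "compact",
    seed: int = 0,
    path: str | Path | None = None,
) -> str:
    """A minimal SAM-protein complex as PDB text (optionally written to path).

    ``compact`` places glycine backbone fragments within 5 Å of the adenine
    moiety on two opposite sides (a loop-like lid and a wall), mimicking the
    enclosed adenine pocket of a knotted methyltransferase; ``open`` parks
    the same fragments near the methionine chain and leaves the adenine
    solvent-exposed.  Both styles add one remote fragment so the structure
    has more than one residue of polymer context.
    """
    if site_style not in ("compact", "open"):
        raise InvalidInputError(f"unknown site style {site_style!r}")
    rng = np.random.default_rng(seed)
    sam = build_template()
    ade = sam.coords(_ADENINE_ATOMS)
    centroid = ade.mean(axis=0)
    # ring normal from SVD of the (nearly planar) adenine coordinates
    _, _, vt = np.linalg.svd(ade - centroid)
    normal = vt[2]
    met_anchor = np.array(sam.atom("CB").xyz)
    met_dir = met_anchor - centroid
    met_dir /= np.linalg.norm(met_dir)

    fragments: list[np.ndarray] = []
    if site_style == "compact":
        fragments.append(_place_fragment(centroid, normal, 4.0))
        fragments.append(_place_fragment(centroid, -normal, 4.0))
        fragments.append(_place_fragment(met_anchor, met_dir, 12.0))
    else:
        fragments.append(_place_fragment(met_anchor, met_dir, 4.5))
        side = np.cross(met_dir, normal)
        side /= np.linalg.norm(side)
        fragments.append(_place_fragment(met_anchor + 3.0 * side, met_dir, 5.0))
        fragments.append(_place_fragment(centroid, normal, 14.0))

    lines: list[str] = ["REMARK synthetic SAM complex (samconf)", ]
    serial = 1
    for resnum, frag in enumerate(fragments, start=1):
        for name, xyz in zip(("N", "CA", "C", "O"), frag):
            x, y, z = xyz
            elem = name[0]
            lines.append(
                f"ATOM  {serial:>5d}  {name:<3s} GLY A{resnum:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {elem:>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.extend(_conformer_pdb_lines(sam, "B", "SAM", 1, start_serial=serial))
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
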