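"""Survey of protein-bound SAM/SAH conformers and binding-site contacts.

Reads protein-ligand structures (PDB/mmCIF), pulls out each SAM or SAH
instance as a named-atom conformer, partitions the ligand into its three
moieties (adenine, ribose, methionine/homocysteine chain), lists protein
residues within a distance cutoff of the ligand (5 Å by default, heavy
atoms only — crystal structures usually lack hydrogens), and aggregates
descriptor distributions per user-supplied structure group (for example
knotted vs unknotted proteins; deciding knottedness is the user's problem,
labels are plain metadata here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import InvalidInputError, MissingAtomError
from .geometry import (
    ClassificationRules,
    Conformer,
    ConformerEnsemble,
    AtomRecord,
    DEFAULT_RULES,
    describe_ensemble,
)

__all__ = [
    "MOIETY_PARTITION",
    "moiety_of",
    "ContactRecord",
    "GroupProfile",
    "extract_ligands",
    "binding_site_contacts",
    "build_group_profiles",
    "compare_groups",
    "read_group_labels",
]

#: Moiety membership of every canonical SAM/SAH heavy atom.  The glycosidic
#: linkage atoms belong to their ring side: N9 to adenine, C1' to ribose;
#: C5' stays with the ribose, SD opens the methionine chain.
MOIETY_PARTITION: dict[str, str] = {
    **{a: "adenine" for a in ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4")},
    **{a: "ribose" for a in ("C1'", "C2'", "O2'", "C3'", "O3'", "C4'", "O4'", "C5'")},
    **{a: "methionine" for a in ("SD", "CE", "CG", "CB", "CA", "N", "C", "O", "OXT")},
}

_BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})
DEFAULT_HET_CODES = frozenset({"SAM", "SAH"})


def moiety_of(atom_name: str) -> str:
    """Moiety label (adenine / ribose / methionine) of a ligand heavy atom."""
    try:
        return MOIETY_PARTITION[atom_name]
    except KeyError:
        raise MissingAtomError(f"atom {atom_name!r} is not a canonical SAM/SAH heavy atom") from None


@dataclass(frozen=True)
class ContactRecord:
    """One protein residue within the cutoff of one ligand instance."""

    structure_id: str
    ligand_instance: str
    residue_name: str
    residue_number: int
    chain: str
    min_distance: float
    contacted_moiety: str
    via_backbone: bool


def _read_structure(path: str | Path) -> gemmi.Structure:
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def _residue_conformer(
    res: gemmi.Residue, conf_id: str, source: str
) -> Conformer:
    """Build a Conformer from a residue, resolving altlocs to the highest
    occupancy (ties to altloc 'A' / earliest)."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ:
            best[atom.name] = atom
    atoms = [
        AtomRecord(
            name=a.name,
            element=a.element.name,
            xyz=(a.pos.x, a.pos.y, a.pos.z),
        )
        for a in best.values()
    ]
    return Conformer(id=conf_id, atoms=atoms, source=source)


def extract_ligands(
    path: str | Path,
    het_codes: Iterable[str] = DEFAULT_HET_CODES,
    all_models: bool = False,
) -> ConformerEnsemble:
    """Extract every SAM/SAH ligand instance from a structure file.

    One conformer per ligand instance (chain + residue number) per selected
    model; by default only the first model is read.  Provenance (file,
    model, chain, residue number) goes into the conformer id and source.
    Returns an empty ensemble with a warning when no matching HET residue
    exists.
    """
    st = _read_structure(path)
    codes = {c.upper() for c in het_codes}
    stem = Path(path).stem
    conformers: list[Conformer] = []
    models = list(st) if all_models else [st[0]]
    for model in models:
        for chain in model:
            for res in chain:
                if res.name.upper() not in codes:
                    continue
                cid = f"{stem}|model{model.num}|{chain.name}|{res.seqid.num}"
                conformers.append(
                    _residue_conformer(res, cid, f"{path} model {model.num}")
                )
    if not conformers:
        warnings.warn(
            f"{path}: no HET residue matching {sorted(codes)} found", stacklevel=2
        )
    return ConformerEnsemble(conformers)


def binding_site_contacts(
    path: str | Path,
    ligand_instance: str | None = None,
    cutoff: float = 5.0,
    het_codes: Iterable[str] = DEFAULT_HET_CODES,
    include_hydrogens: bool = False,
) -> list[ContactRecord]:
    """Protein residues with any (heavy) atom within ``cutoff`` of the ligand.

    ``ligand_instance`` selects one instance by the id format produced by
    :func:`extract_ligands` ("stem|modelN|chain|resnum"); with None and a
    single instance present, that instance is used.  For each contacting
    residue the minimum distance, the ligand moiety achieving it, and
    whether the closest protein atom is a backbone atom (N, CA, C, O) are
    recorded.  Waters and other heteroatoms are excluded.
    """
    st = _read_structure(path)
    codes = {c.upper() for c in het_codes}
    stem = Path(path).stem
    model = st[0]

    ligands: dict[str, gemmi.Residue] = {}
    for chain in model:
        for res in chain:
            if res.name.upper() in codes:
                ligands[f"{stem}|model{model.num}|{chain.name}|{res.seqid.num}"] = res
    if not ligands:
        raise InvalidInputError(f"{path}: no ligand with codes {sorted(codes)}")
    if ligand_instance is None:
        if len(ligands) > 1:
            raise InvalidInputError(
                f"{path}: several ligand instances present, pick one of {sorted(ligands)}"
            )
        ligand_instance, ligand = next(iter(ligands.items()))
    else:
        try:
            ligand = ligands[ligand_instance]
        except KeyError:
            raise InvalidInputError(
                f"{path}: no ligand instance {ligand_instance!r}; have {sorted(ligands)}"
            ) from None

    lig_atoms = [
        a for a in ligand if include_hydrogens or a.element.name != "H"
    ]
    lig_xyz = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in lig_atoms])
    lig_moiety = [MOIETY_PARTITION.get(a.name, "methionine") for a in lig_atoms]

    records: list[ContactRecord] = []
    for chain in model:
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            atoms = [a for a in res if include_hydrogens or a.element.name != "H"]
            if not atoms:
                continue
            res_xyz = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms])
            d = np.linalg.norm(res_xyz[:, None, :] - lig_xyz[None, :, :], axis=-1)
            dmin = float(d.min())
            if dmin > cutoff:
                continue
            pi, li = np.unravel_index(int(d.argmin()), d.shape)
            records.append(
                ContactRecord(
                    structure_id=stem,
                    ligand_instance=ligand_instance,
                    residue_name=res.name,
                    residue_number=res.seqid.num,
                    chain=chain.name,
                    min_distance=dmin,
                    contacted_moiety=lig_moiety[li],
                    via_backbone=atoms[pi].name in _BACKBONE_ATOMS,
                )
            )
    return records


def contacts_to_dataframe(records: Sequence[ContactRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# group profiles
# ---------------------------------------------------------------------------

@dataclass
class GroupProfile:
    """Descriptor distributions of one structure group."""

    group: str
    descriptors: pd.DataFrame
    chi_bin_edges: np.ndarray
    theta_bin_edges: np.ndarray
    chi_hist: np.ndarray
    theta_hist: np.ndarray
    occupancy_2d: np.ndarray  # (theta bins, chi bins)
    class_fractions: dict[str, float]
    shape_fractions: dict[str, float]
    knotted_window_fraction: float

    @property
    def n_conformers(self) -> int:
        return len(self.descriptors)

    def plot(self, axes=None):
        """Histograms of chi and theta side by side."""
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(1, 2, figsize=(9, 3))
        axc, axt = axes
        axc.stairs(self.chi_hist, self.chi_bin_edges, fill=True, color="steelblue")
        axc.set_xlabel("glycosidic dihedral χ (°)")
        axt.stairs(self.theta_hist, self.theta_bin_edges, fill=True, color="seagreen")
        axt.set_xlabel("SD-O4'-N9 angle θ (°)")
        for ax in (axc, axt):
            ax.set_ylabel("conformers")
            ax.set_title(self.group)
        return axes


def read_group_labels(path: str | Path) -> dict[str, str]:
    """Read a structure_id -> group TSV (columns structure_id, group)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"structure_id", "group"}.issubset(df.columns):
        raise InvalidInputError(f"{path}: need columns structure_id, group")
    return dict(zip(df["structure_id"].astype(str), df["group"].astype(str)))


_GLYCO_CLASSES = ("syn", "anti1", "anti2", "intermediate", "other")
_SHAPE_CLASSES = ("bent", "extended")


def build_group_profiles(
    ensemble: ConformerEnsemble | Sequence[Conformer],
    labels: Mapping[str, str],
    rules: ClassificationRules = DEFAULT_RULES,
    bin_width: float = 10.0,
) -> dict[str, GroupProfile]:
    """Per-group descriptor histograms and class fractions.

    ``labels`` maps conformer id (or its structure_id prefix before the
    first '|') to a group name; every conformer must resolve to a label.
    """
    members = list(ensemble)
    desc = describe_ensemble(members, rules)
    groups: list[str] = []
    for cid in desc["conformer_id"]:
        key = cid if cid in labels else cid.split("|", 1)[0]
        if key not in labels:
            raise InvalidInputError(f"conformer {cid!r} has no group label")
        groups.append(labels[key])
    desc = desc.assign(group=groups)

    chi_edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
    theta_edges = np.arange(0.0, 180.0 + bin_width, bin_width)
    profiles: dict[str, GroupProfile] = {}
    for group, sub in desc.groupby("group", sort=True):
        chi_hist, _ = np.histogram(sub["chi_deg"], bins=chi_edges)
        theta_hist, _ = np.histogram(sub["theta_deg"], bins=theta_edges)
        occ, _, _ = np.histogram2d(
            sub["theta_deg"], sub["chi_deg"], bins=(theta_edges, chi_edges)
        )
        n = max(len(sub), 1)
        profiles[group] = GroupProfile(
            group=group,
            descriptors=sub.reset_index(drop=True),
            chi_bin_edges=chi_edges,
            theta_bin_edges=theta_edges,
            chi_hist=chi_hist,
            theta_hist=theta_hist,
            occupancy_2d=occ,
            class_fractions={
                c: float((sub["glyco_class"] == c).sum()) / n for c in _GLYCO_CLASSES
            },
            shape_fractions={
                c: float((sub["shape_class"] == c).sum()) / n for c in _SHAPE_CLASSES
            },
            knotted_window_fraction=float(sub["knotted_mt_like"].sum()) / n,
        )
    return profiles


def compare_groups(profiles: Mapping[str, GroupProfile]) -> pd.DataFrame:
    """Side-by-side summary table of group profiles.

    One row per group: conformer count, glycosidic and shape class
    fractions, descriptor medians with interquartile ranges, and the
    fraction inside the knotted-MT (theta, chi) window.  Profiles must share
    their binning.
    """
    items = list(profiles.values())
    if len(items) < 2:
        raise InvalidInputError("compare_groups needs at least two profiles")
    ref = items[0]
    for p in items[1:]:
        if (
            not np.array_equal(p.chi_bin_edges, ref.chi_bin_edges)
            or not np.array_equal(p.theta_bin_edges, ref.theta_bin_edges)
        ):
            raise InvalidInputError("group profiles have mismatched binning")
    rows = []
    for p in items:
        d = p.descriptors
        if len(d):
            chi_q = np.percentile(d["chi_deg"], [25, 50, 75])
            theta_q = np.percentile(d["theta_deg"], [25, 50, 75])
        else:
            chi_q = theta_q = (float("nan"),) * 3
        row = {
            "group": p.group,
            "n_conformers": p.n_conformers,
            **{f"frac_{c}": p.class_fractions.get(c, 0.0) for c in _GLYCO_CLASSES},
            **{f"frac_{c}": p.shape_fractions.get(c, 0.0) for c in _SHAPE_CLASSES},
            "chi_median": chi_q[1],
            "chi_iqr": chi_q[2] - chi_q[0],
            "theta_median": theta_q[1],
            "theta_iqr": theta_q[2] - theta_q[0],
            "knotted_window_fraction": p.knotted_window_fraction,
            "empty": p.n_conformers == 0,
        }
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")
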