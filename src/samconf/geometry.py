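"""Conformer representation and the two SAM shape descriptors.

A SAM conformation is summarised by two angles:

* chi — the glycosidic dihedral O4'-C1'-N9-C8 (signed, IUPAC right-handed
  convention, range (-180, 180]), separating *syn* from *anti* base
  orientations;
* theta — the planar SD-O4'-N9 bend angle (range [0, 180]), separating
  overall *bent* from *extended* shapes of the molecule.

Classification windows (degrees, closed intervals) follow the conformational
families observed for SAM:

* syn: chi in [-150, -100]
* anti1: chi in [-30, 30]
* anti2: chi in [50, 100]
* intermediate: chi in (-100, -50) — transitional between anti1 and syn
* bent: theta in [80, 125]; everything else counts as extended
* "knotted-MT-like": theta in [80, 125] and chi in [-20, 60], the 2-D window
  occupied by SAM bound to trefoil-knotted methyltransferases.

Values falling in no chi window are classified "other".  Boundary handling
(closed intervals) is a documented convention and configurable through
:class:`ClassificationRules`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DegenerateGeometryError,
    InvalidInputError,
    MissingAtomError,
)
from .labels import canonical_pair

__all__ = [
    "AtomRecord",
    "Conformer",
    "ConformerEnsemble",
    "DescriptorRecord",
    "ClassificationRules",
    "DEFAULT_RULES",
    "SAM_HEAVY_ATOMS",
    "SAH_HEAVY_ATOMS",
    "DESCRIPTOR_ATOMS",
    "SUPERPOSITION_ATOMS",
    "PROTON_GROUPS",
    "compute_dihedral",
    "compute_bend_angle",
    "build_protons",
    "classify_glycosidic",
    "classify_shape",
    "is_knotted_mt_like",
    "describe",
    "describe_ensemble",
    "superpose",
    "apply_transform",
    "heavy_atom_rmsd",
    "interproton_distance",
    "rmsf",
]

#: The canonical 27 heavy atoms of SAM (15 C, 6 N, 5 O, 1 S): the full
#: heavy-atom set of the molecule, used for RMSD clustering.
SAM_HEAVY_ATOMS: tuple[str, ...] = (
    # methionine moiety
    "N", "CA", "C", "O", "OXT", "CB", "CG", "SD", "CE",
    # ribose
    "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "O2'", "C1'",
    # adenine
    "N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4",
)

#: SAH lacks the S-methyl carbon CE but is otherwise named identically.
SAH_HEAVY_ATOMS: tuple[str, ...] = tuple(a for a in SAM_HEAVY_ATOMS if a != "CE")

#: Atoms needed to evaluate the two descriptors.
DESCRIPTOR_ATOMS: tuple[str, ...] = ("SD", "O4'", "C1'", "N9", "C8")

#: Ribose-anchored frame used for visual/structural superposition.
SUPERPOSITION_ATOMS: tuple[str, ...] = ("C5'", "C4'", "O4'", "C1'", "N9")

#: Canonical proton label -> structure atom names.  Multi-atom groups are
#: pseudo-atoms whose effective distance is the r^-6 average over members.
#: The Hgamma/Hgamma' assignment to the two CG methylene protons is an
#: arbitrary but fixed convention (the experiment does not resolve which
#: diastereotopic proton is which).
PROTON_GROUPS: dict[str, tuple[str, ...]] = {
    "H1'": ("H1'",),
    "H2'": ("H2'",),
    "H3'": ("H3'",),
    "H4'": ("H4'",),
    "H5'": ("H5'",),
    "H5''": ("H5''",),
    "H8": ("H8",),
    "H2": ("H2",),
    "Halpha": ("HA",),
    "Hbeta": ("HB2", "HB3"),
    "Hgamma": ("HG2",),
    "Hgamma'": ("HG3",),
    "MET-CH3": ("HE1", "HE2", "HE3"),
}


@dataclass(frozen=True)
class AtomRecord:
    """One named atom with Cartesian coordinates in Ångström."""

    name: str
    element: str
    xyz: tuple[float, float, float]

    def __post_init__(self) -> None:
        xyz = tuple(float(v) for v in self.xyz)
        if len(xyz) != 3 or not all(math.isfinite(v) for v in xyz):
            raise InvalidInputError(f"atom {self.name}: coordinates must be 3 finite values")
        object.__setattr__(self, "xyz", xyz)


@dataclass
class Conformer:
    """A named-atom 3-D structure of a SAM-like ligand."""

    id: str
    atoms: list[AtomRecord]
    source: str = ""

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise InvalidInputError(f"conformer {self.id}: duplicate atom names {dup}")
        self._index: dict[str, int] = {a.name: i for i, a in enumerate(self.atoms)}

    @property
    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    def has_atoms(self, names: Iterable[str]) -> bool:
        return all(n in self._index for n in names)

    def atom(self, name: str) -> AtomRecord:
        try:
            return self.atoms[self._index[name]]
        except KeyError:
            raise MissingAtomError(f"conformer {self.id}: missing atom {name!r}") from None

    def coords(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Coordinates (n, 3) for the given atom names (all atoms if None)."""
        if names is None:
            return np.array([a.xyz for a in self.atoms], dtype=float)
        return np.array([self.atom(n).xyz for n in names], dtype=float)

    def with_coords(self, xyz: np.ndarray, new_id: str | None = None) -> "Conformer":
        """Copy of this conformer with replaced coordinates (same atom order)."""
        if xyz.shape != (len(self.atoms), 3):
            raise InvalidInputError("coordinate array shape does not match atom count")
        atoms = [
            AtomRecord(a.name, a.element, tuple(p)) for a, p in zip(self.atoms, xyz)
        ]
        return Conformer(id=new_id or self.id, atoms=atoms, source=self.source)


@dataclass
class ConformerEnsemble:
    """An ordered collection of conformers, optionally weighted."""

    conformers: list[Conformer]
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (len(self.conformers),):
                raise InvalidInputError("weights length must match conformer count")
            if (w < 0).any():
                raise InvalidInputError("ensemble weights must be >= 0")
            if abs(w.sum() - 1.0) > 1e-9:
                raise InvalidInputError("ensemble weights must sum to 1")
            self.weights = w

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def __getitem__(self, i: int) -> Conformer:
        return self.conformers[i]

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.conformers]


@dataclass(frozen=True)
class DescriptorRecord:
    """The two shape descriptors and their classes for one conformer."""

    conformer_id: str
    chi: float
    theta: float
    glyco_class: str
    shape_class: str
    knotted_mt_like: bool


def _interval(lo: float, hi: float) -> tuple[float, float]:
    return (float(lo), float(hi))


@dataclass(frozen=True)
class ClassificationRules:
    """Degree windows for descriptor classification (closed intervals)."""

    syn_window: tuple[float, float] = _interval(-150, -100)
    anti1_window: tuple[float, float] = _interval(-30, 30)
    anti2_window: tuple[float, float] = _interval(50, 100)
    intermediate_window: tuple[float, float] = _interval(-100, -50)
    bent_window: tuple[float, float] = _interval(80, 125)
    knotted_like_theta: tuple[float, float] = _interval(80, 125)
    knotted_like_chi: tuple[float, float] = _interval(-20, 60)

    def __post_init__(self) -> None:
        # the chi windows must not overlap: classification must be single-valued
        wins = sorted(
            [self.syn_window, self.anti1_window, self.anti2_window],
            key=lambda w: w[0],
        )
        inter = self.intermediate_window
        for lo, hi in wins + [inter]:
            if lo > hi:
                raise InvalidInputError(f"window bounds out of order: ({lo}, {hi})")
        for (l1, h1), (l2, h2) in zip(wins, wins[1:]):
            if h1 >= l2:
                raise InvalidInputError("chi classification windows overlap")
        for lo, hi in wins:
            # intermediate is half-open, so sharing an endpoint is fine
            if lo < inter[1] and hi > inter[0] and not (hi <= inter[0] or lo >= inter[1]):
                raise InvalidInputError("intermediate window overlaps a named chi window")

    @classmethod
    def from_yaml(cls, path) -> "ClassificationRules":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {k: _interval(*v) for k, v in raw.items()}
        return cls(**kwargs)

    def replace(self, **kwargs) -> "ClassificationRules":
        return replace(self, **kwargs)


DEFAULT_RULES = ClassificationRules()


# ---------------------------------------------------------------------------
# elementary geometry
# ---------------------------------------------------------------------------

def _as_points(*pts: Sequence[float]) -> list[np.ndarray]:
    return [np.asarray(p, dtype=float) for p in pts]


def compute_dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees, (-180, 180]) of four points.

    IUPAC right-handed convention: looking down the p2->p3 axis, the angle
    is positive when p4 is rotated clockwise from p1.
    """
    a, b, c, d = _as_points(p1, p2, p3, p4)
    b1, b2, b3 = b - a, c - b, d - c
    if np.linalg.norm(b1) < 1e-12 or np.linalg.norm(b2) < 1e-12 or np.linalg.norm(b3) < 1e-12:
        raise DegenerateGeometryError("dihedral undefined: consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("dihedral undefined: three consecutive points collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def compute_bend_angle(p1, p2, p3) -> float:
    """Planar angle (degrees, [0, 180]) at vertex p2."""
    a, b, c = _as_points(p1, p2, p3)
    v1, v2 = a - b, c - b
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        raise DegenerateGeometryError("angle undefined: coincident points")
    cosang = float(np.dot(v1, v2) / (n1 * n2))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosang))))


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _in_closed(x: float, window: tuple[float, float]) -> bool:
    return window[0] <= x <= window[1]


def classify_glycosidic(chi: float, rules: ClassificationRules = DEFAULT_RULES) -> str:
    """Classify the glycosidic dihedral as syn/anti1/anti2/intermediate/other.

    Named windows are closed; the intermediate window is open so that its
    shared endpoints with syn (-100) remain syn.
    """
    if not -180.0 < chi <= 180.0:
        raise InvalidInputError(f"chi must lie in (-180, 180], got {chi}")
    if _in_closed(chi, rules.syn_window):
        return "syn"
    if _in_closed(chi, rules.anti1_window):
        return "anti1"
    if _in_closed(chi, rules.anti2_window):
        return "anti2"
    lo, hi = rules.intermediate_window
    if lo < chi < hi:
        return "intermediate"
    return "other"


def classify_shape(theta: float, rules: ClassificationRules = DEFAULT_RULES) -> str:
    """Classify the bend angle as bent (inside the window) or extended."""
    if not 0.0 <= theta <= 180.0:
        raise InvalidInputError(f"theta must lie in [0, 180], got {theta}")
    return "bent" if _in_closed(theta, rules.bent_window) else "extended"


def is_knotted_mt_like(
    theta: float, chi: float, rules: ClassificationRules = DEFAULT_RULES
) -> bool:
    """True inside the 2-D (theta, chi) window of knotted-MT-bound SAM."""
    return _in_closed(theta, rules.knotted_like_theta) and _in_closed(
        chi, rules.knotted_like_chi
    )


def describe(
    conformer: Conformer, rules: ClassificationRules = DEFAULT_RULES
) -> DescriptorRecord:
    """Compute chi, theta and their classes for one conformer."""
    for name in DESCRIPTOR_ATOMS:
        if not conformer.has_atoms([name]):
            raise MissingAtomError(
                f"conformer {conformer.id}: descriptor atom {name!r} missing"
            )
    o4, c1, n9, c8 = (conformer.atom(n).xyz for n in ("O4'", "C1'", "N9", "C8"))
    sd = conformer.atom("SD").xyz
    chi = compute_dihedral(o4, c1, n9, c8)
    theta = compute_bend_angle(sd, o4, n9)
    return DescriptorRecord(
        conformer_id=conformer.id,
        chi=chi,
        theta=theta,
        glyco_class=classify_glycosidic(chi, rules),
        shape_class=classify_shape(theta, rules),
        knotted_mt_like=is_knotted_mt_like(theta, chi, rules),
    )


def describe_ensemble(
    ensemble: ConformerEnsemble | Iterable[Conformer],
    rules: ClassificationRules = DEFAULT_RULES,
) -> pd.DataFrame:
    """Descriptor table for an ensemble (one row per conformer)."""
    records = [describe(c, rules) for c in ensemble]
    return pd.DataFrame(
        {
            "conformer_id": [r.conformer_id for r in records],
            "chi_deg": [r.chi for r in records],
            "theta_deg": [r.theta for r in records],
            "glyco_class": [r.glyco_class for r in records],
            "shape_class": [r.shape_class for r in records],
            "knotted_mt_like": [r.knotted_mt_like for r in records],
        }
    )


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """x -> R @ x + t"""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, xyz: np.ndarray) -> np.ndarray:
        return np.asarray(xyz, dtype=float) @ self.rotation.T + self.translation


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation + translation mapping mobile onto target."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = tc - rot @ mc
    return rot, trans


def superpose(
    mobile: Conformer, target: Conformer, atom_subset: Sequence[str]
) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``target``.

    Returns the transform and the RMSD over ``atom_subset`` after applying
    it.  At least 3 subset atoms are required.
    """
    names = list(atom_subset)
    if len(names) < 3:
        raise InvalidInputError("superposition needs at least 3 atoms")
    for conf in (mobile, target):
        for n in names:
            if not conf.has_atoms([n]):
                raise MissingAtomError(f"conformer {conf.id}: missing atom {n!r}")
    mob = mobile.coords(names)
    tgt = target.coords(names)
    rot, trans = _kabsch(mob, tgt)
    tf = RigidTransform(rotation=rot, translation=trans)
    moved = tf.apply(mob)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - tgt) ** 2, axis=1))))
    return tf, rmsd


def apply_transform(conformer: Conformer, tf: RigidTransform) -> Conformer:
    """Apply a rigid transform to every atom of a conformer."""
    return conformer.with_coords(tf.apply(conformer.coords()))


def heavy_atom_rmsd(
    a: Conformer, b: Conformer, atom_subset: Sequence[str] = SAM_HEAVY_ATOMS
) -> float:
    """RMSD over ``atom_subset`` after optimal superposition on that subset."""
    _, rmsd = superpose(a, b, atom_subset)
    return rmsd


# ---------------------------------------------------------------------------
# interproton distances
# ---------------------------------------------------------------------------

def _group_atoms(conformer: Conformer, label: str) -> np.ndarray:
    try:
        names = PROTON_GROUPS[label]
    except KeyError:
        raise MissingAtomError(f"no structural protons known for label {label!r}") from None
    return conformer.coords(names)


def interproton_distance(
    conformer: Conformer,
    pair: tuple[str, str],
    mode: str = "r6",
) -> float:
    """Effective distance between two (pseudo-)protons on one conformer.

    For multi-proton groups (the S-methyl, the CB methylene) the default is
    the NOE-effective r^-6 average over all member pairs,

        d_eff = ( mean_k d_k^-6 )^(-1/6),

    which is what an intensity measurement actually reports for equivalent
    protons.  ``mode="centroid"`` instead measures from the geometric centre
    of each group.
    """
    la, lb = canonical_pair(*pair)
    ca = _group_atoms(conformer, la)
    cb = _group_atoms(conformer, lb)
    if mode == "centroid":
        return float(np.linalg.norm(ca.mean(axis=0) - cb.mean(axis=0)))
    if mode != "r6":
        raise InvalidInputError(f"unknown interproton distance mode {mode!r}")
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1).ravel()
    if (d <= 0).any():
        raise DegenerateGeometryError(
            f"conformer {conformer.id}: coincident protons in pair {la}-{lb}"
        )
    return float(np.mean(d ** -6.0) ** (-1.0 / 6.0))


def build_protons(
    conformer: Conformer,
    proton_labels: Iterable[str] | None = None,
) -> Conformer:
    """Add missing protons from the idealized template's local geometry.

    Crystal structures usually lack hydrogens; to evaluate interproton
    distances on such conformers, each missing proton needed for the given
    labels (all canonical labels by default) is rebuilt by rigidly
    superposing the template onto the conformer over the proton's parent
    heavy atom and its bonded heavy-atom neighbourhood, then copying the
    template proton position through that transform.  The provenance note
    is extended with "+protons(template)".
    """
    from .synthetic import build_template, template_bonds

    template = build_template()
    bonds: dict[str, set[str]] = {}
    for a, b in template_bonds():
        bonds.setdefault(a, set()).add(b)
        bonds.setdefault(b, set()).add(a)

    labels = list(proton_labels) if proton_labels is not None else list(PROTON_GROUPS)
    needed = {h for lab in labels for h in PROTON_GROUPS[lab]}
    missing = [h for h in needed if h not in conformer.atom_names]
    if not missing:
        return conformer

    heavy_names = {a.name for a in template.atoms if a.element != "H"}

    def star(centre: str) -> list[str]:
        # an atom plus its bonded heavy neighbours: internally rigid under
        # torsion driving (only bond angles, never torsions, fix its shape)
        out = [centre]
        out += [
            nb
            for nb in sorted(bonds.get(centre, ()))
            if nb in heavy_names and conformer.has_atoms([nb])
        ]
        return out

    new_atoms = list(conformer.atoms)
    for h in sorted(missing):
        parent = next(iter(bonds[h]))
        if not conformer.has_atoms([parent]):
            raise MissingAtomError(
                f"conformer {conformer.id}: parent atom {parent!r} of proton "
                f"{h!r} is missing"
            )
        frame = star(parent)
        if len(frame) < 3:
            # terminal parent (methyl, hydroxyl): anchor on its hub instead
            hubs = [nb for nb in frame[1:]]
            frame = star(hubs[0]) if hubs else frame
            if parent not in frame:
                frame.append(parent)
        if len(frame) < 3:
            raise MissingAtomError(
                f"conformer {conformer.id}: too few heavy atoms around {parent!r} "
                f"to rebuild proton {h!r}"
            )
        rot, trans = _kabsch(template.coords(frame), conformer.coords(frame))
        pos = rot @ np.array(template.atom(h).xyz) + trans
        new_atoms.append(AtomRecord(h, "H", tuple(pos)))
    source = (conformer.source + " +protons(template)").strip()
    return Conformer(id=conformer.id, atoms=new_atoms, source=source)


# ---------------------------------------------------------------------------
# ensemble fluctuation
# ---------------------------------------------------------------------------

def rmsf(
    ensemble: ConformerEnsemble | Sequence[Conformer],
    atom_subset: Sequence[str] = SAM_HEAVY_ATOMS,
    superpose_on: Sequence[str] | None = None,
) -> pd.Series:
    """Per-atom root-mean-square fluctuation about the ensemble mean.

    Every member is first superposed onto the first conformer on
    ``superpose_on`` (``atom_subset`` if not given); the fluctuation of each
    ``atom_subset`` atom is then measured about its mean position.
    """
    members = list(ensemble)
    if not members:
        raise InvalidInputError("rmsf needs a non-empty ensemble")
    names = list(atom_subset)
    fit_names = list(superpose_on) if superpose_on is not None else names
    ref = members[0]
    stacked = np.empty((len(members), len(names), 3))
    for i, conf in enumerate(members):
        tf, _ = superpose(conf, ref, fit_names)
        stacked[i] = tf.apply(conf.coords(names))
    mean = stacked.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((stacked - mean) ** 2, axis=2), axis=0))
    return pd.Series(fluct, index=names, name="rmsf_A")
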