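"""ROESY cross-peak intensities to interproton distance restraints.

In the isolated-spin-pair approximation the ROESY cross-peak intensity scales
as the inverse sixth power of the interproton distance, so a peak of
intensity ``I`` calibrated against a reference peak of intensity ``I_ref``
and known distance ``r_ref`` gives

    r = (I_ref / I)^(1/6) * r_ref.

The H1'-H2' ribose pair serves as the internal reference (2.90 Å with a
0.2 Å uncertainty).  Uncertainties are propagated assuming independent
errors in ``r_ref``, ``I_ref`` and ``I``:

    dr^2 = ((I_ref/I)^(1/6) * dr_ref)^2
         + ((1/6) * I_ref^(-5/6) * I^(-1/6) * r_ref * dI_ref)^2
         + ((1/6) * I_ref^(1/6)  * r_ref * I^(-7/6) * dI)^2.

Intensities are in arbitrary units: only ratios enter the formula, so no
unit is stored.  Distances are kept at full precision internally; the
two-decimal rounding seen in published tables is presentation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import DuplicatePairError, InvalidInputError
from .labels import canonical_pair

__all__ = [
    "CrossPeak",
    "Calibration",
    "DistanceRestraint",
    "RestraintTable",
    "intensity_to_distance",
    "propagate_distance_error",
    "peaks_to_restraints",
    "read_restraint_table",
    "write_restraint_table",
    "read_crosspeak_table",
    "load_reference_distances",
]


@dataclass(frozen=True)
class CrossPeak:
    """A ROESY cross-peak between two protons.

    Parameters
    ----------
    pair : tuple of str
        The two proton labels (any supported dialect; normalized on
        construction).
    intensity : float
        Cross-peak intensity, arbitrary units, > 0.
    intensity_error : float
        Absolute intensity uncertainty, same units, >= 0.
    """

    pair: tuple[str, str]
    intensity: float
    intensity_error: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", canonical_pair(*self.pair))
        if not self.intensity > 0:
            raise InvalidInputError(
                f"cross-peak {self.pair[0]}-{self.pair[1]}: intensity must be > 0, "
                f"got {self.intensity}"
            )
        if self.intensity_error < 0:
            raise InvalidInputError(
                f"cross-peak {self.pair[0]}-{self.pair[1]}: intensity error must be >= 0"
            )


@dataclass(frozen=True)
class Calibration:
    """Reference-peak calibration for the intensity-to-distance conversion.

    Defaults correspond to the H1'-H2' ribose reference: r_ref = 2.90 Å with
    dr_ref = 0.2 Å.  ``i_ref`` has no default: when the reference peak is not
    part of a user's table its intensity must be supplied explicitly,
    otherwise the conversion is underdetermined.
    """

    i_ref: float
    di_ref: float = 0.0
    r_ref: float = 2.90
    dr_ref: float = 0.2
    reference_pair: tuple[str, str] = ("H1'", "H2'")

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference_pair", canonical_pair(*self.reference_pair))
        if not self.i_ref > 0:
            raise InvalidInputError(f"reference intensity must be > 0, got {self.i_ref}")
        if not self.r_ref > 0:
            raise InvalidInputError(f"reference distance must be > 0, got {self.r_ref}")
        if self.di_ref < 0 or self.dr_ref < 0:
            raise InvalidInputError("reference uncertainties must be >= 0")


@dataclass(frozen=True)
class DistanceRestraint:
    """An interproton distance restraint r ± dr in Ångström."""

    pair: tuple[str, str]
    r: float
    dr: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", canonical_pair(*self.pair))
        if not self.r > 0:
            raise InvalidInputError(
                f"restraint {self.pair[0]}-{self.pair[1]}: distance must be > 0, got {self.r}"
            )
        if self.dr < 0:
            raise InvalidInputError(
                f"restraint {self.pair[0]}-{self.pair[1]}: uncertainty must be >= 0"
            )


@dataclass
class RestraintTable:
    """An ordered collection of distance restraints with unique pairs."""

    restraints: list[DistanceRestraint] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for rest in self.restraints:
            if rest.pair in seen:
                raise DuplicatePairError(
                    f"duplicate restraint pair {rest.pair[0]}-{rest.pair[1]}"
                )
            seen.add(rest.pair)

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)

    def __getitem__(self, key):
        if isinstance(key, tuple):
            pair = canonical_pair(*key)
            for rest in self.restraints:
                if rest.pair == pair:
                    return rest
            raise KeyError(f"no restraint for pair {pair}")
        return self.restraints[key]

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [rest.pair for rest in self.restraints]

    def distances(self) -> list[float]:
        return [rest.r for rest in self.restraints]

    def errors(self) -> list[float]:
        return [rest.dr for rest in self.restraints]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Atom1": [r.pair[0] for r in self.restraints],
                "Atom2": [r.pair[1] for r in self.restraints],
                "Distance_A": [r.r for r in self.restraints],
                "Error_A": [r.dr for r in self.restraints],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RestraintTable":
        restraints = [
            DistanceRestraint(
                pair=(str(row.Atom1), str(row.Atom2)),
                r=float(row.Distance_A),
                dr=float(row.Error_A),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(restraints)


def intensity_to_distance(peak: CrossPeak, cal: Calibration) -> DistanceRestraint:
    """Convert one cross-peak to a distance restraint.

    r = (I_ref / I)^(1/6) * r_ref; the uncertainty is filled in by
    :func:`propagate_distance_error`.
    """
    r = (cal.i_ref / peak.intensity) ** (1.0 / 6.0) * cal.r_ref
    dr = propagate_distance_error(peak, cal)
    return DistanceRestraint(pair=peak.pair, r=r, dr=dr)


def propagate_distance_error(peak: CrossPeak, cal: Calibration) -> float:
    """Propagated distance uncertainty, assuming independent error sources.

    Quadrature sum of the three first-order terms: the reference-distance
    term (I_ref/I)^(1/6) * dr_ref, the reference-intensity term and the
    peak-intensity term (see module docstring).
    """
    i, di = peak.intensity, peak.intensity_error
    iref, diref = cal.i_ref, cal.di_ref
    ratio16 = (iref / i) ** (1.0 / 6.0)
    term_rref = ratio16 * cal.dr_ref
    term_iref = (1.0 / 6.0) * iref ** (-5.0 / 6.0) * i ** (-1.0 / 6.0) * cal.r_ref * diref
    term_i = (1.0 / 6.0) * iref ** (1.0 / 6.0) * cal.r_ref * i ** (-7.0 / 6.0) * di
    return math.sqrt(term_rref**2 + term_iref**2 + term_i**2)


def peaks_to_restraints(peaks: Iterable[CrossPeak], cal: Calibration) -> RestraintTable:
    """Convert a collection of cross-peaks into a restraint table."""
    return RestraintTable([intensity_to_distance(p, cal) for p in peaks])


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", encoding="utf-8", float_precision="round_trip"
    )
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing required columns {missing}")
    return df


def read_restraint_table(path: str | Path) -> RestraintTable:
    """Read a restraint TSV (columns Atom1, Atom2, Distance_A, Error_A).

    ``#`` comment lines are allowed; labels in any supported dialect are
    normalized; row order is preserved.  Duplicate unordered pairs raise
    :class:`~samconf.errors.DuplicatePairError`.
    """
    df = _read_tsv(path, ("Atom1", "Atom2", "Distance_A", "Error_A"))
    return RestraintTable.from_dataframe(df)


def write_restraint_table(table: RestraintTable, path: str | Path) -> None:
    """Write a restraint table as TSV at full stored precision.

    ``read_restraint_table(write(x))`` reproduces ``x`` exactly: values are
    serialized with repr-round-trip precision.
    """
    df = table.to_dataframe()
    df["Distance_A"] = [repr(float(v)) for v in df["Distance_A"]]
    df["Error_A"] = [repr(float(v)) for v in df["Error_A"]]
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_crosspeak_table(path: str | Path) -> list[CrossPeak]:
    """Read a cross-peak TSV (columns Atom1, Atom2, Intensity, IntensityError)."""
    df = _read_tsv(path, ("Atom1", "Atom2", "Intensity", "IntensityError"))
    return [
        CrossPeak(
            pair=(str(row.Atom1), str(row.Atom2)),
            intensity=float(row.Intensity),
            intensity_error=float(row.IntensityError),
        )
        for row in df.itertuples(index=False)
    ]


def load_reference_distances() -> RestraintTable:
    """The packaged experimental SAM restraint table (39 interproton distances).

    These are the ROESY-derived distances of free SAM in water at 25 °C,
    with the H1'-H2' pair (2.90 ± 0.2 Å) as internal calibration.
    """
    with resources.as_file(
        resources.files("samconf.data").joinpath("table1_distances.tsv")
    ) as p:
        return read_restraint_table(p)
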