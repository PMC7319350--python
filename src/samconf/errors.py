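"""Exception hierarchy shared across the package."""


class SamconfError(Exception):
    """Base class for all samconf errors."""


class InvalidInputError(SamconfError, ValueError):
    """A numeric input violates a precondition (e.g. non-positive intensity)."""


class UnknownProtonLabelError(SamconfError, ValueError):
    """A proton label could not be normalized to the canonical vocabulary."""


class DuplicatePairError(SamconfError, ValueError):
    """An unordered proton pair occurs more than once in a restraint table."""


class MissingAtomError(SamconfError, KeyError):
    """A required atom is absent from a conformer."""


class DegenerateGeometryError(SamconfError, ValueError):
    """Coincident or collinear points make an angle/dihedral undefined."""
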