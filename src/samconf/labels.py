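"""Canonical proton vocabulary for SAM and normalization of label dialects.

NMR tables use prose labels ("methyl group", Greek letters), while structure
files use PDB-style names.  Everything in the package speaks the canonical
vocabulary below; :func:`normalize_proton_label` maps the common dialects
onto it and rejects anything else.
"""

from __future__ import annotations

from .errors import UnknownProtonLabelError

#: Canonical proton identifiers of SAM, in the order they appear around the
#: molecule (ribose, adenine, methionine chain, methyl pseudo-atom).
CANONICAL_PROTONS: tuple[str, ...] = (
    "H1'", "H2'", "H3'", "H4'", "H5'", "H5''",
    "H8", "H2",
    "Halpha", "Hbeta", "Hgamma", "Hgamma'",
    "MET-CH3",
)

#: Labels that stand for a group of equivalent (or spectrally unresolved)
#: protons rather than a single nucleus.  MET-CH3 covers the three S-methyl
#: protons; Hbeta covers the two CB methylene protons, which share one
#: chemical shift.
PSEUDO_PROTONS: frozenset[str] = frozenset({"MET-CH3", "Hbeta"})

# Unicode characters that show up in transcribed tables.
_CHAR_MAP = str.maketrans({
    "’": "'",   # right single quote -> prime
    "′": "'",   # prime
    "”": "''",  # right double quote -> double prime
    "″": "''",  # double prime
    "α": "alpha",
    "β": "beta",
    "γ": "gamma",
})

_ALIASES = {
    "h5'2": "H5''",
    "h5''": "H5''",
    "ha": "Halpha",
    "halpha": "Halpha",
    "hb": "Hbeta",
    "hbeta": "Hbeta",
    "hg": "Hgamma",
    "hgamma": "Hgamma",
    "hg'": "Hgamma'",
    "hgamma'": "Hgamma'",
    "methyl group": "MET-CH3",
    "methylgroup": "MET-CH3",
    "met-ch3": "MET-CH3",
    "ch3": "MET-CH3",
    "q-ch3": "MET-CH3",
}
_ALIASES.update({p.lower(): p for p in CANONICAL_PROTONS})


def normalize_proton_label(token: str) -> str:
    """Map a proton label in any supported dialect to its canonical form.

    Raises
    ------
    UnknownProtonLabelError
        If the token is not recognisable as a SAM proton.
    """
    if not isinstance(token, str):
        raise UnknownProtonLabelError(f"proton label must be a string, got {token!r}")
    cleaned = token.strip().translate(_CHAR_MAP)
    # collapse straight double quote used for the second H5' proton
    cleaned = cleaned.replace('"', "''")
    key = cleaned.lower()
    if key in _ALIASES:
        return _ALIASES[key]
    raise UnknownProtonLabelError(f"unknown proton label: {token!r}")


def is_pseudo_atom(label: str) -> bool:
    """True if the canonical label denotes a multi-proton pseudo-atom."""
    return label in PSEUDO_PROTONS


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Normalize both labels and return them as a canonically ordered pair.

    The order is the vocabulary order of :data:`CANONICAL_PROTONS`, so the
    same unordered pair always maps to the same tuple.
    """
    la, lb = normalize_proton_label(a), normalize_proton_label(b)
    if la == lb:
        raise UnknownProtonLabelError(f"a proton pair needs two distinct protons, got {a!r}/{b!r}")
    order = {p: i for i, p in enumerate(CANONICAL_PROTONS)}
    return (la, lb) if order[la] <= order[lb] else (lb, la)
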