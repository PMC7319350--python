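"""Shared programmatic PDB fixture builders for the test suite."""

import numpy as np

from samconf.geometry import SAM_HEAVY_ATOMS


def _pdb_atom(serial, name, resname, chain, resnum, xyz, element, het=False):
    rec = "HETATM" if het else "ATOM  "
    n = name if len(name) >= 4 else f" {name:<3s}"
    x, y, z = xyz
    return (
        f"{rec}{serial:>5d} {n:<4.4s} {resname:<3s} {chain}{resnum:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
    )


def write_boundary_contact_pdb(template, path):
    """SAM plus one residue just inside (4.9 Å) and one just outside (5.1 Å)
    the 5 Å contact cutoff, measured from the ribose O2' atom."""
    o2p = np.array(template.atom("O2'").xyz)
    centre = template.coords(SAM_HEAVY_ATOMS).mean(axis=0)
    u = o2p - centre
    u = u / np.linalg.norm(u)

    def out(d):
        return o2p + d * u

    lines = [
        _pdb_atom(1, "N", "GLY", "A", 1, out(7.5), "N"),
        _pdb_atom(2, "CA", "GLY", "A", 1, out(6.3), "C"),
        _pdb_atom(3, "C", "GLY", "A", 1, out(5.6), "C"),
        _pdb_atom(4, "O", "GLY", "A", 1, out(4.9), "O"),
        _pdb_atom(5, "N", "ALA", "A", 2, out(8.0), "N"),
        _pdb_atom(6, "CA", "ALA", "A", 2, out(7.0), "C"),
        _pdb_atom(7, "C", "ALA", "A", 2, out(6.6), "C"),
        _pdb_atom(8, "O", "ALA", "A", 2, out(7.7), "O"),
        _pdb_atom(9, "CB", "ALA", "A", 2, out(5.1), "C"),
        "TER",
    ]
    serial = 10
    for atom in template.atoms:
        lines.append(
            _pdb_atom(serial, atom.name, "SAM", "L", 1, atom.xyz, atom.element, het=True)
        )
        serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
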