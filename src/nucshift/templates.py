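"""Residue classification tables and CCD-backed connectivity templates.

Bond lists and ideal coordinates for standard residues come from the
chemical component dictionary bundled with biotite; lookups are cached and
missing components simply return None so callers can fall back to
distance-based perception.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

NUCLEIC_RESIDUES = {
    "A", "C", "G", "U", "I",
    "DA", "DC", "DG", "DT", "DU", "DI",
}

PROTEIN_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

WATER_RESIDUES = {"HOH", "WAT", "DOD", "H2O"}

ION_RESIDUES = {
    "NA", "K", "MG", "CA", "CL", "ZN", "MN", "FE", "CU", "BR", "IOD",
    "CS", "LI", "NI", "CD", "SR", "BA", "RB", "F",
}

# single-bond covalent radii, Å (Cordero et al. consensus values)
COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "CL": 1.02, "Cl": 1.02, "BR": 1.20, "Br": 1.20,
    "I": 1.39, "SE": 1.20, "Se": 1.20,
}

ATOMIC_NUMBERS = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16,
    "Cl": 17, "CL": 17, "Se": 34, "SE": 34, "Br": 35, "BR": 35, "I": 53,
}


@lru_cache(maxsize=256)
def _ccd_residue(resname: str):
    import biotite.structure.info as info

    try:
        return info.residue(resname.strip().upper())
    except KeyError:
        return None


@lru_cache(maxsize=256)
def template_bonds(resname: str):
    """Intra-residue bonds as (name1, name2, order) tuples, or None.

    CCD aromatic bond types are reported with order 1.5 so that downstream
    hybridization assignment can recognise them.
    """
    arr = _ccd_residue(resname)
    if arr is None or arr.bonds is None:
        return None
    names = arr.atom_name
    out = []
    for i, j, btype in arr.bonds.as_array():
        bt = int(btype)
        if bt in (5, 6, 7):  # aromatic single/double/triple
            order = 1.5
        elif bt in (1, 2, 3):
            order = float(bt)
        else:
            order = 1.0
        out.append((str(names[i]), str(names[j]), order))
    return tuple(out)


@lru_cache(maxsize=256)
def template_geometry(resname: str):
    """Ideal-coordinate template: (atom names, elements, coords) or None."""
    arr = _ccd_residue(resname)
    if arr is None:
        return None
    return (
        tuple(str(n) for n in arr.atom_name),
        tuple(str(e).capitalize() if len(str(e)) > 1 else str(e) for e in arr.element),
        np.array(arr.coord, dtype=float),
    )


@lru_cache(maxsize=256)
def template_atom_names(resname: str):
    geo = template_geometry(resname)
    return None if geo is None else set(geo[0])
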