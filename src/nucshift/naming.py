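"""Atom-name normalization onto the PDB-v3 canon.

Experimental inputs arrive in at least three dialects: PDB v2 (asterisks for
primes, ``O1P``), PDB v3 (primes, ``OP1``) and BMRB conventions
(``H2'1``/``H2'2``, leading-digit methyls like ``1H2'``).  Everything is
mapped onto the v3 names so that structure atoms and shift-table rows join
on equal keys.  The mapping is idempotent: v3 names are fixed points.
"""

from __future__ import annotations

import re

__all__ = ["normalize_atom_names", "is_normalized"]

# residue-independent renames (v2 remediation + BMRB habits)
_GLOBAL = {
    "O1P": "OP1",
    "O2P": "OP2",
    "O3P": "OP3",
    "H3T": "HO3'",
    "H5T": "HO5'",
    "HO3": "HO3'",
    "HO5": "HO5'",
    "HN": "H",
    # sugar prime protons, numbered-suffix dialect
    "H2'1": "H2'",
    "H2'2": "H2''",
    "H5'1": "H5'",
    "H5'2": "H5''",
    'H2"': "H2''",
    'H5"': "H5''",
    "H2''1": "H2'",  # seen after naive *->' on H2*1
}

# thymine methyl: v2 carried the methyl on C5M with H51/H52/H53
_BY_RESIDUE = {}
for _t in ("DT", "T"):
    _BY_RESIDUE.update({
        (_t, "C5M"): "C7",
        (_t, "H51"): "H71", (_t, "H52"): "H72", (_t, "H53"): "H73",
        (_t, "H5M1"): "H71", (_t, "H5M2"): "H72", (_t, "H5M3"): "H73",
    })

_LEADING_DIGIT = re.compile(r"^([123])(H[A-Z0-9']*)$")


def normalize_atom_names(raw_name: str, residue_name: str = "") -> str:
    """Map one raw atom name onto its PDB-v3 canonical form.

    Unknown names pass through unchanged (the caller decides whether an
    unmatched name is an error); the function is idempotent.
    """
    name = raw_name.strip().replace("*", "'")
    rn = residue_name.strip().upper()
    key = (rn, name)
    if key in _BY_RESIDUE:
        return _BY_RESIDUE[key]
    if name in _GLOBAL:
        return _GLOBAL[name]
    m = _LEADING_DIGIT.match(name)
    if m:
        # 1H2' -> H2', 2H2' -> H2'', 1H6 -> H61 ...
        digit, stem = m.group(1), m.group(2)
        if stem.endswith("'"):
            cand = stem if digit == "1" else stem + "'"
        else:
            cand = stem + digit
        return normalize_atom_names(cand, rn)
    return name


def is_normalized(name: str, residue_name: str = "") -> bool:
    return normalize_atom_names(name, residue_name) == name
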