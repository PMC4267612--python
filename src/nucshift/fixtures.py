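"""Synthetic structures and shift tables with known ground truth.

Toy nucleic-acid chains are built from the CCD ideal-coordinate residue
templates, linked O3'(i)-P(i+1) with an exact 1.60 Å bridge and a helical
twist per residue.  The geometry is valence-complete and compact enough
that fragments have nontrivial neighbors at the 5 Å cutoff, but it is not a
physically accurate B-form helix — tests that need base-pair hydrogen bonds
construct those geometries explicitly.  Synthetic "experimental" shift
tables are manufactured from the mock backend plus a known reference
shielding, optional Gaussian noise and optional injected stereospecific
swaps, so every downstream statistic has a recoverable truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Structure, read_structure
from .templates import template_geometry

__all__ = [
    "SyntheticTruth", "make_toy_nucleic", "make_toy_peptide", "make_toy_ligand",
    "make_synthetic_shifts", "render_pdb", "shift_table_to_star",
]

_DNA = {"A": "DA", "C": "DC", "G": "DG", "T": "DT", "U": "DU"}
_RNA = {"A": "A", "C": "C", "G": "G", "U": "U", "T": "DT"}
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G", "U": "A"}

# free-nucleotide template atoms dropped for an intra-chain residue
_5P_EXTRAS = ("OP3", "HOP3", "HOP2")
# additionally dropped at a 5'-OH terminus
_PHOSPHATE = ("P", "OP1", "OP2")

RISE = 3.6       # Å per residue along the helix axis
TWIST = 40.0     # deg per residue
O3P_BOND = 1.60  # Å, inter-residue bridge


@dataclass
class SyntheticTruth:
    """Ground truth behind a synthetic shift table."""

    sigma_standard: float = 31.0   # ppm
    noise: float = 0.0             # ppm, Gaussian width on delta_exp
    swaps: list[tuple[str, int, str, str]] = field(default_factory=list)
    # each swap: (chain, resnum, name1, name2) — experimental values exchanged
    pair_separation: float = 1.2   # ppm split imposed on prochiral amino pairs
    seed: int = 0


def _rot_z(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _residue_template(resname: str, five_prime: bool, three_prime: bool = True):
    names, elements, coords = template_geometry(resname)
    # the vacant OP3 site is where the previous residue's O3' attaches
    op3_site = coords[names.index("OP3")].copy() if "OP3" in names else None
    keep = [i for i, n in enumerate(names) if n not in _5P_EXTRAS]
    if five_prime:
        keep = [i for i in keep if names[i] not in _PHOSPHATE]
    if not three_prime:
        # O3' is esterified to the next residue's P: no hydroxyl proton
        keep = [i for i in keep if names[i] != "HO3'"]
    names = [names[i] for i in keep]
    elements = [elements[i] for i in keep]
    coords = coords[keep].copy()
    if five_prime:
        # restore the hydroxyl proton on O5' that the phosphate replaced
        i_o5 = names.index("O5'")
        i_c5 = names.index("C5'")
        u = coords[i_o5] - coords[i_c5]
        u /= np.linalg.norm(u)
        names.append("HO5'")
        elements.append("H")
        coords = np.vstack([coords, coords[i_o5] + 0.96 * u])
    return names, elements, coords, op3_site


def _build_strand(sequence: str, alphabet: dict, chain: str, start_resnum: int,
                  curvature: float = 0.0):
    """Place residues along a (optionally bent) helix; returns atom rows."""
    rows = []  # (chain, resnum, resname, name, element, xyz)
    placed_xyz: list[np.ndarray] = []
    placed_tags: list[str] = []
    prev_o3 = None
    for i, letter in enumerate(sequence):
        if letter not in alphabet:
            raise ValueError(f"unsupported residue letter {letter!r}")
        resname = alphabet[letter]
        names, elements, coords0, op3_site = _residue_template(
            resname, five_prime=(i == 0), three_prime=(i == len(sequence) - 1))
        if prev_o3 is None:
            coords = coords0 - coords0[names.index("C1'")]
        else:
            # anchor: the previous O3' occupies this residue's vacant OP3
            # site so the P keeps a tetrahedral oxygen arrangement; among
            # candidate orientations take the first without steric clash
            coords = None
            best, best_min = None, -1.0
            prev_arr = np.array(placed_xyz)
            for k in range(24):
                ang = i * (TWIST + curvature * 40.0) + k * 15.0
                for ax in (_rot_z(ang), _rot_x(30.0) @ _rot_z(ang),
                           _rot_x(-30.0) @ _rot_z(ang)):
                    cand = coords0 @ ax.T
                    cand = cand + (prev_o3 - op3_site @ ax.T)
                    d = np.linalg.norm(prev_arr[:, None, :] - cand[None, :, :], axis=2)
                    # the new P (and its oxygens) legitimately sit near prev O3'
                    d[placed_tags.index(f"{i - 1}:O3'")] = np.inf
                    dmin = float(d.min())
                    if dmin > best_min:
                        best, best_min = cand, dmin
                    if dmin >= 1.45:
                        coords = cand
                        break
                if coords is not None:
                    break
            if coords is None:
                coords = best
        prev_o3 = coords[names.index("O3'")]
        for n, e, xyz in zip(names, elements, coords):
            rows.append((chain, start_resnum + i, resname, n, e, xyz))
            placed_xyz.append(xyz)
            placed_tags.append(f"{i}:{n}")
    return rows


def render_pdb(rows_by_model: list[list[tuple]], name: str = "toy") -> str:
    """Serialize atom rows into multi-model PDB text."""
    lines = [f"HEADER    {name}"]
    multi = len(rows_by_model) > 1
    for m, rows in enumerate(rows_by_model, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        serial = 0
        for chain, resnum, resname, atname, element, xyz in rows:
            serial += 1
            nm = atname if len(atname) >= 4 else f" {atname}"
            lines.append(
                f"ATOM  {serial:5d} {nm:<4s}{'':1s}{resname:>3s} {chain}{resnum:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {element:>2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_toy_nucleic(sequence: str, form: str = "single", n_models: int = 1,
                     jitter: float = 0.0, seed: int = 0, rna: bool = False) -> Structure:
    """Idealized toy nucleic-acid structure with all hydrogens.

    form "single" is one strand, "duplex" adds the reverse-complement strand
    alongside, "hairpin" bends a single strand back on itself.  n_models
    copies are jittered by a seeded Gaussian of width ``jitter`` Å (model 1
    is unjittered when jitter is 0).
    """
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    alphabet = _RNA if rna else _DNA
    if form not in ("single", "duplex", "hairpin"):
        raise ValueError(f"unknown form {form!r}")
    curvature = 1.5 if form == "hairpin" else 0.0
    rows = _build_strand(sequence, alphabet, "A", 1, curvature=curvature)
    if form == "duplex":
        comp = "".join(_COMPLEMENT[c] for c in reversed(sequence))
        rows_b = _build_strand(comp, alphabet, "B", 1)
        xyz_a = np.array([r[5] for r in rows])
        xyz_b = np.array([r[5] for r in rows_b])
        # slide strand B along +x until the closest approach is ~4 Å
        offset = np.array([1.0, 0.0, 0.0])
        shift = 0.0
        for shift in np.arange(0.0, 60.0, 0.5):
            d = np.linalg.norm(
                xyz_a[:, None, :] - (xyz_b[None, :, :] + shift * offset), axis=2
            )
            if d.min() >= 4.0:
                break
        rows_b = [(c, r, rn, an, el, xyz + shift * offset)
                  for (c, r, rn, an, el, xyz) in rows_b]
        rows = rows + rows_b

    rng = np.random.default_rng(seed)
    models = []
    for _ in range(n_models):
        if jitter > 0:
            noise = rng.normal(0.0, jitter, size=(len(rows), 3))
        else:
            noise = np.zeros((len(rows), 3))
        models.append([(c, r, rn, an, el, xyz + dn)
                       for (c, r, rn, an, el, xyz), dn in zip(rows, noise)])
    text = render_pdb(models, name=f"toy-{form}-{sequence}")
    return read_structure(text, "all", name=f"toy-{form}-{sequence}")


_AA3 = {
    "A": "ALA", "G": "GLY", "S": "SER", "C": "CYS", "V": "VAL", "T": "THR",
    "L": "LEU", "I": "ILE", "P": "PRO", "F": "PHE", "M": "MET", "D": "ASP",
    "N": "ASN", "E": "GLU", "Q": "GLN", "K": "LYS", "R": "ARG", "H": "HIS",
    "W": "TRP", "Y": "TYR",
}


def make_toy_peptide(sequence: str, n_models: int = 1, jitter: float = 0.0,
                     seed: int = 0, chain: str = "P") -> Structure:
    """Extended-conformation toy peptide from CCD amino-acid templates."""
    sequence = sequence.upper()
    rows = []
    prev_c = None
    prev_dir = np.array([1.0, 0.0, 0.0])
    for i, letter in enumerate(sequence):
        if letter not in _AA3:
            raise ValueError(f"unsupported residue letter {letter!r}")
        resname = _AA3[letter]
        names, elements, coords = template_geometry(resname)
        keep = [k for k, n in enumerate(names)
                if not (n in ("OXT", "HXT") and i < len(sequence) - 1)
                and not (n == "H2" and i > 0)
                and n != "HXT"]
        names = [names[k] for k in keep]
        elements = [elements[k] for k in keep]
        coords = coords[keep].copy()
        R = _rot_z(i * 180.0)
        coords = coords @ R.T
        if prev_c is None:
            shift = -coords[names.index("CA")]
        else:
            shift = (prev_c + 1.33 * prev_dir) - coords[names.index("N")]
        coords = coords + shift
        i_c, i_ca = names.index("C"), names.index("CA")
        d = coords[i_c] - coords[i_ca]
        prev_dir = 0.5 * d / np.linalg.norm(d) + 0.5 * np.array([1.0, 0.0, 0.0])
        prev_dir /= np.linalg.norm(prev_dir)
        prev_c = coords[i_c]
        for n, e, xyz in zip(names, elements, coords):
            rows.append((chain, i + 1, resname, n, e, xyz))
    rng = np.random.default_rng(seed)
    models = []
    for _ in range(n_models):
        noise = rng.normal(0.0, jitter, size=(len(rows), 3)) if jitter > 0 else 0.0
        models.append([(c, r, rn, an, el, xyz + (noise[k] if jitter > 0 else 0.0))
                       for k, (c, r, rn, an, el, xyz) in enumerate(rows)])
    text = render_pdb(models, name=f"toy-peptide-{sequence}")
    return read_structure(text, "all", name=f"toy-peptide-{sequence}")


def make_toy_ligand(kind: str = "toluene") -> tuple[Structure, "object"]:
    """Hand-built ligand test cases; returns (Structure, bond graph).

    kind: "toluene" (ring + CH3), "ring_arm" (ring + CH2-CH2-OH) or
    "acyclic" (butane-like chain).  Residue name LIG classifies as ligand.
    """
    import networkx as nx

    from .structure import Atom, Model, Structure as S, atom_id as aid

    atoms: list[tuple[str, str, np.ndarray]] = []  # (name, element, xyz)
    bonds: list[tuple[str, str, float]] = []

    def ring6(prefix="C", z=0.0):
        r = 1.40
        names = []
        for k in range(6):
            t = np.deg2rad(60 * k)
            names.append(f"{prefix}{k + 1}")
            atoms.append((names[-1], "C", np.array([r * np.cos(t), r * np.sin(t), z])))
        for k in range(6):
            bonds.append((names[k], names[(k + 1) % 6], 1.5))
        return names

    if kind in ("toluene", "ring_arm"):
        ring = ring6()
        # ring hydrogens on C2..C6 (C1 carries the substituent)
        for k in range(1, 6):
            t = np.deg2rad(60 * k)
            atoms.append((f"H{k + 1}", "H", np.array([2.48 * np.cos(t), 2.48 * np.sin(t), 0.0])))
            bonds.append((f"C{k + 1}", f"H{k + 1}", 1.0))
        if kind == "toluene":
            atoms.append(("C7", "C", np.array([2.90, 0.0, 0.0])))
            bonds.append(("C1", "C7", 1.0))
            for j, dz in enumerate((1.0, -0.5, -0.5)):
                dy = (0.0, 0.87, -0.87)[j]
                atoms.append((f"H7{j + 1}", "H", np.array([3.26, dy, dz])))
                bonds.append(("C7", f"H7{j + 1}", 1.0))
        else:
            chainxyz = {"C7": [2.90, 0.0, 0.0], "C8": [3.66, 0.0, 1.26], "O1": [5.02, 0.0, 1.10]}
            for n, xyz in chainxyz.items():
                atoms.append((n, "C" if n.startswith("C") else "O", np.array(xyz)))
            bonds += [("C1", "C7", 1.0), ("C7", "C8", 1.0), ("C8", "O1", 1.0)]
            hxyz = {"H71": [2.40, 0.89, -0.36], "H72": [2.40, -0.89, -0.36],
                    "H81": [3.40, 0.89, 1.86], "H82": [3.40, -0.89, 1.86],
                    "HO1": [5.45, 0.0, 1.95]}
            parent = {"H71": "C7", "H72": "C7", "H81": "C8", "H82": "C8", "HO1": "O1"}
            for n, xyz in hxyz.items():
                atoms.append((n, "H", np.array(xyz)))
                bonds.append((parent[n], n, 1.0))
    elif kind == "acyclic":
        for k in range(4):
            atoms.append((f"C{k + 1}", "C", np.array([1.5 * k, 0.3 * (k % 2), 0.0])))
            if k:
                bonds.append((f"C{k}", f"C{k + 1}", 1.0))
        nh = 0
        for k in range(4):
            count = 3 if k in (0, 3) else 2
            for j in range(count):
                nh += 1
                atoms.append((f"H{nh}", "H",
                              np.array([1.5 * k, 0.3 * (k % 2) + 0.9 * np.cos(2.1 * j),
                                        0.9 * np.sin(2.1 * j) + 0.4])))
                bonds.append((f"C{k + 1}", f"H{nh}", 1.0))
    else:
        raise ValueError(f"unknown ligand kind {kind!r}")

    alist = [Atom(aid("L", 1, "LIG", n), n, e, xyz, 0, "L", 1, "LIG")
             for n, e, xyz in atoms]
    model = Model(alist)
    st = S(models=[model], entity_class={("L", 1): "ligand"}, name=f"toy-{kind}")
    g = nx.Graph()
    for a in alist:
        g.add_node(a.atom_id, element=a.element)
    for n1, n2, order in bonds:
        g.add_edge(aid("L", 1, "LIG", n1), aid("L", 1, "LIG", n2), order=order)
    return st, g


# ---------------------------------------------------------------------------
# Synthetic shift tables


def shift_table_to_star(entries: dict, nucleus: str = "1H",
                        source: str = "synthetic") -> str:
    """Serialize shift entries as an NMR-STAR v3 chemical-shift loop."""
    lines = [
        f"data_{source}", "", "save_assigned_chemical_shifts",
        "   _Assigned_chem_shift_list.Sf_category  assigned_chemical_shifts", "",
        "   loop_",
        "      _Atom_chem_shift.ID",
        "      _Atom_chem_shift.Auth_asym_ID",
        "      _Atom_chem_shift.Comp_index_ID",
        "      _Atom_chem_shift.Comp_ID",
        "      _Atom_chem_shift.Atom_ID",
        "      _Atom_chem_shift.Atom_type",
        "      _Atom_chem_shift.Atom_isotope_number",
        "      _Atom_chem_shift.Val",
        "",
    ]
    element = "".join(c for c in nucleus if c.isalpha()) or "H"
    isotope = "".join(c for c in nucleus if c.isdigit()) or "1"
    for k, ((chain, resnum, resname, name), val) in enumerate(sorted(entries.items()), 1):
        nm = f"\"{name}\"" if "'" in name else name
        lines.append(f"      {k:4d} {chain} {resnum:3d} {resname:<3s} {nm:<7s} "
                     f"{element} {isotope} {val:9.4f}")
    lines += ["   stop_", "save_", ""]
    return "\n".join(lines)


def make_synthetic_shifts(structure: Structure, truth: SyntheticTruth,
                          cutoff: float = 5.0, model_index: int = 0):
    """Manufacture an "experimental" shift table from the mock backend.

    delta_exp = sigma_standard_true - sigma_mock + Gaussian(0, noise) for
    every central-fragment proton of the chosen model, then listed prochiral
    pairs are swapped.  Returns (ShiftTable, sigma_by_atom, star_text).
    """
    from .pipeline import predict_shieldings
    from .structure import ShiftTable

    sigma = predict_shieldings(structure, cutoff=cutoff, model_index=model_index,
                               backend="mock", seed=truth.seed)
    model = structure.models[model_index]
    if truth.pair_separation > 0:
        # give prochiral amino pairs distinguishable predictions: the first
        # member (H21/H41/H61) goes downfield, the second upfield — without
        # this, amino-proton swaps are undetectable in principle
        from .analysis import PROCHIRAL_PAIRS
        from .structure import atom_id as _aid
        for a in model.atoms:
            for resnames, (n1, n2) in PROCHIRAL_PAIRS:
                if a.resname in resnames and a.name in (n1, n2):
                    sign = -1.0 if a.name == n1 else +1.0
                    aid2 = _aid(a.chain, a.resnum, a.resname, a.name)
                    if aid2 in sigma:
                        sigma[aid2] += sign * truth.pair_separation / 2.0
    by_id = {a.atom_id: a for a in model.atoms}
    rng = np.random.default_rng(truth.seed + 1)
    entries = {}
    for aid_, s in sorted(sigma.items()):
        a = by_id[aid_]
        if not a.is_hydrogen:
            continue
        entries[(a.chain, a.resnum, a.resname, a.name)] = (
            truth.sigma_standard - s + (rng.normal(0.0, truth.noise) if truth.noise > 0 else 0.0)
        )
    for chain, resnum, n1, n2 in truth.swaps:
        k1 = next((k for k in entries if k[0] == chain and k[1] == resnum and k[3] == n1), None)
        k2 = next((k for k in entries if k[0] == chain and k[1] == resnum and k[3] == n2), None)
        if k1 is None or k2 is None:
            raise ValueError(f"swap target {chain}/{resnum} {n1}/{n2} not present")
        entries[k1], entries[k2] = entries[k2], entries[k1]
    table = ShiftTable(entries=entries, nucleus="1H", source="synthetic")
    return table, sigma, shift_table_to_star(entries)
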