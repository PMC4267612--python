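"""Structure and chemical-shift ingestion.

Parses multi-model PDB files (via gemmi) and NMR-STAR chemical-shift loops
into a light internal data model, normalizes atom naming across the PDB-v2 /
PDB-v3 / BMRB dialects, and perceives covalent bonds from CCD residue
templates with a distance-based fallback.

Atom identifiers are strings of the form ``"A/7.DG/H21"`` (chain / residue
number . residue name / atom name).  They are stable across models of an NMR
ensemble, which is what lets per-model shieldings be averaged atom-by-atom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import networkx as nx
import numpy as np

from .naming import normalize_atom_names
from .templates import (
    COVALENT_RADII,
    ION_RESIDUES,
    NUCLEIC_RESIDUES,
    PROTEIN_RESIDUES,
    WATER_RESIDUES,
    template_bonds,
)

__all__ = [
    "Atom",
    "Model",
    "Structure",
    "ShiftTable",
    "read_structure",
    "perceive_bonds",
    "read_shift_table",
    "atom_id",
]


def atom_id(chain: str, resnum: int, resname: str, name: str) -> str:
    """Canonical atom key, stable across models of an ensemble."""
    return f"{chain}/{resnum}.{resname}/{name}"


@dataclass
class Atom:
    """One atom of one model."""

    atom_id: str
    name: str
    element: str
    coords: np.ndarray  # Å, shape (3,)
    formal_charge: int = 0
    chain: str = "A"
    resnum: int = 1
    resname: str = "UNK"

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def residue_ref(self) -> tuple[str, int, str]:
        return (self.chain, self.resnum, self.resname)


@dataclass
class Model:
    """One conformer: an ordered atom list plus an id index."""

    atoms: list[Atom]
    index: dict[str, Atom] = field(default_factory=dict)

    def __post_init__(self):
        if not self.index:
            self.index = {a.atom_id: a for a in self.atoms}
        if len(self.index) != len(self.atoms):
            seen: set[str] = set()
            for a in self.atoms:
                if a.atom_id in seen:
                    raise ValueError(f"duplicate atom id {a.atom_id!r} within model")
                seen.add(a.atom_id)

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def residues(self) -> list[tuple[str, int, str]]:
        out: list[tuple[str, int, str]] = []
        for a in self.atoms:
            ref = a.residue_ref
            if not out or out[-1] != ref:
                if ref in out:  # non-contiguous residue: keep first position
                    continue
                out.append(ref)
        return out

    def residue_atoms(self, chain: str, resnum: int) -> list[Atom]:
        return [a for a in self.atoms if a.chain == chain and a.resnum == resnum]


@dataclass
class Structure:
    """A (possibly multi-model) structure with per-residue entity classes.

    entity_class maps (chain, resnum) to one of
    ``nucleic | protein | ligand | solvent | ion``.
    """

    models: list[Model]
    entity_class: dict[tuple[str, int], str]
    name: str = ""
    source_text: str | None = None  # original PDB text, if parsed from one

    def __post_init__(self):
        self._check_topology()

    def _check_topology(self) -> None:
        ids0 = [a.atom_id for a in self.models[0].atoms]
        for k, m in enumerate(self.models[1:], start=2):
            ids = [a.atom_id for a in m.atoms]
            if ids != ids0:
                raise ValueError(
                    f"inconsistent topology: model {k} differs from model 1 "
                    f"({len(ids)} vs {len(ids0)} atoms or differing names)"
                )

    @property
    def n_models(self) -> int:
        return len(self.models)

    def class_of(self, a: Atom) -> str:
        return self.entity_class[(a.chain, a.resnum)]


def classify_residue(resname: str, is_het: bool) -> str:
    rn = resname.strip().upper()
    if rn in WATER_RESIDUES:
        return "solvent"
    if rn in ION_RESIDUES:
        return "ion"
    if rn in NUCLEIC_RESIDUES:
        return "nucleic"
    if rn in PROTEIN_RESIDUES:
        return "protein"
    return "ligand"


def read_structure(pdb_text: str, model_selection="all", name: str = "") -> Structure:
    """Parse a (multi-model) PDB string.

    model_selection is "all" or a list of 1-based model indices in file
    order.  Hydrogens must be present on standard residues: hydrogen
    placement is out of scope, so a standard residue with no hydrogens is a
    hard error.  Highest-occupancy alternative conformations are kept.
    """
    st = gemmi.read_pdb_string(pdb_text)
    st.remove_alternative_conformations()
    if len(st) == 0:
        raise ValueError("no models found in PDB input")

    if model_selection == "all":
        chosen = list(range(1, len(st) + 1))
    else:
        chosen = list(model_selection)
        for i in chosen:
            if not 1 <= i <= len(st):
                raise ValueError(f"model index {i} out of range 1..{len(st)}")

    models: list[Model] = []
    entity_class: dict[tuple[str, int], str] = {}
    for midx in chosen:
        gm = st[midx - 1]
        atoms: list[Atom] = []
        for chain in gm:
            for res in chain:
                resname = res.name.strip()
                cls = classify_residue(resname, res.het_flag == "H")
                entity_class.setdefault((chain.name, res.seqid.num), cls)
                for at in res:
                    nm = normalize_atom_names(at.name, resname)
                    atoms.append(
                        Atom(
                            atom_id=atom_id(chain.name, res.seqid.num, resname, nm),
                            name=nm,
                            element=at.element.name,
                            coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                            formal_charge=at.charge,
                            chain=chain.name,
                            resnum=res.seqid.num,
                            resname=resname,
                        )
                    )
        models.append(Model(atoms))

    _require_hydrogens(models[0], entity_class)
    _assign_phosphate_charges(models)
    return Structure(models=models, entity_class=entity_class, name=name, source_text=pdb_text)


def _require_hydrogens(model: Model, entity_class: dict) -> None:
    for chain, resnum, resname in model.residues():
        if entity_class[(chain, resnum)] not in ("nucleic", "protein"):
            continue
        ratoms = model.residue_atoms(chain, resnum)
        if not any(a.is_hydrogen for a in ratoms):
            raise ValueError(
                f"residue {chain}/{resnum} {resname} has no hydrogens; "
                "hydrogen placement is out of scope — add H before import"
            )


def _assign_phosphate_charges(models: list[Model]) -> None:
    """Give deprotonated phosphates their formal charge.

    Each terminal phosphate oxygen beyond the first that carries no proton
    contributes -1; the charge is booked on that oxygen.  Detection is
    name-based (OP1/OP2/OP3 without a matching HOPx in the residue), which
    covers the standard nucleotide templates.
    """
    for model in models:
        by_res: dict[tuple[str, int], list[Atom]] = {}
        for a in model.atoms:
            by_res.setdefault((a.chain, a.resnum), []).append(a)
        for ratoms in by_res.values():
            names = {a.name for a in ratoms}
            if "P" not in names:
                continue
            bare = [
                n for n in ("OP1", "OP2", "OP3")
                if n in names and f"HOP{n[-1]}" not in names and f"H{n}" not in names
            ]
            # one bare terminal O stays as P=O; each further one is anionic
            for n in bare[1:]:
                for a in ratoms:
                    if a.name == n:
                        a.formal_charge = -1


# ---------------------------------------------------------------------------
# Bond perception


def perceive_bonds(model: Model, tolerance: float = 0.45) -> nx.Graph:
    """Build the covalent bond graph of one model.

    Standard residues use CCD templates (bond orders included); consecutive
    residues are linked through O3'-P (nucleic) or C-N (peptide) bonds when
    the geometry supports it.  Atoms the templates do not cover fall back to
    distance-based perception with covalent radii + ``tolerance`` Å.
    """
    g = nx.Graph()
    for a in model.atoms:
        g.add_node(a.atom_id, element=a.element)

    by_res: dict[tuple[str, int, str], list[Atom]] = {}
    order: list[tuple[str, int, str]] = []
    for a in model.atoms:
        key = a.residue_ref
        if key not in by_res:
            by_res[key] = []
            order.append(key)
        by_res[key].append(a)

    for key in order:
        ratoms = by_res[key]
        tmpl = template_bonds(key[2])
        present = {a.name: a for a in ratoms}
        if tmpl is not None:
            for n1, n2, bo in tmpl:
                if n1 in present and n2 in present:
                    g.add_edge(present[n1].atom_id, present[n2].atom_id, order=bo)
        else:
            _distance_bonds(ratoms, g, tolerance)

    # inter-residue links within a chain
    for (k1, k2) in zip(order, order[1:]):
        if k1[0] != k2[0]:
            continue
        a1 = {a.name: a for a in by_res[k1]}
        a2 = {a.name: a for a in by_res[k2]}
        if "O3'" in a1 and "P" in a2:
            if _dist(a1["O3'"], a2["P"]) < 2.2:
                g.add_edge(a1["O3'"].atom_id, a2["P"].atom_id, order=1)
        if "C" in a1 and "N" in a2:
            if _dist(a1["C"], a2["N"]) < 2.0:
                g.add_edge(a1["C"].atom_id, a2["N"].atom_id, order=1)

    # orphans (e.g. terminal HO5' absent from the free-nucleotide template);
    # generous tolerance — it only ever adds a bond to an atom with none
    for a in model.atoms:
        if g.degree(a.atom_id) == 0:
            _attach_orphan(a, model, g, tolerance + 0.4)

    for a in model.atoms:
        if g.degree(a.atom_id) == 0 and a.resname.upper() not in ION_RESIDUES:
            warnings.warn(f"atom {a.atom_id} has no bonds and is not a monoatomic ion")
    return g


def perceive_bonds_distance(model: Model, tolerance: float = 0.45) -> nx.Graph:
    """Pure distance-based perception (used as the template path's oracle)."""
    g = nx.Graph()
    for a in model.atoms:
        g.add_node(a.atom_id, element=a.element)
    _distance_bonds(model.atoms, g, tolerance)
    return g


def _dist(a: Atom, b: Atom) -> float:
    return float(np.linalg.norm(a.coords - b.coords))


def _distance_bonds(atoms: list[Atom], g: nx.Graph, tolerance: float) -> None:
    n = len(atoms)
    coords = np.array([a.coords for a in atoms])
    radii = np.array([COVALENT_RADII.get(a.element, 0.77) for a in atoms])
    for i in range(n):
        d = np.linalg.norm(coords[i + 1:] - coords[i], axis=1)
        cut = radii[i] + radii[i + 1:] + tolerance
        for j in np.nonzero(d <= cut)[0]:
            k = i + 1 + j
            if atoms[i].is_hydrogen and atoms[k].is_hydrogen:
                continue  # H-H pairs are never covalent here
            if d[j] < 0.4:
                continue
            g.add_edge(atoms[i].atom_id, atoms[k].atom_id, order=1)
    # a hydrogen keeps only its nearest heavy neighbor
    by_id = {a.atom_id: a for a in atoms}
    for a in atoms:
        if not a.is_hydrogen:
            continue
        nbrs = list(g.neighbors(a.atom_id))
        if len(nbrs) > 1:
            nbrs.sort(key=lambda nid: _dist(a, by_id[nid]))
            for nid in nbrs[1:]:
                g.remove_edge(a.atom_id, nid)


def _attach_orphan(a: Atom, model: Model, g: nx.Graph, tolerance: float) -> None:
    best, bestd = None, np.inf
    for b in model.atoms:
        if b.atom_id == a.atom_id or (a.is_hydrogen and b.is_hydrogen):
            continue
        d = _dist(a, b)
        cut = COVALENT_RADII.get(a.element, 0.77) + COVALENT_RADII.get(b.element, 0.77) + tolerance
        if d <= cut and d < bestd and d > 0.4:
            best, bestd = b, d
    if best is not None:
        g.add_edge(a.atom_id, best.atom_id, order=1)


# ---------------------------------------------------------------------------
# NMR-STAR chemical shifts


@dataclass
class ShiftTable:
    """Experimental shifts keyed by (chain, resnum, resname, atom name)."""

    entries: dict[tuple[str, int, str, str], float]
    nucleus: str = "1H"
    source: str = ""
    unmatched: list[tuple[str, int, str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, chain: str, resnum: int, resname: str, name: str):
        return self.entries.get((chain, resnum, resname, name))

    def match_structure(self, structure: Structure) -> tuple[int, int]:
        """Count (matched, unmatched) entries against model-1 atoms."""
        ids = {a.atom_id for a in structure.models[0].atoms}
        self.unmatched = []
        matched = 0
        for (chain, resnum, resname, name) in self.entries:
            if atom_id(chain, resnum, resname, name) in ids:
                matched += 1
            else:
                self.unmatched.append((chain, resnum, resname, name))
        return matched, len(self.unmatched)


_V3_TAGS = {
    "seq": ("Comp_index_ID", "Seq_ID"),
    "comp": ("Comp_ID",),
    "atom": ("Atom_ID",),
    "type": ("Atom_type",),
    "val": ("Val",),
    "chain": ("Auth_asym_ID", "Entity_assembly_ID"),
}
_V2_TAGS = {
    "seq": ("Residue_seq_code",),
    "comp": ("Residue_label",),
    "atom": ("Atom_name",),
    "type": ("Atom_type",),
    "val": ("Chem_shift_value",),
    "chain": ("Mol_system_component_name",),
}


def _star_loops(text: str):
    """Yield (tags, rows) for every loop in a STAR/NMR-STAR file."""
    tokens: list[str] = []
    for line in text.splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        i = 0
        while i < len(s):
            if s[i] in "'\"":
                q = s[i]
                j = s.index(q, i + 1)
                tokens.append(s[i + 1:j])
                i = j + 1
            elif s[i].isspace():
                i += 1
            else:
                j = i
                while j < len(s) and not s[j].isspace():
                    j += 1
                tokens.append(s[i:j])
                i = j
    i = 0
    while i < len(tokens):
        if tokens[i].lower() != "loop_":
            i += 1
            continue
        i += 1
        tags = []
        while i < len(tokens) and tokens[i].startswith("_"):
            tags.append(tokens[i])
            i += 1
        values = []
        while i < len(tokens) and tokens[i].lower() not in ("stop_", "loop_") \
                and not tokens[i].startswith("_") \
                and not tokens[i].lower().startswith(("save_", "data_")):
            values.append(tokens[i])
            i += 1
        if tags and len(values) % len(tags) == 0:
            rows = [values[k:k + len(tags)] for k in range(0, len(values), len(tags))]
            yield tags, rows


def _pick(tags: list[str], names: tuple[str, ...]):
    short = [t.split(".")[-1].lstrip("_") for t in tags]
    for want in names:
        for k, s in enumerate(short):
            if s == want:
                return k
    return None


def read_shift_table(
    star_text: str,
    entity_filter=None,
    nucleus: str = "1H",
    default_chain: str = "A",
    source: str = "",
) -> ShiftTable:
    """Read a chemical-shift loop from NMR-STAR v2 or v3 text.

    entity_filter, if given, is a callable (chain, resnum, resname, atom
    name) -> bool applied after name normalization.  Ambiguous duplicate
    keys are an error; entries are never silently dropped.
    """
    want_element = "".join(c for c in nucleus if c.isalpha()) or "H"
    entries: dict[tuple[str, int, str, str], float] = {}
    found_loop = False
    for tags, rows in _star_loops(star_text):
        for tagmap in (_V3_TAGS, _V2_TAGS):
            cols = {k: _pick(tags, names) for k, names in tagmap.items()}
            if cols["val"] is not None and cols["atom"] is not None:
                break
        if cols["val"] is None or cols["atom"] is None:
            continue
        found_loop = True
        dupes = []
        for row in rows:
            el = row[cols["type"]] if cols["type"] is not None else "H"
            if el.upper() != want_element.upper():
                continue
            resnum = int(row[cols["seq"]]) if cols["seq"] is not None else 0
            resname = row[cols["comp"]].upper() if cols["comp"] is not None else "UNK"
            chain = row[cols["chain"]] if cols["chain"] is not None else default_chain
            if chain in (".", "?", ""):
                chain = default_chain
            if chain.isdigit():  # Entity_assembly_ID 1,2,... -> A,B,...
                chain = chr(ord("A") + int(chain) - 1)
            name = normalize_atom_names(row[cols["atom"]], resname)
            val = float(row[cols["val"]])
            if not np.isfinite(val):
                raise ValueError(f"non-finite shift for {chain}/{resnum}/{name}")
            key = (chain, resnum, resname, name)
            if entity_filter is not None and not entity_filter(*key):
                continue
            if key in entries and entries[key] != val:
                dupes.append(key)
            entries[key] = val
        if dupes:
            raise ValueError(f"ambiguous duplicate shift keys: {sorted(set(dupes))}")
    if not found_loop:
        raise ValueError("no chemical-shift loop found in STAR input")
    return ShiftTable(entries=entries, nucleus=nucleus, source=source)
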