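"""Partitioning a structure into mutually exclusive fragments.

The scheme cuts each nucleotide at the glycosidic bond into a nucleobase
fragment (base ring, exocyclic substituents, the glycosidic nitrogen) and a
sugar+phosphate fragment (sugar including C1'/H1' plus the residue's own
5'-phosphate).  Amino acids split into backbone and side chain; ligands
split into fused-ring systems and aliphatic substituent arms, with
single-heavy-atom substituents merged into the adjacent ring.  The union of
fragments covers every non-solvent, non-ion atom exactly once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx

from .structure import Atom, Model, Structure

__all__ = [
    "Fragment",
    "Partition",
    "partition_nucleic",
    "partition_protein",
    "partition_ligand",
    "partition_system",
]

FRAGMENT_KINDS = ("nucleobase", "sugar_phosphate", "aa_backbone", "aa_sidechain", "ligand_group")

_BACKBONE_NAMES = {
    "N", "H", "H1", "H2", "H3", "CA", "HA", "HA2", "HA3",
    "C", "O", "OXT", "HXT", "OC1", "OC2",
}

_GLYCOSIDIC_N = ("N9", "N1")


@dataclass(frozen=True)
class Fragment:
    fragment_id: str
    kind: str
    atom_ids: frozenset[str]
    anchor_residue: tuple[str, int]

    def __post_init__(self):
        if self.kind not in FRAGMENT_KINDS:
            raise ValueError(f"unknown fragment kind {self.kind!r}")
        if not self.atom_ids:
            raise ValueError(f"fragment {self.fragment_id} is empty")


@dataclass
class Partition:
    fragments: list[Fragment]
    atom_to_fragment: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.atom_to_fragment:
            for f in self.fragments:
                for aid in f.atom_ids:
                    if aid in self.atom_to_fragment:
                        raise ValueError(
                            f"atom {aid} in fragments {self.atom_to_fragment[aid]} "
                            f"and {f.fragment_id}"
                        )
                    self.atom_to_fragment[aid] = f.fragment_id

    def __len__(self) -> int:
        return len(self.fragments)

    def by_id(self, fragment_id: str) -> Fragment:
        for f in self.fragments:
            if f.fragment_id == fragment_id:
                return f
        raise KeyError(fragment_id)

    def validate(self, model: Model, excluded: set[str]) -> None:
        """Assert mutual exclusivity and exhaustiveness over included atoms."""
        covered = set(self.atom_to_fragment)
        expected = {a.atom_id for a in model.atoms} - excluded
        missing = expected - covered
        extra = covered - expected
        if missing or extra:
            raise ValueError(
                f"partition not exhaustive/exclusive: missing={sorted(missing)[:5]} "
                f"extra={sorted(extra)[:5]}"
            )


def _residue_groups(model: Model):
    by_res: dict[tuple[str, int, str], list[Atom]] = {}
    order = []
    for a in model.atoms:
        key = a.residue_ref
        if key not in by_res:
            by_res[key] = []
            order.append(key)
        by_res[key].append(a)
    return order, by_res


def partition_nucleic(model: Model, graph: nx.Graph, residues=None) -> list[Fragment]:
    """Two fragments per nucleotide: nucleobase and sugar(+phosphate).

    The glycosidic N stays with the base, C1'/H1' with the sugar; a 5'
    terminus without phosphate still yields one sugar_phosphate fragment.
    Residues where no glycosidic bond is found become a single fragment.
    """
    order, by_res = _residue_groups(model)
    if residues is not None:
        order = [k for k in order if (k[0], k[1]) in residues]
    out: list[Fragment] = []
    for chain, resnum, resname in order:
        ratoms = by_res[(chain, resnum, resname)]
        ids = {a.atom_id for a in ratoms}
        names = {a.atom_id: a.name for a in ratoms}
        gly = None
        for aid in ids:
            if names[aid] == "C1'":
                for nb in graph.neighbors(aid):
                    if nb in ids and names[nb] in _GLYCOSIDIC_N:
                        gly = (aid, nb)
        anchor = (chain, resnum)
        if gly is None:
            warnings.warn(
                f"no glycosidic bond in {chain}/{resnum} {resname}; kept as one fragment"
            )
            out.append(Fragment(f"{chain}.{resnum}.ligand_group", "ligand_group",
                                frozenset(ids), anchor))
            continue
        sub = graph.subgraph(ids).copy()
        sub.remove_edge(*gly)
        comps = list(nx.connected_components(sub))
        base = next(c for c in comps if gly[1] in c)
        rest = ids - base
        out.append(Fragment(f"{chain}.{resnum}.nucleobase", "nucleobase",
                            frozenset(base), anchor))
        out.append(Fragment(f"{chain}.{resnum}.sugar_phosphate", "sugar_phosphate",
                            frozenset(rest), anchor))
    return out


def partition_protein(model: Model, graph: nx.Graph, residues=None) -> list[Fragment]:
    """Backbone and side-chain fragments per amino acid; glycine has no side chain."""
    order, by_res = _residue_groups(model)
    if residues is not None:
        order = [k for k in order if (k[0], k[1]) in residues]
    out: list[Fragment] = []
    for chain, resnum, resname in order:
        ratoms = by_res[(chain, resnum, resname)]
        bb = {a.atom_id for a in ratoms if a.name in _BACKBONE_NAMES}
        sc = {a.atom_id for a in ratoms} - bb
        anchor = (chain, resnum)
        if bb:
            out.append(Fragment(f"{chain}.{resnum}.aa_backbone", "aa_backbone",
                                frozenset(bb), anchor))
        if sc:
            out.append(Fragment(f"{chain}.{resnum}.aa_sidechain", "aa_sidechain",
                                frozenset(sc), anchor))
    return out


def partition_ligand(model: Model, graph: nx.Graph, residues=None) -> list[Fragment]:
    """Ring systems plus aliphatic substituent arms.

    Fused rings sharing atoms merge; an acyclic branch with >= 2 heavy atoms
    is its own fragment; a single-heavy-atom substituent joins the ring it
    hangs off.  Hydrogens follow their heavy atom.
    """
    order, by_res = _residue_groups(model)
    if residues is not None:
        order = [k for k in order if (k[0], k[1]) in residues]
    out: list[Fragment] = []
    elements = {a.atom_id: a.element for m in [model] for a in m.atoms}
    for chain, resnum, resname in order:
        ratoms = by_res[(chain, resnum, resname)]
        ids = {a.atom_id for a in ratoms}
        heavy = {aid for aid in ids if elements[aid] != "H"}
        hsub = graph.subgraph(heavy)
        ring_atoms: set[str] = set()
        for cyc in nx.cycle_basis(nx.Graph(hsub)):
            ring_atoms.update(cyc)
        anchor = (chain, resnum)

        groups: list[set[str]] = []
        if ring_atoms:
            ring_systems = [set(c) for c in nx.connected_components(hsub.subgraph(ring_atoms))]
            branch_comps = [set(c) for c in
                            nx.connected_components(hsub.subgraph(heavy - ring_atoms))]
            for br in branch_comps:
                if len(br) >= 2:
                    groups.append(br)
                else:
                    host = _adjacent_ring(br, ring_systems, hsub)
                    host.update(br)
            groups = ring_systems + groups
        else:
            groups = [set(c) for c in nx.connected_components(hsub)]
            if not groups:  # hydrogens only (unlikely); one fragment
                groups = [set()]

        # hydrogens travel with their heavy atom
        for aid in ids - heavy:
            nbrs = [nb for nb in graph.neighbors(aid) if nb in heavy]
            target = None
            if nbrs:
                target = next((grp for grp in groups if nbrs[0] in grp), None)
            if target is None:
                target = groups[0]
            target.add(aid)

        for k, grp in enumerate(g for g in groups if g):
            out.append(Fragment(f"{chain}.{resnum}.ligand_group.{k}", "ligand_group",
                                frozenset(grp), anchor))
    return out


def _adjacent_ring(branch: set[str], ring_systems: list[set[str]], hsub: nx.Graph) -> set[str]:
    for aid in branch:
        for nb in hsub.neighbors(aid):
            for rs in ring_systems:
                if nb in rs:
                    return rs
    return ring_systems[0]


def partition_system(structure: Structure, graph: nx.Graph,
                     model_index: int = 0, include_solvent: bool = False) -> Partition:
    """Concatenate per-entity partitions and validate coverage.

    Solvent and monoatomic ions are excluded (they enter neither the QM
    region nor, by default, the point charges); include_solvent keeps them
    as ligand_group fragments instead.
    """
    model = structure.models[model_index]
    nuc, prot, lig = set(), set(), set()
    excluded: set[str] = set()
    for a in model.atoms:
        cls = structure.entity_class[(a.chain, a.resnum)]
        if cls == "nucleic":
            nuc.add((a.chain, a.resnum))
        elif cls == "protein":
            prot.add((a.chain, a.resnum))
        elif cls == "ligand":
            lig.add((a.chain, a.resnum))
        elif include_solvent:
            lig.add((a.chain, a.resnum))
        else:
            excluded.add(a.atom_id)
    fragments = (
        partition_nucleic(model, graph, residues=nuc)
        + partition_protein(model, graph, residues=prot)
        + partition_ligand(model, graph, residues=lig)
    )
    part = Partition(fragments)
    part.validate(model, excluded)
    return part


def partition_to_tsv(partition: Partition) -> str:
    """Audit dump: fragment_id, kind, chain, residue, atom names."""
    lines = ["fragment_id\tkind\tchain\tresidue\tatoms"]
    for f in partition.fragments:
        names = ",".join(sorted(aid.rsplit("/", 1)[1] for aid in f.atom_ids))
        lines.append(f"{f.fragment_id}\t{f.kind}\t{f.anchor_residue[0]}\t"
                     f"{f.anchor_residue[1]}\t{names}")
    return "\n".join(lines) + "\n"
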