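"""Parent-molecule assembly: central fragment + surroundings + caps.

A fragment's parent molecule is the QM region of its shielding job: every
fragment with at least one atom (hydrogens included) within the cutoff of
the central fragment is added completely, and each covalent bond severed at
the resulting boundary is saturated by a cap — a single hydrogen placed
along the broken-bond direction, or an O-H group when a phosphate loses a
bridging oxygen.  Cap geometry uses fixed standard bond lengths; nothing is
optimized, so parents are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .fragmentation import Partition
from .structure import Atom, Model

__all__ = ["CapAtom", "ParentMolecule", "select_surroundings", "cap_broken_bond", "build_parent"]

# cap X-H bond lengths by host element, Å
H_CAP_LENGTH = {"C": 1.09, "N": 1.01, "O": 0.96}
P_O_CAP_LENGTH = 1.60
O_H_CAP_LENGTH = 0.96
CAP_CLASH_QM = 0.8   # Å, cap vs existing QM atom
CAP_CLASH_CAP = 0.5  # Å, cap vs cap


@dataclass(frozen=True)
class CapAtom:
    element: str            # "H" or "O" (an O cap carries its own H cap record)
    coords: np.ndarray      # Å
    host_atom: str          # atom id whose broken bond this saturates
    replaced_atom: str      # atom id of the removed neighbor


@dataclass
class ParentMolecule:
    central_fragment: str
    surrounding_fragments: frozenset[str]
    qm_atoms: list[Atom]           # central + surroundings, structure atoms
    caps: list[CapAtom]
    net_charge: int
    multiplicity: int = 1
    cutoff_used: float = 5.0
    central_atom_ids: frozenset[str] = field(default_factory=frozenset)

    @property
    def n_caps(self) -> int:
        """Number of capped broken bonds (an O-H cap counts once)."""
        return len({(c.host_atom, c.replaced_atom) for c in self.caps})

    @property
    def n_cap_atoms(self) -> int:
        return len(self.caps)

    @property
    def qm_atom_ids(self) -> frozenset[str]:
        return frozenset(a.atom_id for a in self.qm_atoms)

    def all_coords(self) -> np.ndarray:
        real = [a.coords for a in self.qm_atoms]
        return np.array(real + [c.coords for c in self.caps], dtype=float)

    def to_xyz(self) -> str:
        """Parent geometry as an XYZ block for inspection."""
        n = len(self.qm_atoms) + len(self.caps)
        lines = [str(n), f"parent {self.central_fragment} cutoff={self.cutoff_used}"]
        for a in self.qm_atoms:
            x, y, z = a.coords
            lines.append(f"{a.element:2s} {x:12.6f} {y:12.6f} {z:12.6f}")
        for c in self.caps:
            x, y, z = c.coords
            lines.append(f"{c.element:2s} {x:12.6f} {y:12.6f} {z:12.6f}")
        return "\n".join(lines) + "\n"


def select_surroundings(model: Model, partition: Partition, central_id: str,
                        cutoff: float) -> frozenset[str]:
    """Fragments with any atom within ``cutoff`` Å of the central fragment.

    The comparison is inclusive and involves all atoms, hydrogens included;
    the relation is symmetric and monotone in the cutoff by construction.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    central = partition.by_id(central_id)  # KeyError for unknown id
    by_id = {a.atom_id: a for a in model.atoms}
    ccoords = np.array([by_id[aid].coords for aid in central.atom_ids])
    tree = cKDTree(ccoords)
    out = set()
    for f in partition.fragments:
        if f.fragment_id == central_id:
            continue
        pts = np.array([by_id[aid].coords for aid in f.atom_ids])
        d, _ = tree.query(pts, k=1)
        if float(np.min(d)) <= cutoff:
            out.add(f.fragment_id)
    return frozenset(out)


def cap_broken_bond(host: Atom, replaced: Atom, graph: nx.Graph) -> list[CapAtom]:
    """Caps saturating one severed bond; host stays in the QM region.

    P losing a bridging O gets an O-H cap (P-O 1.60 Å, O-H 0.96 Å,
    staggered); any other host gets a single H along host->replaced at the
    host element's standard X-H length.
    """
    if not graph.has_edge(host.atom_id, replaced.atom_id):
        raise ValueError(f"{host.atom_id} and {replaced.atom_id} are not bonded")
    direction = replaced.coords - host.coords
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("coincident host/replaced atoms")
    u = direction / norm

    if host.element == "P" and replaced.element == "O":
        o_pos = host.coords + P_O_CAP_LENGTH * u
        h_pos = o_pos + O_H_CAP_LENGTH * _staggered(u)
        return [
            CapAtom("O", o_pos, host.atom_id, replaced.atom_id),
            CapAtom("H", h_pos, host.atom_id, replaced.atom_id),
        ]
    if host.element not in H_CAP_LENGTH:
        raise ValueError(f"no cap rule for host element {host.element!r} ({host.atom_id})")
    h_pos = host.coords + H_CAP_LENGTH[host.element] * u
    return [CapAtom("H", h_pos, host.atom_id, replaced.atom_id)]


def _staggered(u: np.ndarray) -> np.ndarray:
    """Unit vector at ~109.5 deg from u, deterministic tie-break on the frame."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    perp = ref - np.dot(ref, u) * u
    perp /= np.linalg.norm(perp)
    ang = np.deg2rad(109.5)
    return np.cos(ang) * u + np.sin(ang) * perp


def build_parent(model: Model, partition: Partition, graph: nx.Graph,
                 central_id: str, cutoff: float = 5.0) -> ParentMolecule:
    """Assemble the QM region for one central fragment.

    qm_atoms keep structure order (central block first, then surroundings);
    every graph edge crossing the QM boundary is capped exactly once; the
    net charge is the sum of formal charges of the real QM atoms.
    """
    central = partition.by_id(central_id)
    surrounding = select_surroundings(model, partition, central_id, cutoff)
    qm_ids = set(central.atom_ids)
    for fid in surrounding:
        qm_ids |= partition.by_id(fid).atom_ids

    order = {a.atom_id: i for i, a in enumerate(model.atoms)}
    by_id = {a.atom_id: a for a in model.atoms}
    qm_atoms = [by_id[aid] for aid in sorted(
        qm_ids, key=lambda i: (i not in central.atom_ids, order[i]))]

    caps: list[CapAtom] = []
    for aid in sorted(qm_ids, key=order.get):
        for nb in sorted(graph.neighbors(aid), key=order.get):
            if nb not in qm_ids and nb in partition.atom_to_fragment:
                caps.extend(cap_broken_bond(by_id[aid], by_id[nb], graph))

    _check_clashes(qm_atoms, caps)
    net_charge = int(sum(by_id[aid].formal_charge for aid in qm_ids))
    return ParentMolecule(
        central_fragment=central_id,
        surrounding_fragments=surrounding,
        qm_atoms=qm_atoms,
        caps=caps,
        net_charge=net_charge,
        multiplicity=1,
        cutoff_used=cutoff,
        central_atom_ids=frozenset(central.atom_ids),
    )


def _check_clashes(qm_atoms: list[Atom], caps: list[CapAtom]) -> None:
    if not caps:
        return
    cap_xyz = np.array([c.coords for c in caps])
    qm_xyz = np.array([a.coords for a in qm_atoms])
    for k, cap in enumerate(caps):
        d = np.linalg.norm(qm_xyz - cap_xyz[k], axis=1)
        host_idx = [i for i, a in enumerate(qm_atoms) if a.atom_id == cap.host_atom]
        d[host_idx] = np.inf
        # the O of an O-H cap is this H cap's own host-side partner
        if np.min(d) < CAP_CLASH_QM and not (
            cap.element == "H"
            and any(c.element == "O" and c.host_atom == cap.host_atom for c in caps)
        ):
            i = int(np.argmin(d))
            raise ValueError(
                f"cap for bond {cap.host_atom}->{cap.replaced_atom} clashes with "
                f"QM atom {qm_atoms[i].atom_id} at {d[i]:.2f} Å"
            )
    if len(caps) > 1:
        same_group = lambda a, b: a.host_atom == b.host_atom and a.replaced_atom == b.replaced_atom
        for i in range(len(caps)):
            for j in range(i + 1, len(caps)):
                if same_group(caps[i], caps[j]):
                    continue
                if np.linalg.norm(cap_xyz[i] - cap_xyz[j]) < CAP_CLASH_CAP:
                    raise ValueError(
                        f"cap clash between bonds {caps[i].host_atom}->{caps[i].replaced_atom} "
                        f"and {caps[j].host_atom}->{caps[j].replaced_atom}"
                    )


def parent_manifest(parents: list[ParentMolecule]) -> list[dict]:
    """JSON-ready manifest: one record per parent molecule."""
    return [
        {
            "central": p.central_fragment,
            "surroundings": sorted(p.surrounding_fragments),
            "n_qm_atoms": len(p.qm_atoms),
            "n_caps": p.n_caps,
            "net_charge": p.net_charge,
            "cutoff": p.cutoff_used,
        }
        for p in parents
    ]
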