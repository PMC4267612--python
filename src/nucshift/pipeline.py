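"""End-to-end orchestration: structure -> fragments -> parents -> shieldings.

This is the glue the CLI and the fixtures use: perceive bonds, partition,
build one parent molecule per fragment, compute the PEOE embedding charges
once per model, and run every shielding job through the chosen backend,
keeping only central-fragment records.  Each step remains individually
accessible for callers that need intermediates.
"""

from __future__ import annotations

from .charges import gasteiger_charges, remainder_point_charges
from .fragmentation import Partition, partition_system
from .parents import ParentMolecule, build_parent
from .qm import QMJobSpec, run_batch
from .structure import Structure, perceive_bonds

__all__ = ["build_all_parents", "make_job_specs", "predict_shieldings"]


def build_all_parents(structure: Structure, cutoff: float = 5.0,
                      model_index: int = 0):
    """Bonds, partition and one parent per fragment for one model."""
    model = structure.models[model_index]
    graph = perceive_bonds(model)
    partition = partition_system(structure, graph, model_index=model_index)
    parents = [build_parent(model, partition, graph, f.fragment_id, cutoff)
               for f in partition.fragments]
    return graph, partition, parents


def make_job_specs(structure: Structure, parents: list[ParentMolecule],
                   graph, partition: Partition, model_index: int = 0,
                   method: str = "mPW1PW91", basis: str = "6-311G(d)",
                   solvent_model: str | None = "IEFPCM/water",
                   tag: str = "m1") -> list[QMJobSpec]:
    """One GIAO job per parent with its remainder as point charges."""
    model = structure.models[model_index]
    charges = gasteiger_charges(graph, formal_charges={
        a.atom_id: a.formal_charge for a in model.atoms if a.formal_charge})
    included = set(partition.atom_to_fragment)
    specs = []
    for k, parent in enumerate(parents):
        pcs = remainder_point_charges(model, parent, charges, include=included)
        specs.append(QMJobSpec(parent=parent, point_charges=pcs,
                               method=method, basis=basis,
                               solvent_model=solvent_model,
                               job_id=f"{tag}-{k:04d}-{parent.central_fragment}"))
    return specs


def predict_shieldings(structure: Structure, cutoff: float = 5.0,
                       model_index: int = 0, backend: str = "mock",
                       seed: int = 0, noise: float = 0.0,
                       logs: dict[str, str] | None = None) -> dict[str, float]:
    """Central-fragment isotropic shieldings for one model, by atom id."""
    graph, partition, parents = build_all_parents(structure, cutoff, model_index)
    specs = make_job_specs(structure, parents, graph, partition,
                           model_index=model_index, tag=f"m{model_index + 1}")
    collected, report = run_batch(specs, backend=backend, seed=seed,
                                  noise=noise, logs=logs)
    failed = [r.job_id for r in report if not r.ok]
    if failed and not collected:
        raise RuntimeError(f"all {len(failed)} shielding jobs failed")
    return collected
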