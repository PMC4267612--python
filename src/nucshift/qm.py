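"""QM job generation and shielding extraction.

Jobs request GIAO isotropic shieldings (default mPW1PW91/6-311G(d) with
IEF-PCM water) for a parent molecule with its remainder embedded as point
charges.  The deck dialect is Gaussian-style — route line, title, charge /
multiplicity, Cartesian block, trailing point-charge block — and is written
byte-stably so goldens can be diffed.  A deterministic mock backend stands
in for the electronic-structure engine in tests and demos: it produces a
smooth, geometry-dependent surrogate shielding, not physics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .charges import PointChargeSet
from .parents import ParentMolecule
from .templates import ATOMIC_NUMBERS

__all__ = [
    "QMJobSpec", "ShieldingRecord",
    "write_qm_input", "parse_shieldings", "mock_backend", "mock_log_text", "run_batch",
]

# surrogate baseline shieldings per element, ppm (mock backend only)
MOCK_SIGMA0 = {"H": 31.0, "C": 185.0, "N": 255.0, "O": 330.0, "P": 360.0, "S": 400.0}
MOCK_C1 = 0.05  # ppm Å^2, neighbor-deshielding coupling
MOCK_C2 = 1.0   # ppm Å, point-charge coupling


@dataclass
class QMJobSpec:
    parent: ParentMolecule
    point_charges: PointChargeSet
    method: str = "mPW1PW91"
    basis: str = "6-311G(d)"
    solvent_model: str | None = "IEFPCM/water"
    job_id: str = "job"

    def __post_init__(self):
        if not self.method or not self.basis:
            raise ValueError("method and basis must be non-empty")


@dataclass
class ShieldingRecord:
    index: int                 # job-local 0-based atom index
    atom_id: str | None        # structure atom id; None for caps
    element: str
    sigma: float               # isotropic shielding, ppm
    is_cap: bool = False
    in_central: bool = False


@dataclass
class JobResult:
    job_id: str
    ok: bool
    records: list[ShieldingRecord] = field(default_factory=list)
    message: str = ""


def write_qm_input(spec: QMJobSpec) -> str:
    """Render the input deck; identical specs give identical bytes."""
    route = f"#P {spec.method}/{spec.basis} NMR=GIAO NoSymm"
    if spec.solvent_model:
        scrf = spec.solvent_model.split("/")
        solvent = scrf[1] if len(scrf) > 1 else "water"
        route += f" SCRF=({scrf[0]},Solvent={solvent})"
    if len(spec.point_charges) > 0:
        route += " Charge"
    lines = [f"%chk={spec.job_id}.chk", route, "",
             f"{spec.job_id} GIAO shielding", "",
             f"{spec.parent.net_charge} {spec.parent.multiplicity}"]
    for a in spec.parent.qm_atoms:
        x, y, z = a.coords
        lines.append(f"{a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    for c in spec.parent.caps:
        x, y, z = c.coords
        lines.append(f"{c.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}")
    lines.append("")
    if len(spec.point_charges) > 0:
        for (x, y, z), q in zip(spec.point_charges.coords, spec.point_charges.charges):
            lines.append(f"{x:14.6f} {y:14.6f} {z:14.6f} {q:12.6f}")
        lines.append("")
    return "\n".join(lines) + "\n"


_ISO_RE = re.compile(r"^\s*(\d+)\s+([A-Za-z]{1,2})\s+Isotropic\s*=\s*(-?\d+\.\d+)", re.M)


def parse_shieldings(log_text: str, spec: QMJobSpec) -> list[ShieldingRecord]:
    """Extract isotropic shieldings from an engine log.

    Atoms are mapped back to structure ids by input order (real atoms first,
    then caps).  An atom-count mismatch is a hard error; a log without a
    normal-termination mark raises so failed jobs are never silently used.
    """
    matches = _ISO_RE.findall(log_text)
    n_expected = len(spec.parent.qm_atoms) + spec.parent.n_cap_atoms
    if "Normal termination" not in log_text:
        raise RuntimeError(f"job {spec.job_id}: abnormal termination")
    if len(matches) != n_expected:
        raise ValueError(
            f"job {spec.job_id}: log has {len(matches)} shieldings, expected {n_expected}"
        )
    records = []
    central = spec.parent.central_atom_ids
    for k, (idx, el, val) in enumerate(matches):
        if k < len(spec.parent.qm_atoms):
            a = spec.parent.qm_atoms[k]
            if el.capitalize() != a.element.capitalize():
                raise ValueError(
                    f"job {spec.job_id}: element mismatch at atom {k + 1}: "
                    f"log {el} vs spec {a.element}"
                )
            records.append(ShieldingRecord(k, a.atom_id, a.element, float(val),
                                           is_cap=False,
                                           in_central=a.atom_id in central))
        else:
            c = spec.parent.caps[k - len(spec.parent.qm_atoms)]
            records.append(ShieldingRecord(k, None, c.element, float(val), is_cap=True))
    return records


def mock_backend(spec: QMJobSpec, seed: int = 0, noise: float = 0.0) -> list[ShieldingRecord]:
    """Deterministic surrogate shieldings.

    sigma_i = sigma0(el_i) - c1 * sum_j Z_j / d_ij^2  - c2 * sum_k q_k / d_ik
    over QM neighbors j and point charges k; optional seeded Gaussian noise.
    Same spec + seed -> identical records.
    """
    atoms = list(spec.parent.qm_atoms)
    elements = [a.element for a in atoms] + [c.element for c in spec.parent.caps]
    xyz = spec.parent.all_coords()
    z = np.array([ATOMIC_NUMBERS.get(e.capitalize(), 6) for e in elements], dtype=float)
    n = len(elements)
    sigmas = np.empty(n)
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    sigmas = np.array([MOCK_SIGMA0.get(e.capitalize(), 200.0) for e in elements])
    sigmas = sigmas - MOCK_C1 * (z[None, :] / d ** 2).sum(axis=1)
    if len(spec.point_charges) > 0:
        dq = np.linalg.norm(xyz[:, None, :] - spec.point_charges.coords[None, :, :], axis=2)
        sigmas = sigmas - MOCK_C2 * (spec.point_charges.charges[None, :] / dq).sum(axis=1)
    if noise > 0:
        rng = np.random.default_rng(seed)
        sigmas = sigmas + rng.normal(0.0, noise, size=n)
    central = spec.parent.central_atom_ids
    out = []
    for k in range(n):
        if k < len(atoms):
            a = atoms[k]
            out.append(ShieldingRecord(k, a.atom_id, a.element, float(sigmas[k]),
                                       in_central=a.atom_id in central))
        else:
            c = spec.parent.caps[k - len(atoms)]
            out.append(ShieldingRecord(k, None, c.element, float(sigmas[k]), is_cap=True))
    return out


def mock_log_text(spec: QMJobSpec, seed: int = 0, noise: float = 0.0,
                  truncate: bool = False) -> str:
    """Engine-log-shaped text for the mock backend (parser round trips)."""
    records = mock_backend(spec, seed=seed, noise=noise)
    lines = [f" Entering Gaussian-style mock for {spec.job_id}",
             " SCF Done.", " Magnetic shielding tensor (ppm):"]
    for r in records:
        lines.append(f"  {r.index + 1:4d}  {r.element:<2s}  Isotropic = {r.sigma:12.4f}"
                     f"   Anisotropy = {0.0:12.4f}")
    if truncate:
        lines = lines[: 3 + max(1, len(records) // 2)]
    else:
        lines.append(" Normal termination of mock backend.")
    return "\n".join(lines) + "\n"


def central_shieldings(records: list[ShieldingRecord]) -> dict[str, float]:
    """Keep only central-fragment, non-cap records (the prediction payload)."""
    return {r.atom_id: r.sigma for r in records if r.in_central and not r.is_cap}


def run_batch(specs: list[QMJobSpec], backend="mock", seed: int = 0,
              noise: float = 0.0, logs: dict[str, str] | None = None,
              parallelism: int = 1) -> tuple[dict[str, float], list[JobResult]]:
    """Run all jobs; collect central-fragment shieldings plus a status report.

    backend "mock" evaluates the surrogate; backend "logs" parses
    pre-computed engine logs passed as {job_id: text}.  Failures are
    isolated per job: the batch completes and the report says what failed.
    """
    if backend == "logs" and logs is None:
        raise ValueError("backend 'logs' needs a logs mapping before starting")
    if backend not in ("mock", "logs"):
        raise ValueError(f"unknown backend {backend!r}")
    ids = [s.job_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError("job_id values must be unique per run")
    collected: dict[str, float] = {}
    report: list[JobResult] = []
    for k, spec in enumerate(specs):
        try:
            if backend == "mock":
                # per-job seed offset keeps noise independent across jobs
                records = mock_backend(spec, seed=seed + k, noise=noise)
            else:
                if spec.job_id not in logs:
                    raise FileNotFoundError(f"no log for job {spec.job_id}")
                records = parse_shieldings(logs[spec.job_id], spec)
            collected.update(central_shieldings(records))
            report.append(JobResult(spec.job_id, True, records))
        except Exception as exc:  # fault isolation: one bad log never kills a batch
            report.append(JobResult(spec.job_id, False, [], str(exc)))
    return collected, report
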