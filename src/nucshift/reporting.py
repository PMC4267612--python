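"""Presentation artifacts: error-mapped PDB files and run summaries.

The spatial error map writes |delta_calc - delta_exp| into the B-factor
column of the input PDB so any molecular viewer can color the structure by
prediction error; atoms without an experimental shift carry the sentinel
-1.00.  Everything outside the B-factor field stays byte-identical to the
input text.
"""

from __future__ import annotations

import io
import json

import pandas as pd

from .analysis import StatsReport
from .naming import normalize_atom_names
from .structure import atom_id

__all__ = ["write_error_pdb", "write_summary", "report_to_frame"]

SENTINEL = -1.00
CLIP = 99.99
SCHEMA_VERSION = 1


def write_error_pdb(pdb_text: str, error_map: dict[str, float],
                    model_index: int = 1) -> str:
    """Rewrite a PDB's B-factor column with absolute shift errors.

    error_map keys are atom ids; values are |error| in ppm, clipped at
    99.99.  Only ATOM/HETATM records of the selected model (1-based; a file
    without MODEL cards counts as model 1) are touched, and only columns
    61-66.
    """
    out = []
    current_model = 1
    seen_model_card = False
    for line in pdb_text.splitlines(keepends=True):
        rec = line[:6]
        if rec == "MODEL ":
            current_model = int(line.split()[1])
            seen_model_card = True
        if rec in ("ATOM  ", "HETATM") and current_model == model_index:
            chain = line[21].strip() or "A"
            resnum = int(line[22:26])
            resname = line[17:20].strip()
            name = normalize_atom_names(line[12:16].strip(), resname)
            aid = atom_id(chain, resnum, resname, name)
            if aid in error_map:
                b = min(abs(float(error_map[aid])), CLIP)
            else:
                b = SENTINEL
            line = line[:60] + f"{b:6.2f}" + line[66:]
        out.append(line)
    return "".join(out)


def report_to_frame(report: StatsReport) -> pd.DataFrame:
    """Per-atom table: chain, residue, atom, delta_exp, sigma_calc,
    delta_calc, signed error, model."""
    rows = []
    for p in report.pairs:
        chain, resnum, resname, name = p.key
        rows.append({
            "chain": chain, "resnum": resnum, "resname": resname, "atom": name,
            "delta_exp": p.delta_exp, "sigma_calc": p.sigma_calc,
            "delta_calc": report.delta_calc[p.atom_id],
            "error": report.errors[p.atom_id],
            "model": p.model,
        })
    return pd.DataFrame(rows)


def write_summary(reports: dict[str, StatsReport], metadata: dict | None = None) -> tuple[str, str]:
    """One summary row per (system, model or 'avg'); returns (JSON, TSV).

    The TSV carries the same rows as the JSON "rows" array; the JSON adds a
    schema version and the run metadata (cutoff, method/basis, ...).
    """
    if not reports:
        raise ValueError("no reports to summarize")
    rows = []
    for label, rep in reports.items():
        system, _, model = label.partition(":")
        rows.append({
            "system": system,
            "model": model or "1",
            "n_shifts": rep.n,
            "mad_ppm": round(rep.mad, 6),
            "r2": None if rep.r2 is None else round(rep.r2, 6),
            "slope": None if rep.slope is None else round(rep.slope, 6),
            "sigma_standard_ppm": round(rep.sigma_standard, 6),
            "excluded": ",".join(rep.excluded) if rep.excluded else "-",
        })
    payload = {"schema_version": SCHEMA_VERSION, "metadata": metadata or {}, "rows": rows}
    js = json.dumps(payload, indent=2, sort_keys=True)
    buf = io.StringIO()
    pd.DataFrame(rows).to_csv(buf, sep="\t", index=False)
    return js, buf.getvalue()
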