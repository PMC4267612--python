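"""Shift referencing and validation analytics.

Computed shieldings become shifts through an internal standard:
sigma_std = mean(delta_exp + sigma_calc) over the matched protons, and
delta_calc = sigma_std - sigma_calc.  This choice zeroes the mean signed
error by construction, removing the systematic offset of the level of
theory without an external TMS calculation.  On top of that sit the
validation analytics: MAD / R^2 / slope against experiment, ensemble
averaging over NMR models (referencing is affine, so averaging shieldings
then referencing equals referencing then averaging shifts), a stereospecific
swap scan for amino-group protons, decoy discrimination between rival
structures, and the H-bond-length / error correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats

from .structure import Model, ShiftTable, Structure, atom_id

__all__ = [
    "MatchedPair", "StatsReport",
    "match_shifts", "compute_internal_standard", "shieldings_to_shifts",
    "compare", "ensemble_average", "swap_scan", "decoy_discrimination",
    "find_hbonds", "hbond_error_correlation",
]


@dataclass
class MatchedPair:
    key: tuple[str, int, str, str]   # chain, resnum, resname, atom name
    delta_exp: float
    sigma_calc: float
    model: str = "1"

    @property
    def atom_id(self) -> str:
        return atom_id(*self.key)


@dataclass
class StatsReport:
    sigma_standard: float
    n: int
    pairs: list[MatchedPair]
    delta_calc: dict[str, float]      # atom id -> predicted shift
    errors: dict[str, float]          # atom id -> delta_calc - delta_exp
    mad: float
    r2: float | None = None
    slope: float | None = None
    intercept: float | None = None
    max_error_atom: str | None = None
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.errors:
            mean_signed = float(np.mean(list(self.errors.values())))
            assert abs(mean_signed) < 1e-9, (
                f"internal-standard referencing must zero the mean signed error "
                f"(got {mean_signed:.3e} ppm)"
            )


def match_shifts(sigma_by_atom: dict[str, float], table: ShiftTable,
                 selection=None, model: str = "1") -> list[MatchedPair]:
    """Join computed shieldings with experimental shifts on atom identity.

    selection, if given, is a callable on the (chain, resnum, resname, name)
    key, e.g. an entity restriction to the DNA part of a complex.
    """
    pairs = []
    for key, dexp in sorted(table.entries.items()):
        if selection is not None and not selection(*key):
            continue
        aid = atom_id(*key)
        if aid in sigma_by_atom:
            pairs.append(MatchedPair(key, float(dexp), float(sigma_by_atom[aid]), model))
    return pairs


def compute_internal_standard(pairs: list[MatchedPair]) -> float:
    """sigma_std = mean(delta_exp + sigma_calc); needs >= 1 pair."""
    if not pairs:
        raise ValueError("cannot reference an empty pair set")
    return float(np.mean([p.delta_exp + p.sigma_calc for p in pairs]))


def shieldings_to_shifts(sigma_by_atom: dict[str, float], sigma_standard: float) -> dict[str, float]:
    """delta_calc = sigma_std - sigma_calc, for matched and unmatched atoms alike."""
    if not math.isfinite(sigma_standard):
        raise ValueError("sigma_standard must be finite")
    return {aid: sigma_standard - s for aid, s in sigma_by_atom.items()}


def compare(sigma_by_atom: dict[str, float], table: ShiftTable,
            selection=None, exclude: list[str] | None = None,
            model: str = "1") -> StatsReport:
    """Reference on the matched set and report MAD / regression statistics.

    The regression is delta_exp (y) on sigma_calc (x); a perfect prediction
    has slope -1 and R^2 = 1.  ``exclude`` removes atom ids from the
    referencing population and the statistics (reported alongside).
    """
    pairs = match_shifts(sigma_by_atom, table, selection=selection, model=model)
    excl = set(exclude or [])
    pairs = [p for p in pairs if p.atom_id not in excl]
    if not pairs:
        raise ValueError("no matched shift/shielding pairs")
    sigma_std = compute_internal_standard(pairs)
    delta_calc = shieldings_to_shifts(sigma_by_atom, sigma_std)
    errors = {p.atom_id: delta_calc[p.atom_id] - p.delta_exp for p in pairs}
    mad = float(np.mean(np.abs(list(errors.values()))))
    r2 = slope = intercept = None
    if len(pairs) >= 2:
        x = np.array([p.sigma_calc for p in pairs])
        y = np.array([p.delta_exp for p in pairs])
        if np.ptp(x) > 0:
            res = sstats.linregress(x, y)
            r2, slope, intercept = float(res.rvalue ** 2), float(res.slope), float(res.intercept)
    worst = max(errors, key=lambda k: abs(errors[k])) if errors else None
    return StatsReport(sigma_standard=sigma_std, n=len(pairs), pairs=pairs,
                       delta_calc=delta_calc, errors=errors, mad=mad,
                       r2=r2, slope=slope, intercept=intercept,
                       max_error_atom=worst, excluded=sorted(excl))


def ensemble_average(per_model: dict[str, dict[str, float]]) -> tuple[dict[str, float], list[str]]:
    """Average shieldings atom-by-atom across models.

    Atoms absent from any model are excluded and listed.  Because
    referencing is affine, averaging shieldings and then referencing equals
    referencing each model and averaging the shifts.
    """
    if not per_model:
        raise ValueError("no models to average")
    keysets = [set(d) for d in per_model.values()]
    common = set.intersection(*keysets)
    dropped = sorted(set.union(*keysets) - common)
    avg = {aid: float(np.mean([d[aid] for d in per_model.values()])) for aid in common}
    return avg, dropped


# ---------------------------------------------------------------------------
# Stereospecific swap scan

# prochiral amino pairs: (residue names, (first, second)); convention says
# the first member carries the larger (downfield, > 7 ppm) shift
PROCHIRAL_PAIRS = (
    (("G", "DG"), ("H21", "H22")),
    (("C", "DC"), ("H41", "H42")),
    (("A", "DA"), ("H61", "H62")),
)
CONVENTION_SPLIT_PPM = 7.0


@dataclass
class SwapCandidate:
    residue: tuple[str, int, str]
    pair: tuple[str, str]
    delta_improvement: float          # (|e1|+|e2|)_orig - (|e1|+|e2|)_swapped
    flagged: bool
    convention_violation: bool
    untestable: bool = False


def swap_scan(report: StatsReport, threshold: float = 0.1,
              pair_table=PROCHIRAL_PAIRS) -> list[SwapCandidate]:
    """Scan amino-group proton pairs for likely swapped assignments.

    For each residue with both pair members matched, the swap gain is the
    drop in summed absolute error when the two experimental shifts are
    interchanged; gains above ``threshold`` (ppm) are flagged.  Pairs whose
    experimental shifts invert the deposition convention (first member
    downfield of 7 ppm, second upfield) are flagged independently.
    """
    by_res: dict[tuple[str, int, str], dict[str, MatchedPair]] = {}
    for p in report.pairs:
        chain, resnum, resname, name = p.key
        by_res.setdefault((chain, resnum, resname), {})[name] = p
    out = []
    for (chain, resnum, resname), atoms in sorted(by_res.items()):
        for resnames, (n1, n2) in pair_table:
            if resname not in resnames:
                continue
            p1, p2 = atoms.get(n1), atoms.get(n2)
            if p1 is None and p2 is None:
                continue
            if p1 is None or p2 is None:
                out.append(SwapCandidate((chain, resnum, resname), (n1, n2),
                                         0.0, False, False, untestable=True))
                continue
            d1 = report.delta_calc[p1.atom_id]
            d2 = report.delta_calc[p2.atom_id]
            orig = abs(d1 - p1.delta_exp) + abs(d2 - p2.delta_exp)
            swapped = abs(d1 - p2.delta_exp) + abs(d2 - p1.delta_exp)
            gain = orig - swapped
            violation = (p1.delta_exp < CONVENTION_SPLIT_PPM < p2.delta_exp)
            out.append(SwapCandidate((chain, resnum, resname), (n1, n2),
                                     float(gain), gain > threshold, violation))
    return out


# ---------------------------------------------------------------------------
# Decoy discrimination


def decoy_discrimination(sigma_a: dict[str, float], sigma_b: dict[str, float],
                         table_a: ShiftTable, table_b: ShiftTable,
                         selection=None) -> dict:
    """Cross-MAD matrix between two rival structures and two shift sets.

    Each of the four comparisons gets its own internal standard.  The
    verdict per experimental set is the prediction set with the smaller
    MAD; discrimination succeeds when each set picks its own structure.
    """
    mads = {}
    for pname, sig in (("A", sigma_a), ("B", sigma_b)):
        for tname, tab in (("a", table_a), ("b", table_b)):
            pairs = match_shifts(sig, tab, selection=selection)
            if not pairs:
                raise ValueError(f"no overlapping atoms between prediction {pname} "
                                 f"and table {tname}")
            rep = compare(sig, tab, selection=selection)
            mads[(pname, tname)] = rep.mad
    verdict = {t: min(("A", "B"), key=lambda p: mads[(p, t)]) for t in ("a", "b")}
    return {"mad": mads, "verdict": verdict,
            "correct": verdict["a"] == "A" and verdict["b"] == "B"}


# ---------------------------------------------------------------------------
# Hydrogen bonds

HBOND_MAX_HA = 2.5     # Å, H...acceptor
HBOND_MIN_ANGLE = 120  # deg, donor-H...acceptor


@dataclass
class HBond:
    hydrogen: str
    donor: str
    acceptor: str
    distance: float   # H...A, Å
    angle: float      # D-H...A, deg


def find_hbonds(model: Model, graph) -> list[HBond]:
    """Geometric H-bond detection: N/O donors and acceptors,
    H...A <= 2.5 Å and D-H...A angle >= 120 deg."""
    by_id = {a.atom_id: a for a in model.atoms}
    out = []
    hydrogens = [a for a in model.atoms if a.is_hydrogen]
    acceptors = [a for a in model.atoms if a.element in ("N", "O")]
    for h in hydrogens:
        donors = [by_id[nb] for nb in graph.neighbors(h.atom_id)
                  if by_id[nb].element in ("N", "O")]
        if not donors:
            continue
        d = donors[0]
        for acc in acceptors:
            if acc.atom_id == d.atom_id or graph.has_edge(h.atom_id, acc.atom_id):
                continue
            r = float(np.linalg.norm(h.coords - acc.coords))
            if r > HBOND_MAX_HA:
                continue
            v1 = d.coords - h.coords
            v2 = acc.coords - h.coords
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
            if ang >= HBOND_MIN_ANGLE:
                out.append(HBond(h.atom_id, d.atom_id, acc.atom_id, r, ang))
    return out


def hbond_error_correlation(model: Model, graph, report: StatsReport) -> dict:
    """Pearson r between H...acceptor length and the signed shift error.

    Only donor protons with a computed error enter; a proton in several
    H-bonds contributes its shortest one.  With fewer than three usable
    protons, or degenerate errors, only the table is returned.
    """
    bonds = find_hbonds(model, graph)
    best: dict[str, HBond] = {}
    for hb in bonds:
        if hb.hydrogen not in best or hb.distance < best[hb.hydrogen].distance:
            best[hb.hydrogen] = hb
    rows = [(hb, report.errors[h]) for h, hb in sorted(best.items())
            if h in report.errors]
    r = None
    if len(rows) >= 3:
        x = np.array([hb.distance for hb, _ in rows])
        y = np.array([e for _, e in rows])
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            r = float(sstats.pearsonr(x, y).statistic)
    return {"r": r, "table": rows, "n": len(rows)}
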