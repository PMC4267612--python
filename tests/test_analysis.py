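"""Referencing identities, comparison statistics, ensemble averaging,
swap scan, decoy discrimination and H-bond/error correlation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from nucshift import analysis, fixtures
from nucshift.analysis import (
    MatchedPair,
    compare,
    compute_internal_standard,
    decoy_discrimination,
    ensemble_average,
    find_hbonds,
    hbond_error_correlation,
    shieldings_to_shifts,
    swap_scan,
)
from nucshift.structure import Atom, Model, ShiftTable, atom_id


def pairs_of(vals):
    return [MatchedPair(("A", i + 1, "DG", "H8"), d, s)
            for i, (d, s) in enumerate(vals)]


class TestInternalStandard:
    def test_single_pair_forces_value(self):
        assert compute_internal_standard(pairs_of([(5.0, 26.0)])) == 31.0

    def test_consistent_pairs_zero_errors(self):
        p = pairs_of([(5.0, 26.0), (7.0, 24.0)])
        std = compute_internal_standard(p)
        assert std == 31.0
        shifts = shieldings_to_shifts({x.atom_id: x.sigma_calc for x in p}, std)
        assert all(shifts[x.atom_id] == pytest.approx(x.delta_exp) for x in p)

    @given(hst.floats(-5, 5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_offset_invariance(self, c):
        """Adding c to every shielding moves the standard by c and leaves
        all errors unchanged (referencing is affine)."""
        base = pairs_of([(5.0, 26.0), (7.1, 24.2), (3.3, 27.9)])
        shifted = pairs_of([(d, s + c) for d, s in [(5.0, 26.0), (7.1, 24.2), (3.3, 27.9)]])
        s0, s1 = compute_internal_standard(base), compute_internal_standard(shifted)
        assert s1 - s0 == pytest.approx(c, abs=1e-9)
        e0 = [s0 - p.sigma_calc - p.delta_exp for p in base]
        e1 = [s1 - p.sigma_calc - p.delta_exp for p in shifted]
        assert e0 == pytest.approx(e1, abs=1e-9)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            compute_internal_standard([])

    def test_shift_shielding_roundtrip(self):
        sig = {"a": 26.0, "b": 28.5}
        d = shieldings_to_shifts(sig, 31.0)
        back = {k: 31.0 - v for k, v in d.items()}
        assert back == sig


class TestCompare:
    def _table(self, entries):
        return ShiftTable(entries=entries)

    def test_perfect_prediction(self):
        sig = {atom_id("A", i, "DG", "H8"): 31.0 - d for i, d in enumerate([5.0, 7.0, 8.1], 1)}
        tab = self._table({("A", i, "DG", "H8"): d for i, d in enumerate([5.0, 7.0, 8.1], 1)})
        rep = compare(sig, tab)
        assert rep.mad == pytest.approx(0.0, abs=1e-12)
        assert rep.r2 == pytest.approx(1.0, abs=1e-12)
        assert rep.slope == pytest.approx(-1.0, abs=1e-12)

    def test_five_pair_closed_form_regression(self):
        """MAD / slope / R^2 match the normal-equation oracle."""
        x = np.array([26.0, 24.5, 27.2, 25.1, 23.8])   # sigma_calc
        y = np.array([5.2, 6.4, 3.9, 6.0, 7.4])        # delta_exp
        sig = {atom_id("A", i + 1, "DG", "H8"): float(s) for i, s in enumerate(x)}
        tab = self._table({("A", i + 1, "DG", "H8"): float(d) for i, d in enumerate(y)})
        rep = compare(sig, tab)
        std = float(np.mean(y + x))
        err = (std - x) - y
        xm, ym = x - x.mean(), y - y.mean()
        slope = float((xm @ ym) / (xm @ xm))
        r2 = float((xm @ ym) ** 2 / ((xm @ xm) * (ym @ ym)))
        assert rep.sigma_standard == pytest.approx(std, abs=1e-12)
        assert rep.mad == pytest.approx(float(np.mean(np.abs(err))), abs=1e-12)
        assert rep.slope == pytest.approx(slope, abs=1e-12)
        assert rep.r2 == pytest.approx(r2, abs=1e-12)
        assert abs(float(np.mean(list(rep.errors.values())))) < 1e-9

    def test_symmetric_noise_changes_mad_by_2e_over_n(self):
        n, e = 6, 0.42
        deltas = [5.0, 6.0, 7.0, 4.5, 5.5, 6.5]
        sig = {atom_id("A", i + 1, "DG", "H8"): 31.0 - d for i, d in enumerate(deltas)}
        tab0 = self._table({("A", i + 1, "DG", "H8"): d for i, d in enumerate(deltas)})
        noisy = dict(tab0.entries)
        noisy[("A", 1, "DG", "H8")] += e
        noisy[("A", 2, "DG", "H8")] -= e
        rep0, rep1 = compare(sig, tab0), compare(sig, self._table(noisy))
        assert rep1.mad - rep0.mad == pytest.approx(2 * e / n, abs=1e-12)

    def test_single_pair_gives_mad_only(self):
        sig = {atom_id("A", 1, "DG", "H8"): 26.0}
        rep = compare(sig, self._table({("A", 1, "DG", "H8"): 5.0}))
        assert rep.mad == 0.0 and rep.r2 is None and rep.slope is None

    def test_selection_restricts_population(self, gc_synthetic):
        st, truth, table, sigma, _ = gc_synthetic
        only_g = lambda c, r, rn, n: rn == "DG"
        rep = compare(sigma, table, selection=only_g)
        assert all(p.key[2] == "DG" for p in rep.pairs)
        assert 0 < rep.n < len(table)

    def test_exclusion_list(self, gc_synthetic):
        st, truth, table, sigma, _ = gc_synthetic
        rep0 = compare(sigma, table)
        drop = rep0.pairs[0].atom_id
        rep1 = compare(sigma, table, exclude=[drop])
        assert rep1.n == rep0.n - 1
        assert drop not in rep1.errors and rep1.excluded == [drop]


class TestEnsembleAverage:
    def test_identical_models_average_to_single(self):
        d = {"x": 30.0, "y": 28.0}
        avg, dropped = ensemble_average({str(i): dict(d) for i in range(10)})
        assert avg == d and dropped == []

    def test_two_model_mean(self):
        avg, _ = ensemble_average({"1": {"x": 30.0}, "2": {"x": 32.0}})
        assert avg["x"] == 31.0

    def test_missing_atom_excluded_and_listed(self):
        avg, dropped = ensemble_average({"1": {"x": 30.0, "y": 1.0}, "2": {"x": 32.0}})
        assert set(avg) == {"x"} and dropped == ["y"]

    def test_referencing_commutes_with_averaging(self):
        """Average-then-reference equals reference-then-average-shifts."""
        rng = np.random.default_rng(3)
        keys = [("A", i + 1, "DG", "H8") for i in range(8)]
        tab = ShiftTable(entries={k: float(5 + rng.normal()) for k in keys})
        per_model = {}
        for m in range(5):
            per_model[str(m)] = {atom_id(*k): float(26 + rng.normal(0, 0.5))
                                 for k in keys}
        avg, _ = ensemble_average(per_model)
        rep_avg = compare(avg, tab)
        shift_stack = []
        for sig in per_model.values():
            r = compare(sig, tab)
            shift_stack.append([r.delta_calc[atom_id(*k)] for k in keys])
        mean_shifts = np.mean(shift_stack, axis=0)
        got = [rep_avg.delta_calc[atom_id(*k)] for k in keys]
        assert got == pytest.approx(list(mean_shifts), abs=1e-9)


class TestSwapScan:
    def test_injected_swap_is_the_only_flag(self, seven_mer):
        truth = fixtures.SyntheticTruth(seed=3, swaps=[("A", 2, "H41", "H42")])
        table, sigma, _ = fixtures.make_synthetic_shifts(seven_mer, truth)
        rep = compare(sigma, table)
        flagged = [c for c in swap_scan(rep) if c.flagged]
        assert len(flagged) == 1
        assert flagged[0].residue[:2] == ("A", 2)
        assert flagged[0].pair == ("H41", "H42")
        assert flagged[0].delta_improvement > 0.1

    def test_symmetric_errors_not_flagged(self):
        sig = {atom_id("A", 1, "DG", "H21"): 24.0, atom_id("A", 1, "DG", "H22"): 26.0,
               atom_id("A", 1, "DG", "H8"): 23.0, atom_id("A", 1, "DG", "H1'"): 25.0}
        tab = ShiftTable(entries={("A", 1, "DG", "H21"): 7.0, ("A", 1, "DG", "H22"): 5.0,
                                  ("A", 1, "DG", "H8"): 8.0, ("A", 1, "DG", "H1'"): 6.0})
        rep = compare(sig, tab)
        cands = swap_scan(rep)
        assert len(cands) == 1 and not cands[0].flagged

    def test_convention_violation_flag(self):
        # H21 upfield of 7 ppm while H22 downfield: violates deposition pattern
        sig = {atom_id("A", 1, "DG", "H21"): 24.9, atom_id("A", 1, "DG", "H22"): 23.5}
        tab = ShiftTable(entries={("A", 1, "DG", "H21"): 6.1, ("A", 1, "DG", "H22"): 7.5})
        rep = compare(sig, tab)
        c = swap_scan(rep)[0]
        assert c.convention_violation

    def test_half_pair_untestable(self):
        sig = {atom_id("A", 1, "DC", "H41"): 24.0, atom_id("A", 1, "DC", "H5"): 25.5}
        tab = ShiftTable(entries={("A", 1, "DC", "H41"): 7.2, ("A", 1, "DC", "H5"): 5.3})
        rep = compare(sig, tab)
        cands = swap_scan(rep)
        assert len(cands) == 1 and cands[0].untestable


class TestDecoy:
    def test_constructed_truths_give_diagonal_minimum(self):
        stA = fixtures.make_toy_nucleic("GCGC", form="single")
        stB = fixtures.make_toy_nucleic("GCGC", form="hairpin")
        ta, sa, _ = fixtures.make_synthetic_shifts(stA, fixtures.SyntheticTruth(noise=0.05, seed=7))
        tb, sb, _ = fixtures.make_synthetic_shifts(stB, fixtures.SyntheticTruth(noise=0.05, seed=8))
        res = decoy_discrimination(sa, sb, ta, tb)
        m = res["mad"]
        assert m[("A", "a")] < m[("B", "a")]
        assert m[("B", "b")] < m[("A", "b")]
        assert res["correct"]

    def test_identical_tables_give_identical_columns(self, gc_synthetic):
        st, truth, table, sigma, _ = gc_synthetic
        sig_b = {k: v + 0.3 for k, v in sigma.items()}
        res = decoy_discrimination(sigma, sig_b, table, table)
        m = res["mad"]
        assert m[("A", "a")] == pytest.approx(m[("A", "b")], abs=1e-12)
        assert m[("B", "a")] == pytest.approx(m[("B", "b")], abs=1e-12)

    def test_disjoint_atoms_rejected(self, gc_synthetic):
        st, truth, table, sigma, _ = gc_synthetic
        with pytest.raises(ValueError, match="no overlapping"):
            decoy_discrimination({"Q/9.XX/H1": 1.0}, {"Q/9.XX/H1": 1.0}, table, table)


def _nh_o_cluster(distances):
    """Colinear N-H...O groups at the given H...O distances."""
    import networkx as nx
    atoms, g = [], nx.Graph()
    for i, d in enumerate(distances):
        x0 = 10.0 * i
        for n, e, c in [("N1", "N", [x0, 0, 0]), ("H1", "H", [x0 + 1.01, 0, 0]),
                        ("O1", "O", [x0 + 1.01 + d, 0, 0])]:
            atoms.append(Atom(atom_id("X", i + 1, "LIG", n), n, e,
                              np.array(c, dtype=float), 0, "X", i + 1, "LIG"))
    for a in atoms:
        g.add_node(a.atom_id, element=a.element)
    for i in range(len(distances)):
        g.add_edge(atom_id("X", i + 1, "LIG", "N1"), atom_id("X", i + 1, "LIG", "H1"))
    return Model(atoms), g


class TestHBonds:
    def test_detection_matches_brute_force(self):
        model, g = _nh_o_cluster([1.8, 2.0, 2.4, 2.6])  # last exceeds 2.5 Å
        found = find_hbonds(model, g)
        assert sorted(round(b.distance, 2) for b in found) == [1.8, 2.0, 2.4]
        by_id = {a.atom_id: a for a in model.atoms}
        brute = []
        for h in model.atoms:
            if not h.is_hydrogen:
                continue
            don = [by_id[n] for n in g.neighbors(h.atom_id)][0]
            for acc in model.atoms:
                if acc.element not in "NO" or acc.atom_id == don.atom_id:
                    continue
                r = np.linalg.norm(h.coords - acc.coords)
                v1, v2 = don.coords - h.coords, acc.coords - h.coords
                ang = np.degrees(np.arccos(np.clip(
                    v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)))
                if r <= 2.5 and ang >= 120:
                    brute.append((h.atom_id, acc.atom_id))
        assert {(b.hydrogen, b.acceptor) for b in found} == set(brute)

    def test_linear_errors_give_r_one(self):
        model, g = _nh_o_cluster([1.8, 2.0, 2.2, 2.4])
        sig, entries = {}, {}
        for i, d in enumerate([1.8, 2.0, 2.2, 2.4]):
            aid = atom_id("X", i + 1, "LIG", "H1")
            sig[aid] = 26.0
            entries[("X", i + 1, "LIG", "H1")] = 5.0 - (2.0 * d - 4.2)  # error linear in d
        rep = compare(sig, ShiftTable(entries=entries))
        res = hbond_error_correlation(model, g, rep)
        assert res["n"] == 4
        assert res["r"] == pytest.approx(1.0, abs=1e-9)

    def test_constant_errors_leave_r_undefined(self):
        model, g = _nh_o_cluster([1.8, 2.0, 2.2])
        sig = {atom_id("X", i + 1, "LIG", "H1"): 26.0 for i in range(3)}
        entries = {("X", i + 1, "LIG", "H1"): 5.0 for i in range(3)}
        rep = compare(sig, ShiftTable(entries=entries))
        res = hbond_error_correlation(model, g, rep)
        assert res["r"] is None and res["n"] == 3
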