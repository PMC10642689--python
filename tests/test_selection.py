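import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from opsinkit.codons import SENSE_CODONS
from opsinkit.selection import (
    back_translate_alignment,
    ng86_dnds,
    compare_groups_dnds,
    relaxation_test,
    tuning_site_report,
    trait_association_test,
    TraitVector,
)
from opsinkit.selection.ng86 import UndefinedResultError
from opsinkit.selection.pagel import _TreeArrays, _p2, _prune
from opsinkit.simul import simulate_codon_pair, simulate_species_tree
from tests.conftest import rooted
from tests.oracles import ng86_pair_oracle, mk_likelihood_oracle


class TestBackTranslate:
    def test_gap_becomes_triplet_gap(self):
        aln = back_translate_alignment({"t": "M-K"}, {"t": "ATGAAA"})
        assert aln.row("t") == "ATG---AAA"

    def test_mismatching_cds_names_taxon(self):
        with pytest.raises(ValueError, match="badtaxon"):
            back_translate_alignment({"badtaxon": "MK"}, {"badtaxon": "ATGCTG"})

    @given(st.lists(st.sampled_from(SENSE_CODONS), min_size=2, max_size=30),
           st.integers(0, 5))
    @settings(max_examples=30, deadline=None)
    def test_round_trip_identity(self, codons, gap_at):
        from Bio.Seq import Seq
        cds = "".join(codons)
        prot = str(Seq(cds).translate())
        row = prot[:gap_at] + "-" + prot[gap_at:]
        aln = back_translate_alignment({"t": row}, {"t": cds})
        assert aln.row("t").replace("---", "") == cds
        back = str(Seq(aln.row("t").replace("---", "")).translate())
        assert back == prot


class TestNg86:
    def test_identical_sequences(self):
        r = ng86_dnds("ATGAAA", "ATGAAA")
        assert r.dN == 0 and r.dS == 0
        assert math.isnan(r.omega)

    def test_hand_worked_synonymous_example(self):
        # 9 lysine codons; one AAA->AAG third-position change
        r = ng86_dnds("AAA" * 9, "AAA" * 8 + "AAG")
        assert (r.S, r.N, r.Sd, r.Nd) == (3.0, 24.0, 1.0, 0.0)
        assert r.dS == pytest.approx(0.4408, abs=5e-5)
        assert r.dN == 0.0
        assert r.omega == 0.0

    def test_hand_worked_nonsynonymous_example(self):
        # one AAA->ACA change; sites averaged over both sequences (ACA's
        # third position is fourfold degenerate): S = 10/3, N = 71/3
        r = ng86_dnds("AAA" * 9, "AAA" * 8 + "ACA")
        assert (r.Sd, r.Nd) == (0.0, 1.0)
        assert r.S == pytest.approx(10 / 3)
        assert r.dN == pytest.approx(-0.75 * math.log(1 - (4 / 3) * (3 / 71)))
        assert r.dS == 0.0
        assert math.isinf(r.omega)

    def test_symmetry_and_site_sum(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a = "".join(rng.choice(SENSE_CODONS, 30))
            b = "".join(rng.choice(SENSE_CODONS, 30))
            r1, r2 = ng86_dnds(a, b), ng86_dnds(b, a)
            assert r1.S == pytest.approx(r2.S)
            assert r1.Sd == pytest.approx(r2.Sd)
            assert r1.N + r1.S == pytest.approx(3 * r1.n_codons)

    def test_matches_brute_force_oracle_on_random_pairs(self):
        rng = np.random.default_rng(13)
        for _ in range(60):
            a = "".join(rng.choice(SENSE_CODONS, 30))
            b = "".join(rng.choice(SENSE_CODONS, 30))
            r = ng86_dnds(a, b)
            S, N, Sd, Nd, dS, dN = ng86_pair_oracle(a, b)
            assert r.S == pytest.approx(S, abs=1e-9)
            assert r.N == pytest.approx(N, abs=1e-9)
            assert r.Sd == pytest.approx(Sd, abs=1e-9)
            assert r.Nd == pytest.approx(Nd, abs=1e-9)
            if not math.isnan(dS):
                assert r.dS == pytest.approx(dS, abs=1e-9)

    def test_gap_columns_skipped_and_empty_rejected(self):
        r = ng86_dnds("ATG---AAA", "ATGAAAAAA")
        assert r.n_codons == 2
        with pytest.raises(UndefinedResultError):
            ng86_dnds("---", "---")

    @pytest.mark.parametrize("omega", [0.1, 0.5, 1.0])
    def test_estimator_recovery(self, omega):
        est = [ng86_dnds(*simulate_codon_pair(500, 0.4, omega, 1.0,
                                              7000 + 13 * i)).omega
               for i in range(30)]
        mean = np.nanmean(est)
        assert abs(mean - omega) / omega < 0.2


class TestGroupComparison:
    def test_identical_groups_p_near_one(self):
        vals = {"nocturnal": [0.1, 0.2, 0.3], "diurnal": [0.1, 0.2, 0.3],
                "both": [0.1, 0.2, 0.3]}
        out = compare_groups_dnds(vals, n_perm=499, seed=1)
        assert out["p_value"] > 0.9

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(2)
        vals = {"nocturnal": rng.normal(0.1, 0.02, 20),
                "diurnal": rng.normal(0.2, 0.02, 20)}
        out = compare_groups_dnds(vals, n_perm=999, seed=3)
        assert out["p_value"] < 0.01

    def test_nonfinite_excluded_and_reported(self):
        vals = {"a": [0.1, 0.2, np.inf], "b": [0.3, 0.4, np.nan]}
        out = compare_groups_dnds(vals, n_perm=99, seed=1)
        assert out["n_excluded"] == 2

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups_dnds({"a": [0.1], "b": [0.2, 0.3]})

    def test_null_pvalues_uniform(self):
        # calibration: p-values under a common distribution are ~U(0,1)
        rng = np.random.default_rng(4)
        pvals = []
        for i in range(120):
            vals = {"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10)}
            pvals.append(compare_groups_dnds(vals, n_perm=199,
                                             seed=500 + i)["p_value"])
        from scipy.stats import kstest
        d = kstest(pvals, "uniform").statistic
        assert d < 1.36 / math.sqrt(len(pvals))  # 5% KS critical value


class TestRelaxation:
    def test_duplicated_values_ratio_one(self):
        a, b = simulate_codon_pair(200, 0.3, 0.3, 2.0, seed=5)
        c, d = simulate_codon_pair(200, 0.3, 0.3, 2.0, seed=6)
        aln = {"f1": a, "f2": b, "b1": a, "b2": b}
        res = relaxation_test(aln, ["f1", "f2"], n_perm=99, seed=1)
        assert res.ratio == pytest.approx(1.0)

    def test_relaxed_foreground_detected(self):
        sig = 0
        for s in range(3):
            aln, fg_ids = two_clade_alignment(0.8, 0.1, seed=100 + s,
                                              n_per_side=5)
            res = relaxation_test(aln, fg_ids, n_perm=199, seed=s)
            assert res.ratio > 1
            if res.p_value < 0.05:
                sig += 1
        assert sig >= 2

    def test_partition_too_small_rejected(self):
        a, b = simulate_codon_pair(60, 0.2, 0.3, 2.0, seed=7)
        with pytest.raises(ValueError):
            relaxation_test({"x": a, "y": b, "z": a}, ["x"], n_perm=9, seed=0)


def two_clade_alignment(omega_fg, omega_bg, seed, n_per_side=5, codons=300):
    """One gene family with a relaxed foreground clade and a purifying
    background clade, as in a parent/retrocopy comparison."""
    from opsinkit.simul.codon_evolve import evolve_branch, random_root_cds
    from opsinkit.codons import cds_to_indices, indices_to_cds
    rng = np.random.default_rng(seed)
    root = cds_to_indices(random_root_cds(codons, rng, start_codon=False))
    anc_fg = evolve_branch(root, 0.05, omega_bg, 2.0, rng)
    anc_bg = evolve_branch(root, 0.05, omega_bg, 2.0, rng)
    aln = {}
    for i in range(n_per_side):
        aln[f"fg{i}"] = indices_to_cds(
            evolve_branch(anc_fg, 0.15, omega_fg, 2.0, rng))
        aln[f"bg{i}"] = indices_to_cds(
            evolve_branch(anc_bg, 0.15, omega_bg, 2.0, rng))
    return aln, [k for k in aln if k.startswith("fg")]


class TestTuningSites:
    ALN = {
        "ref": "MSRT" * 40,          # 160 aa reference
        "sub": "MSRT" * 28 + "MART" + "MSRT" * 11,   # S->A at position 114
        "gap": "MSRT" * 28 + "M-RT" + "MSRT" * 11,
    }

    def test_substitution_label(self):
        recs = tuning_site_report(self.ALN, "ref", [114])
        by_taxon = {r["taxon"]: r for r in recs}
        assert by_taxon["sub"]["label"] == "S114A"
        assert by_taxon["gap"]["label"] == "missing"

    def test_identical_taxon_empty_label(self):
        aln = {"ref": "MSRT", "same": "MSRT"}
        recs = tuning_site_report(aln, "ref", [2])
        assert recs[0]["label"] == ""

    def test_out_of_range_site_rejected(self):
        with pytest.raises(ValueError):
            tuning_site_report(self.ALN, "ref", [9999])

    def test_reference_coordinates_skip_gaps(self):
        aln = {"ref": "M-SRT", "q": "MKART"}
        recs = tuning_site_report(aln, "ref", [2])  # ungapped position 2 = S
        assert recs[0]["reference_residue"] == "S"
        assert recs[0]["label"] == "S2A"


class TestTraitAssociation:
    def test_constant_traits_degenerate(self):
        tree = simulate_species_tree(8, 1.0, 0.0, seed=31)
        tv = TraitVector({f"s{i}": "nocturnal" for i in range(1, 9)},
                         {f"s{i}": 0 for i in range(1, 9)})
        with pytest.warns(UserWarning):
            out = trait_association_test(tree, tv, n_boot=9, seed=0)
        assert out["lr"] == 0.0 and out["p_value"] == 1.0

    def test_pruning_matches_exhaustive_enumeration(self):
        # 2-state pruning vs brute-force summation over ancestral states
        tree = rooted("(((A:0.3,B:0.5):0.2,C:0.9):0.4,(D:0.6,E:0.2):0.7);")
        states = {"A": 0, "B": 1, "C": 0, "D": 1, "E": 0}
        q01, q10 = 0.7, 1.3
        ta = _TreeArrays(tree, sorted(states))
        lnl = _prune(ta, _p2(q01, q10, ta.branch_lengths), states, 2)

        def P_of_edge(t):
            return _p2(q01, q10, np.array([t]))[0]

        expected = mk_likelihood_oracle(tree, states, P_of_edge)
        assert lnl == pytest.approx(expected, abs=1e-9)

    def test_perfectly_correlated_traits_detected(self):
        tree = simulate_species_tree(30, 1.0, 0.0, seed=33)
        rng = np.random.default_rng(9)
        from opsinkit.selection.pagel import _TreeArrays, _simulate_trait
        ta = _TreeArrays(tree, [lf.taxon.label for lf in tree.leaf_node_iter()])
        # simulate one trait with enough flips, mirror it in the other
        height = max(ta.branch_lengths.sum() / 30, 1e-9)
        a = _simulate_trait(ta, 1.2 / height * 0.5, 1.2 / height * 0.5, rng)
        if len(set(a.values())) < 2:
            pytest.skip("degenerate draw")
        tv = TraitVector({sp: ("diurnal" if v else "nocturnal")
                          for sp, v in a.items()}, dict(a))
        out = trait_association_test(tree, tv, n_boot=49, seed=2)
        assert out["p_value"] <= 0.05
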