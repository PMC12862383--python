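"""Protein/intron RBH matching, Dollo ages, and age-stratified statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

import shortsplice as ss
from shortsplice.orthology import JunctionWindow, age_summaries
from shortsplice.synthetic import _simulate_presence

NEWICK = "((Pbur,(Ptet,Pcau)),Tthe);"


def _window(gene, idx, seq, pos=50, phase=0):
    return JunctionWindow(gene_id=gene, intron_index=idx, window=seq,
                         offset_in_protein=pos, phase=phase)


class TestProteinRbh:
    PROTS = {
        "a": "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ",
        "b": "MWWTNNHHLLPPQQGGEERRKKDDSSAAVVII",
        "c": "MCCGGHHIIKKLLMMNNPPQQRRSSTTVVWWYY",
    }

    def test_identical_proteomes_identity_mapping(self):
        pairs = ss.protein_rbh(self.PROTS, dict(self.PROTS))
        assert dict(zip(pairs["gene_a"], pairs["gene_b"])) == {"a": "a", "b": "b", "c": "c"}

    def test_non_reciprocal_best_dropped(self):
        # b1 is a's best hit, but b1's best hit is a2 (an exact copy of b1)
        pa = {"a": self.PROTS["a"], "a2": self.PROTS["b"]}
        pb = {"b1": self.PROTS["b"]}
        pairs = ss.protein_rbh(pa, pb)
        assert pairs["gene_a"].tolist() == ["a2"]

    def test_tied_best_hits_dropped(self):
        pa = {"a": self.PROTS["a"]}
        pb = {"b1": self.PROTS["a"], "b2": self.PROTS["a"]}
        pairs = ss.protein_rbh(pa, pb)
        assert pairs.empty

    def test_empty_proteome_rejected(self):
        with pytest.raises(ValueError):
            ss.protein_rbh({}, self.PROTS)


class TestJunctionWindows:
    PROTEIN = "".join("ACDEFGHIKLMNPQRSTVWY" * 10)  # 200 aa

    def test_interior_window_is_ten_each_side(self):
        (w,) = ss.junction_windows(self.PROTEIN, "g", [(1, 50, 0)])
        assert w.window == self.PROTEIN[40:60]
        assert (w.left_len, w.right_len) == (10, 10)

    def test_truncated_at_n_terminus(self):
        (w,) = ss.junction_windows(self.PROTEIN, "g", [(1, 4, 0)])
        assert w.window == self.PROTEIN[0:14]
        assert w.left_len == 4

    def test_minimum_flank_excludes_short_side(self):
        out = ss.junction_windows(self.PROTEIN, "g", [(1, 2, 0)], min_flank=8)
        assert out == []

    def test_position_outside_protein_excluded(self):
        assert ss.junction_windows(self.PROTEIN, "g", [(1, 500, 0)]) == []


class TestMatchIntrons:
    def test_identical_windows_match_with_identity_one(self):
        wa = [_window("ga", 1, "ACDEFGHIKLMNPQRSTVWY")]
        wb = [_window("gb", 1, "ACDEFGHIKLMNPQRSTVWY")]
        out = ss.match_introns(wa, wb)
        assert len(out) == 1
        assert out.loc[0, "identity"] == 1.0
        assert out.loc[0, "is_rbh"]

    def test_half_identity_still_eligible(self):
        wa = [_window("ga", 1, "AAAAAAAAAA" + "WWWWWWWWWW")]
        wb = [_window("gb", 1, "AAAAAAAAAA" + "YYYYYYYYYY")]
        out = ss.match_introns(wa, wb)
        assert len(out) == 1
        assert out.loc[0, "identity"] == pytest.approx(0.5)

    def test_below_threshold_rejected(self):
        # 7 of 20 identities = 0.35 < 0.40 (W/F mismatches align without gaps)
        wa = [_window("ga", 1, "AAAAAAA" + "W" * 13)]
        wb = [_window("gb", 1, "AAAAAAA" + "F" * 13)]
        out = ss.match_introns(wa, wb)
        assert out.empty

    def test_phase_mismatch_rejected(self):
        wa = [_window("ga", 1, "ACDEFGHIKLMNPQRSTVWY", phase=0)]
        wb = [_window("gb", 1, "ACDEFGHIKLMNPQRSTVWY", phase=1)]
        assert ss.match_introns(wa, wb).empty
        assert len(ss.match_introns(wa, wb, require_phase_match=False)) == 1

    def test_symmetry(self, rng):
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        wa = [_window("ga", k, "".join(rng.choice(aas, size=20))) for k in range(1, 6)]
        wb = [_window("gb", k, "".join(rng.choice(aas, size=20))) for k in range(1, 6)]
        fwd = ss.match_introns(wa, wb)
        rev = ss.match_introns(wb, wa)
        assert set(zip(fwd["intron_a"], fwd["intron_b"])) == set(
            zip(rev["intron_b"], rev["intron_a"])
        )


class TestSpeciesTreeAges:
    def test_reference_must_be_leaf(self):
        with pytest.raises(ValueError):
            ss.SpeciesTree(NEWICK, "nosuch")

    @pytest.mark.parametrize(
        "present,expected",
        [
            (["Pbur"], 1),
            (["Pbur", "Ptet"], 2),
            (["Pbur", "Pcau"], 2),
            (["Pbur", "Ptet", "Pcau"], 2),
            (["Pbur", "Tthe"], 3),
            (["Pbur", "Ptet", "Pcau", "Tthe"], 3),
        ],
    )
    def test_mrca_age_classes(self, default_tree, present, expected):
        assert default_tree.age_of_mrca(present) == expected

    def test_max_age(self, default_tree):
        assert default_tree.max_age == 3


def _brute_force_dollo_age(pattern: dict[str, str], tree: ss.SpeciesTree) -> int:
    """Enumerate all single-gain/any-loss scenarios; min losses wins.

    A gain node is admissible iff every present leaf descends from it and the
    reference does; losses are counted as the number of maximal subtrees
    below the gain node containing no present leaf (gene_missing leaves are
    compatible with either state and never force a loss).
    """
    present = {sp for sp, st in pattern.items() if st == "present"}
    absent = {sp for sp, st in pattern.items() if st == "absent"}
    best = None
    for node in tree.tree.preorder_node_iter():
        leaves = {l.taxon.label for l in node.leaf_iter()}
        if not present <= leaves:
            continue

        def min_losses(n):
            labels = {l.taxon.label for l in n.leaf_iter()}
            if not (labels & present):
                # whole subtree can be explained by one loss, unless every
                # leaf is merely gene_missing (then no loss is needed)
                return 1 if labels & absent else 0
            return sum(min_losses(c) for c in n.child_nodes())

        losses = min_losses(node)
        age = tree._node_age.get(id(node))
        if age is None:
            continue  # gain off the reference path cannot explain a reference intron
        if best is None or losses < best[0]:
            best = (losses, age)
    return best[1]


class TestAssignAge:
    def test_agrees_with_brute_force_on_all_patterns(self, default_tree):
        others = ["Ptet", "Pcau", "Tthe"]
        for states in itertools.product(["present", "absent"], repeat=3):
            pattern = {"Pbur": "present", **dict(zip(others, states))}
            assert ss.assign_age(pattern, default_tree) == _brute_force_dollo_age(
                pattern, default_tree
            )

    def test_gene_missing_is_uninformative(self, default_tree):
        pattern = {"Pbur": "present", "Ptet": "gene_missing", "Pcau": "absent", "Tthe": "present"}
        assert ss.assign_age(pattern, default_tree) == 3
        pattern = {"Pbur": "present", "Ptet": "gene_missing", "Pcau": "gene_missing", "Tthe": "absent"}
        assert ss.assign_age(pattern, default_tree) == 1

    def test_reference_absent_invalid(self, default_tree):
        pattern = {"Pbur": "absent", "Ptet": "present", "Pcau": "absent", "Tthe": "absent"}
        with pytest.raises(ValueError):
            ss.assign_age(pattern, default_tree)

    def test_birth_node_recovery_on_loss_free_histories(self, default_tree, rng):
        hits = 0
        n = 500
        for _ in range(n):
            birth = int(rng.choice([1, 2, 3], p=[0.47, 0.43, 0.10]))
            presence = _simulate_presence(rng, default_tree, birth, loss_prob=0.0)
            pattern = {sp: "present" if v else "absent" for sp, v in presence.items()}
            hits += ss.assign_age(pattern, default_tree) == birth
        assert hits == n


class TestPresencePatterns:
    def _introns(self):
        return pd.DataFrame({"intron_id": ["gA.i1", "gB.i1", "gC.i1"], "gene_id": ["gA", "gB", "gC"]})

    def test_patterns_and_eligibility(self, default_tree):
        orth = {
            "Ptet": {"gA": "x", "gB": "y"},
            "Pcau": {"gA": "x"},
            "Tthe": {"gA": "x"},
        }
        matches = {"Ptet": {"gA.i1"}, "Pcau": {"gA.i1"}, "Tthe": {"gA.i1"}}
        pats = ss.presence_patterns(self._introns(), orth, matches, default_tree)
        byid = pats.set_index("intron_id")
        assert [byid.loc["gA.i1", sp] for sp in ["Pbur", "Ptet", "Pcau", "Tthe"]] == ["present"] * 4
        assert byid.loc["gB.i1", "Ptet"] == "absent"
        assert not byid.loc["gB.i1", "eligible"]  # gene in only 2 of 4 species
        assert byid.loc["gC.i1", "age_zero"]  # no orthologs at all
        ages = ss.assign_ages(pats, default_tree).set_index("intron_id")["age_group"]
        assert ages["gA.i1"] == 3
        assert ages["gC.i1"] == 0
        assert np.isnan(ages["gB.i1"])


class TestAgeStatistics:
    def test_proportion_se_formula(self):
        assert ss.proportion_se(0.5, 100) == pytest.approx(0.05)

    def test_trend_test_matches_r(self):
        # frozen from R prop.trend.test(c(30,25,20,10), rep(100,4))
        chi2, p = ss.cochran_armitage_trend([30, 25, 20, 10], [100, 100, 100, 100])
        assert chi2 == pytest.approx(12.62371615, rel=1e-8)
        assert p == pytest.approx(0.0003808833826, rel=1e-8)

    def test_flat_proportions_not_significant(self):
        chi2, p = ss.cochran_armitage_trend([20, 20, 20], [100, 100, 100])
        assert chi2 == pytest.approx(0.0)
        assert p == 1.0

    def test_age_summaries_planted_retention_trend(self, rng):
        # retention decreasing with age, as the cohort generator plants
        n = 300
        ages = rng.choice([1, 2, 3], size=n, p=[0.45, 0.4, 0.15])
        assignments = pd.DataFrame(
            {
                "intron_id": [f"g{k}.i1" for k in range(n)],
                "gene_id": [f"g{k}" for k in range(n)],
                "age_group": ages.astype(float),
            }
        )
        features = pd.DataFrame(
            {
                "intron_id": assignments["intron_id"],
                "gc": rng.uniform(0.1, 0.3, n),
                "length": rng.integers(15, 40, n),
            }
        )
        psi = pd.Series(
            np.clip(0.3 - 0.08 * ages + 0.02 * rng.normal(size=n), 0, 1),
            index=assignments["intron_id"],
        )
        dsi_ids = set(assignments["intron_id"][(ages == 1) & (rng.random(n) < 0.5)])
        out = age_summaries(assignments, features, mean_psi=psi, dsi_ids=dsi_ids)
        medians = [out["groups"][g]["median_psi"] for g in (1, 2, 3)]
        assert medians[0] > medians[1] > medians[2]
        assert out["dsi_trend"]["p"] < 0.01
        g1 = out["groups"][1]
        assert g1["dsi_proportion_se"] == pytest.approx(
            ss.proportion_se(g1["dsi_proportion"], g1["n"])
        )
        assert out["psi_by_age_mannwhitney"]["1_vs_3"]["p"] < 1e-6
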