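"""Wagner and DTL parsimony, quantization, presence and proteome rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ace.experiments import dtl_brute_force, wagner_brute_force
from ace.io import EventTable, FamilyProfile
from ace.reconcile import (CopyProfile, DtlCosts, add_singletons,
                           ancestral_presence, complex_presence,
                           dtl_reconcile, proteome_size, quantize_events,
                           quantize_table, reconcile_sample,
                           wagner_parsimony)
from ace.simulate import simulate_species_tree
from ace.trees import Tree


class TestWagnerParsimony:
    def test_uniform_single_copy_has_no_events(self, balanced_tree):
        prof = CopyProfile("f", {g: 1 for g in "ABCD"})
        res = wagner_parsimony(balanced_tree, prof)
        assert res.cost == 0
        assert set(res.states.values()) == {1}
        assert sum(res.gains.values()) == sum(res.losses.values()) == 0

    def test_single_loss_reconstructed(self, balanced_tree):
        prof = CopyProfile("f", {"A": 1, "B": 1, "C": 1, "D": 0})
        res = wagner_parsimony(balanced_tree, prof)
        assert res.cost == 1
        assert res.states["ROOT"] == 1
        assert res.losses["D"] == 1

    def test_tie_broken_toward_smaller_root_state(self, balanced_tree):
        prof = CopyProfile("f", {"A": 1, "B": 1, "C": 0, "D": 0})
        res = wagner_parsimony(balanced_tree, prof)
        assert res.cost == 1
        assert res.states["ROOT"] == 0  # gain on the AB branch preferred

    def test_absent_genomes_count_as_zero(self, balanced_tree):
        res = wagner_parsimony(balanced_tree, CopyProfile("f", {"A": 2}))
        assert res.states["ROOT"] == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_cost_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        tree = simulate_species_tree(int(rng.integers(3, 7)), seed=seed)
        copies = {g: int(rng.integers(0, 4)) for g in tree.leaf_names}
        copies[tree.leaf_names[0]] = max(1, copies[tree.leaf_names[0]])
        prof = CopyProfile("f", copies)
        assert wagner_parsimony(tree, prof).cost == pytest.approx(
            wagner_brute_force(tree, prof))


class TestDtlReconcile:
    def test_congruent_tree_costs_zero_with_speciations_only(
            self, balanced_tree):
        g = Tree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        lm = dict(zip("abcd", "ABCD"))
        res = dtl_reconcile(balanced_tree, g, leaf_map=lm)
        assert res.cost == 0
        assert res.D.sum() == res.T.sum() == res.L.sum() == 0
        assert res.origination == balanced_tree.root
        assert (res.copies == 1).all()

    def test_discordant_topology_needs_one_transfer(self):
        s = Tree.from_newick("((A:1,B:1):1,C:2);")
        g = Tree.from_newick("((a:1,c:1):1,b:1);")
        res = dtl_reconcile(s, g, DtlCosts(2, 3, 1),
                            {"a": "A", "c": "C", "b": "B"})
        assert res.cost == 3
        assert len(res.transfers) == 1

    def test_single_leaf_family_originates_at_leaf(self, balanced_tree):
        g = Tree.from_newick("a;")
        res = dtl_reconcile(balanced_tree, g, leaf_map={"a": "A"})
        assert res.cost == 0
        assert res.origination == balanced_tree.index["A"]
        assert res.O[balanced_tree.index["A"]] == 1

    def test_unmapped_leaf_errors(self, balanced_tree):
        g = Tree.from_newick("(a:1,zz:1);")
        with pytest.raises(ValueError, match="maps to no species leaf"):
            dtl_reconcile(balanced_tree, g, leaf_map={"a": "A"})

    def test_unrooted_input_is_rooted_at_min_cost_edge(self, balanced_tree):
        g = Tree.from_newick("(a:1,b:1,(c:1,d:1):1);")
        lm = dict(zip("abcd", "ABCD"))
        res = dtl_reconcile(balanced_tree, g, leaf_map=lm)
        assert res.cost == 0  # congruent after optimal rooting

    @pytest.mark.parametrize("seed", range(20))
    def test_cost_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        stree = simulate_species_tree(int(rng.integers(3, 5)), seed=seed)
        k = int(rng.integers(2, 5))
        names = [f"g{i}" for i in range(k)]
        lm = {g: stree.leaf_names[int(rng.integers(len(stree.leaf_names)))]
              for g in names}
        parts = [f"{g}:1" for g in names]
        while len(parts) > 1:
            i, j = sorted(rng.choice(len(parts), 2, replace=False))
            b, a = parts.pop(int(j)), parts.pop(int(i))
            parts.append(f"({a},{b}):1")
        gtree = Tree.from_newick(parts[0] + ";")
        costs = DtlCosts(2, 3, 1)
        assert dtl_reconcile(stree, gtree, costs, lm).cost == pytest.approx(
            dtl_brute_force(stree, gtree, costs, lm))

    def test_infinite_transfer_cost_forbids_transfers(self):
        s = Tree.from_newick("((A:1,B:1):1,C:2);")
        g = Tree.from_newick("((a:1,c:1):1,b:1);")
        lm = {"a": "A", "c": "C", "b": "B"}
        res = dtl_reconcile(s, g, DtlCosts(2, 1e9, 1), lm)
        assert res.T.sum() == 0
        assert len(res.transfers) == 0

    def test_cost_monotone_in_each_event_cost(self):
        s = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        g = Tree.from_newick("(((a:1,c:1):1,b:1):1,d:1);")
        lm = dict(zip("abcd", "ABCD"))
        base = dtl_reconcile(s, g, DtlCosts(2, 3, 1), lm).cost
        for costs in (DtlCosts(4, 3, 1), DtlCosts(2, 5, 1),
                      DtlCosts(2, 3, 3)):
            assert dtl_reconcile(s, g, costs, lm).cost >= base


class TestReconcileSample:
    def test_identical_trees_give_integer_frequencies(self, balanced_tree):
        g = Tree.from_newick("((A|0:1,B|0:1):1,(C|0:1,D|0:1):1);")
        prof = FamilyProfile("f", [(f"{x}|0", x) for x in "ABCD"],
                             [g, g, g])
        events, routes = reconcile_sample(balanced_tree, prof)
        vals = events[["O", "D", "T", "L", "C"]].to_numpy()
        assert np.all(vals == np.round(vals))
        assert routes.empty

    def test_event_in_half_the_sample_has_frequency_half(self):
        s = Tree.from_newick("((A:1,B:1):1,C:2);")
        congruent = Tree.from_newick("((A|0:1,B|0:1):1,C|0:1);")
        discordant = Tree.from_newick("((A|0:1,C|0:1):1,B|0:1);")
        prof = FamilyProfile("f", [(f"{x}|0", x) for x in "ABC"],
                             [congruent, discordant])
        events, routes = reconcile_sample(s, prof)
        assert routes["frequency"].tolist() == [0.5]
        t_total = events.groupby("node")["T"].sum().sum()
        assert t_total == pytest.approx(0.5)

    def test_no_gene_trees_errors(self, balanced_tree):
        with pytest.raises(ValueError, match="no gene trees"):
            reconcile_sample(balanced_tree,
                             FamilyProfile("f", [("a", "A"), ("b", "B")]))


class TestSingletons:
    def _table(self):
        return EventTable(pd.DataFrame(
            columns=["family", "node", "O", "D", "T", "L", "C"]))

    def test_singleton_becomes_leaf_origination(self, balanced_tree):
        out = add_singletons(self._table(),
                             [FamilyProfile("f1", [("s1", "A")])],
                             balanced_tree)
        row = out.df.iloc[0]
        assert (row["node"], row["O"], row["C"]) == ("A", 1.0, 1.0)

    def test_no_singletons_is_identity(self, balanced_tree):
        tab = self._table()
        assert add_singletons(tab, [], balanced_tree) is tab

    def test_two_singletons_same_genome_two_rows(self, balanced_tree):
        out = add_singletons(self._table(),
                             [FamilyProfile("f1", [("s1", "A")]),
                              FamilyProfile("f2", [("s2", "A")])],
                             balanced_tree)
        assert (out.df["node"] == "A").sum() == 2

    def test_non_singleton_rejected(self, balanced_tree):
        with pytest.raises(ValueError, match="not a singleton"):
            add_singletons(self._table(),
                           [FamilyProfile("f", [("a", "A"), ("b", "B")])],
                           balanced_tree)


class TestQuantization:
    @pytest.mark.parametrize("freq,expected", [
        (0.25, 0), (0.3, 1), (1.29, 1), (1.3, 2), (2.3, 3), (2.31, 3),
        (0.0, 0),
    ])
    def test_staircase_boundaries(self, freq, expected):
        assert quantize_events(freq) == expected

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            quantize_events(-0.1)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0, 10), st.floats(0, 10))
    def test_monotone_in_frequency(self, f1, f2):
        lo, hi = sorted((f1, f2))
        assert quantize_events(lo) <= quantize_events(hi)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 20))
    def test_integer_counts_are_fixed_points(self, k):
        if k == 0:
            assert quantize_events(0.0) == 0
        else:
            assert quantize_events(float(k)) == k

    def test_quantize_table_sets_provenance(self):
        tab = EventTable(pd.DataFrame([
            {"family": "f", "node": "A", "O": 0.4, "D": 1.5, "T": 0.1,
             "L": 2.3, "C": 0.9}]))
        q = quantize_table(tab)
        assert q.provenance == "quantized"
        assert q.df.loc[0, ["O", "D", "T", "L", "C"]].tolist() == \
            [1, 2, 0, 3, 1]
        with pytest.raises(ValueError, match="raw"):
            quantize_table(q)


class TestPresenceAndProteome:
    def _raw(self):
        return EventTable(pd.DataFrame([
            {"family": "f1", "node": "X", "O": 0, "D": 0, "T": 0, "L": 0,
             "C": 1.0},
            {"family": "f2", "node": "X", "O": 0, "D": 0, "T": 0, "L": 0,
             "C": 0.5},
            {"family": "f3", "node": "X", "O": 0, "D": 0, "T": 0, "L": 0,
             "C": 0.29},
        ]))

    def test_presence_boundary_inclusive_at_cutoff(self):
        pres = ancestral_presence(
            EventTable(pd.DataFrame([
                {"family": "f", "node": "X", "O": 0, "D": 0, "T": 0,
                 "L": 0, "C": 0.30},
                {"family": "g", "node": "X", "O": 0, "D": 0, "T": 0,
                 "L": 0, "C": 0.29}])))
        assert pres.set_index("family")["present"].to_dict() == \
            {"f": True, "g": False}

    def test_presence_requires_raw_table(self):
        q = EventTable(self._raw().df.assign(C=[1, 1, 0]), "quantized")
        with pytest.raises(ValueError, match="raw"):
            ancestral_presence(q)

    def test_proteome_size_sums_copy_frequencies(self):
        assert proteome_size(self._raw(), "X") == pytest.approx(1.79)

    def test_unknown_node_errors(self):
        with pytest.raises(KeyError):
            proteome_size(self._raw(), "nope")

    def test_completeness_correction_scales_leaf(self):
        assert proteome_size(self._raw(), "X", {"X": 0.5}) == \
            pytest.approx(3.58)


class TestComplexPresence:
    @pytest.mark.parametrize("flags,expected", [
        ([True, True, False, False], True),   # 2 of 4, boundary inclusive
        ([True, False, False], False),        # 1 of 3
        ([True], True),
    ])
    def test_majority_rule(self, flags, expected):
        assert complex_presence(flags) is expected

    def test_zero_subunits_errors(self):
        with pytest.raises(ValueError):
            complex_presence([])
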