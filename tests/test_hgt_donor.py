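"""Donor-classification workflow on labeled homolog trees."""

import numpy as np
import pytest

from ace.hgt_donor import (LabeledHomologTree, classify_donor,
                           coverage_filter, find_query_clades,
                           prune_long_branches, sample_outgroup,
                           select_subtree)
from ace.io import Alignment
from ace.simulate import plant_donor_tree


def _tip(tid, phylum="Proteobacteria", query=False, length=0.1,
         domain="Bacteria", superphylum="Gracilicutes"):
    if query:
        domain, superphylum, phylum = "Bacteria", "PVC", "Chlamydiae"
    return f"{tid}|{domain}|{superphylum}|{phylum}|{1 if query else 0}" \
        f":{length}"


def _chain(tips, support=95):
    out = tips[0]
    for t in tips[1:]:
        out = f"({out},{t}){support}:0.1"
    return out


class TestLabeledTreeParsing:
    def test_tip_metadata_extracted(self):
        nwk = f"({_tip('q1', query=True)},{_tip('x1')});"
        lt = LabeledHomologTree.from_newick(nwk)
        assert lt.query == {"q1"}
        assert lt.taxonomy["x1"] == ("Bacteria", "Gracilicutes",
                                     "Proteobacteria")

    def test_round_trip(self):
        nwk = f"({_tip('q1', query=True)},{_tip('x1')});"
        lt = LabeledHomologTree.from_newick(nwk)
        again = LabeledHomologTree.from_newick(lt.to_newick())
        assert again.query == lt.query
        assert again.taxonomy == lt.taxonomy

    def test_malformed_label_rejected(self):
        with pytest.raises(ValueError, match="bad tip label"):
            LabeledHomologTree.from_newick("(a:1,b:1);")


class TestPruneLongBranches:
    def test_equal_lengths_keep_everything(self):
        nwk = "(" + _chain([_tip(f"t{i}") for i in range(6)]) + ");"
        lt = LabeledHomologTree.from_newick(nwk)
        _, removed = prune_long_branches(lt)
        assert removed == []

    def test_single_outlier_removed(self):
        tips = [_tip(f"t{i}", length=0.1) for i in range(9)]
        tips.append(_tip("far", length=1.0))
        lt = LabeledHomologTree.from_newick("(" + _chain(tips) + ");")
        pruned, removed = prune_long_branches(lt)
        assert removed == ["far"]  # Q3 = 0.1, IQR = 0 -> threshold 0.1
        assert "far" not in pruned.tree.leaf_names

    def test_threshold_is_strict(self):
        # all tips exactly at the threshold stay
        tips = [_tip(f"t{i}", length=0.2) for i in range(8)]
        lt = LabeledHomologTree.from_newick("(" + _chain(tips) + ");")
        _, removed = prune_long_branches(lt)
        assert removed == []

    def test_never_removes_at_or_below_median(self):
        rng = np.random.default_rng(0)
        tips = [_tip(f"t{i}", length=round(float(rng.lognormal(-2, 1)), 4))
                for i in range(30)]
        lt = LabeledHomologTree.from_newick("(" + _chain(tips) + ");")
        lengths = {lt.tree.names[i]: lt.tree.lengths[i]
                   for i in lt.tree.leaves}
        _, removed = prune_long_branches(lt)
        med = np.median(list(lengths.values()))
        assert all(lengths[t] > med for t in removed)

    def test_too_few_tips_errors(self):
        lt = LabeledHomologTree.from_newick(
            "(" + _chain([_tip("a"), _tip("b"), _tip("c")]) + ");")
        with pytest.raises(ValueError, match="4 tips"):
            prune_long_branches(lt)


class TestCoverageFilter:
    def test_boundary_inclusive(self):
        aln = Alignment.from_dict({
            "keep": "ACDE------",   # coverage 0.4
            "drop": "ACD-------",   # coverage 0.3
            "gone": "----------",
        })
        assert coverage_filter(aln) == ["keep"]

    def test_zero_length_alignment_errors(self):
        with pytest.raises(ValueError):
            coverage_filter(Alignment(["a"], np.empty((1, 0), "S1")))


class TestFindQueryClades:
    def test_pure_query_clade_found(self):
        nwk = (f"(({_tip('q1', query=True)},({_tip('q2', query=True)},"
               f"{_tip('q3', query=True)})95:0.1)95:0.1,"
               f"({_tip('x1')},{_tip('x2')})95:0.1);")
        lt = LabeledHomologTree.from_newick(nwk)
        clades = find_query_clades(lt)
        assert len(clades) == 1
        assert lt.query_tips(clades[0]) == {"q1", "q2", "q3"}

    def test_quarter_fraction_boundary_inclusive(self):
        tips = [_tip(f"q{i}", query=True) for i in range(4)]
        tips += [_tip(f"x{i}") for i in range(12)]
        lt = LabeledHomologTree.from_newick("(" + _chain(tips) + ");")
        assert len(find_query_clades(lt)) == 1  # 4/16 = 25% qualifies

    def test_two_disjoint_clades_ordered_by_query_count(self):
        # query tips are rare overall, so neither the root nor the big
        # outgroup clades qualify; the two pure query clades do
        big = _chain([_tip(f"q{i}", query=True) for i in range(5)])
        small = _chain([_tip(f"p{i}", query=True) for i in range(3)])
        out1 = _chain([_tip(f"x{i}") for i in range(20)])
        out2 = _chain([_tip(f"y{i}") for i in range(12)])
        lt = LabeledHomologTree.from_newick(
            f"(({big},{out1})95:0.1,({small},{out2})95:0.1);")
        clades = find_query_clades(lt)
        assert len(clades) == 2
        assert len(lt.query_tips(clades[0])) == 5
        assert len(lt.query_tips(clades[1])) == 3

    def test_single_query_tip_does_not_qualify(self):
        nwk = f"({_tip('q1', query=True)},({_tip('x1')},{_tip('x2')}));"
        lt = LabeledHomologTree.from_newick(nwk)
        assert find_query_clades(lt) == []


class TestSelectSubtree:
    def _big_tree(self, n_extra, support=95):
        query = _chain([_tip(f"q{i}", query=True) for i in range(5)])
        inner = f"({query},{_tip('s0')}){support}:0.1"
        added = 0
        step = 0
        while added < n_extra:
            take = min(60, n_extra - added)
            clade = _chain([_tip(f"e{step}_{i}") for i in range(take)],
                           support)
            inner = f"({inner},{clade}){support}:0.1"
            added += take
            step += 1
        return LabeledHomologTree.from_newick(f"({inner});")

    def test_small_tree_returned_whole(self):
        lt = self._big_tree(120)
        clade = find_query_clades(lt)[0]
        sub = select_subtree(lt, clade)
        assert set(sub.tree.leaf_names) == set(lt.tree.leaf_names)

    def test_eligible_ancestor_selected(self):
        lt = self._big_tree(301)
        clade = find_query_clades(lt)[0]
        sub = select_subtree(lt, clade)
        extra = len(sub.tree.leaf_names) - 5
        assert 150 <= extra <= 400
        assert len(sub.tree.leaf_names) < len(lt.tree.leaf_names)

    def test_low_support_ancestors_skipped(self):
        # all internal supports 60 (< 0.7): no eligible node, whole tree
        lt = self._big_tree(301, support=60)
        clade = find_query_clades(lt)[0]
        sub = select_subtree(lt, clade)
        assert set(sub.tree.leaf_names) == set(lt.tree.leaf_names)


class TestSampleOutgroup:
    def test_small_sister_taken_whole(self):
        query = _chain([_tip(f"q{i}", query=True) for i in range(3)])
        sister = _chain([_tip(f"s{i}") for i in range(30)])
        lt = LabeledHomologTree.from_newick(f"(({query},{sister})95:0.1);")
        sub_tips = {f"q{i}" for i in range(3)}
        out = sample_outgroup(lt, sub_tips, seed=1)
        assert len(out) == 30

    def test_large_sister_capped_and_reproducible(self):
        query = _chain([_tip(f"q{i}", query=True) for i in range(3)])
        sister = _chain([_tip(f"s{i}") for i in range(80)])
        lt = LabeledHomologTree.from_newick(f"(({query},{sister})95:0.1);")
        sub_tips = {f"q{i}" for i in range(3)}
        a = sample_outgroup(lt, sub_tips, seed=7)
        b = sample_outgroup(lt, sub_tips, seed=7)
        c = sample_outgroup(lt, sub_tips, seed=8)
        assert len(a) == 50 and a == b and a != c

    def test_escalates_past_small_sister(self):
        query = _chain([_tip(f"q{i}", query=True) for i in range(3)])
        sister = _chain([_tip(f"s{i}") for i in range(10)])
        uncle = _chain([_tip(f"u{i}") for i in range(25)])
        lt = LabeledHomologTree.from_newick(
            f"((({query},{sister})95:0.1,{uncle})95:0.1);")
        out = sample_outgroup(lt, {f"q{i}" for i in range(3)}, seed=1)
        assert len(out) == 35  # pooled 10 + 25 candidates

    def test_warns_when_root_reached_short(self):
        query = _chain([_tip(f"q{i}", query=True) for i in range(3)])
        sister = _chain([_tip(f"s{i}") for i in range(5)])
        lt = LabeledHomologTree.from_newick(f"(({query},{sister})95:0.1);")
        with pytest.warns(UserWarning):
            out = sample_outgroup(lt, {f"q{i}" for i in range(3)}, seed=1)
        assert len(out) == 5


class TestClassifyDonor:
    def test_planted_phylum_recovered(self):
        lt, truth = plant_donor_tree(purity=1.0, seed=0)
        call = classify_donor(lt, "fam", level=0.75)
        assert call.status == "donor-assigned"
        assert call.label == truth.donor_phylum
        assert call.rank == "phylum"

    def test_partial_purity_resolves_only_at_loose_level(self):
        lt, truth = plant_donor_tree(purity=0.8, seed=2)
        loose = classify_donor(lt, "fam", level=0.75)
        strict = classify_donor(lt, "fam", level=0.90)
        assert loose.status == "donor-assigned"
        assert loose.label == truth.donor_phylum
        assert strict.status == "unresolved"

    def test_low_sister_support_is_unresolved(self):
        query = _chain([_tip(f"q{i}", query=True) for i in range(3)])
        sister = _chain([_tip(f"s{i}") for i in range(4)], support=70)
        nested = _chain([_tip(f"n{i}") for i in range(4)])
        lt = LabeledHomologTree.from_newick(
            f"((({query},{sister})95:0.1,{nested})95:0.1);")
        assert classify_donor(lt, "fam").status == "unresolved"

    def test_no_non_query_homologs_is_de_novo(self):
        nwk = "(" + _chain([_tip(f"q{i}", query=True)
                            for i in range(4)]) + ");"
        lt = LabeledHomologTree.from_newick(nwk)
        assert classify_donor(lt, "fam").status == "de-novo-candidate"

    def test_non_monophyletic_query_is_unresolved(self):
        nwk = (f"(({_tip('q1', query=True)},{_tip('x1')})95:0.1,"
               f"({_tip('q2', query=True)},{_tip('x2')})95:0.1);")
        lt = LabeledHomologTree.from_newick(nwk)
        assert classify_donor(lt, "fam").status == "unresolved"
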