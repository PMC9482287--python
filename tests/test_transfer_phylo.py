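"""Monophyly queries, IGT/HGT classification, site audit, NJ builder."""

import random

import dendropy
import numpy as np
import pytest

from organellekit import synthetic_data as syn
from organellekit import transfer_phylo as tp

# ---------------------------------------------------------------------------
# helpers


def _support_tree(newick, groups, query, outgroup):
    return tp.SupportTree.from_newick(newick, groups, query, outgroup)


def random_rooted_newick(rng, labels):
    """Random binary rooted topology with random supports."""
    nodes = [f"{lab}:1.0" for lab in labels]
    while len(nodes) > 1:
        i = rng.randrange(len(nodes))
        a = nodes.pop(i)
        j = rng.randrange(len(nodes))
        b = nodes.pop(j)
        sup = rng.randint(0, 100)
        nodes.append(f"({a},{b}){sup}:1.0")
    return nodes[0] + ";"


def _mrca_leafset(st, tip_set):
    """Oracle: leaf set under the MRCA found by root-path intersection."""
    paths = []
    for t in tip_set:
        node = st.tree.find_node_with_taxon_label(t)
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        paths.append(path)
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)

    def depth(n):
        d = 0
        while n.parent_node is not None:
            d += 1
            n = n.parent_node
        return d

    mrca = max(common, key=depth)
    return {l.taxon.label for l in mrca.leaf_iter()}


def _shuffled_newick(newick, seed):
    tree = dendropy.Tree.get(
        data=newick, schema="newick",
        suppress_internal_node_taxa=True, preserve_underscores=True,
    )
    rng = random.Random(seed)
    for node in tree.preorder_node_iter():
        if node.num_child_nodes() > 1:
            children = list(node.child_nodes())
            rng.shuffle(children)
            node.set_child_nodes(children)
    return tree.as_string(schema="newick", suppress_rooting=True)


# ---------------------------------------------------------------------------


class TestMonophyly:
    def _caterpillar(self):
        groups = {"A": "Lamiales", "B": "Lamiales", "C": "Lamiales", "D": "outgroup"}
        return _support_tree("(((A,B)80,C)90,D);", groups, "A", "D")

    def test_cherry_is_monophyletic_with_support(self):
        st = self._caterpillar()
        mono, support = st.is_monophyletic({"A", "B"})
        assert mono and support == 80

    def test_non_clade_subset_is_not_monophyletic(self):
        st = self._caterpillar()
        assert st.is_monophyletic({"A", "C"}) == (False, None)

    def test_unknown_tips_rejected(self):
        st = self._caterpillar()
        with pytest.raises(tp.TreeError):
            st.is_monophyletic({"A", "Z"})

    def test_matches_mrca_oracle_on_random_trees(self):
        rng = random.Random(99)
        for _ in range(30):
            n = rng.randint(4, 8)
            labels = [f"t{i}" for i in range(n)]
            newick = random_rooted_newick(rng, labels)
            groups = {lab: "Lamiales" for lab in labels}
            groups[labels[-1]] = "outgroup"
            st = _support_tree(newick, groups, labels[0], labels[-1])
            non_out = [lab for lab in labels if lab != labels[-1]]
            for _ in range(20):
                size = rng.randint(2, len(non_out))
                subset = set(rng.sample(non_out, size))
                mono, _ = st.is_monophyletic(subset)
                assert mono == (_mrca_leafset(st, subset) == subset)


class TestClassifyTransfer:
    def _classify(self, key, **kw):
        sc = syn.default_tree_scenarios()[key]
        st = _support_tree(sc.newick, sc.groups, sc.query, sc.outgroup)
        return tp.classify_transfer(
            st, n_informative_sites=sc.n_informative_sites, **kw
        )

    def test_query_inside_lamiales_is_igt(self):
        call = self._classify("rpoB-1")
        assert (call.verdict, call.donor) == ("IGT", "Lamiales")

    def test_query_sister_to_bletilla_is_hgt_from_orchidaceae(self):
        call = self._classify("ycf2-1")
        assert (call.verdict, call.donor) == ("HGT", "Orchidaceae")
        assert call.support == 85

    def test_query_inside_gentianaceae_is_hgt_at_full_support(self):
        call = self._classify("rpl16-1")
        assert (call.verdict, call.donor, call.support) == ("HGT", "Gentianaceae", 100)

    def test_short_fragments_are_undetermined(self):
        for key in ("ycf15-1", "ycf2-2"):
            call = self._classify(key)
            assert (call.verdict, call.reason) == ("undetermined", "too_short")

    def test_uniform_low_support_is_undetermined(self):
        groups = {
            "Lamiales_1": "Lamiales", "Lamiales_2": "Lamiales",
            "Gent_1": "Gentianaceae", "Gent_2": "Gentianaceae",
            "OUT": "outgroup",
        }
        newick = "(((Q,Gent_1)60,Gent_2)60,(Lamiales_1,Lamiales_2)60,OUT);"
        st = _support_tree(newick, groups, "Q", "OUT")
        call = tp.classify_transfer(st, n_informative_sites=20)
        assert (call.verdict, call.reason) == ("undetermined", "low_support")

    def test_invariant_under_tip_order_permutation(self):
        for key in ("rpoB-1", "ycf2-1", "rpl14-1", "ycf15-1"):
            sc = syn.default_tree_scenarios()[key]
            base = self._classify(key)
            for seed in (1, 2, 3):
                shuffled = _shuffled_newick(sc.newick, seed)
                st = _support_tree(shuffled, sc.groups, sc.query, sc.outgroup)
                call = tp.classify_transfer(
                    st, n_informative_sites=sc.n_informative_sites
                )
                assert (call.verdict, call.donor, call.support) == (
                    base.verdict, base.donor, base.support
                )

    def test_invariant_under_rerooting(self):
        """The same unrooted topology written from another rooting gives
        the identical call once rooted on the designated outgroup."""
        sc = syn.default_tree_scenarios()["ycf2-1"]
        q = sc.query
        rerooted = (
            f"((Lamiales_1:0.010,Lamiales_2:0.012)95:0.010,"
            f"((({q}:0.010,Bletilla_1:0.010)64:0.010,"
            f"(Orchidaceae_1:0.015,Orchidaceae_2:0.015)90:0.012)85:0.020,"
            f"(Gentianaceae_1:0.040,Outgroup_1:0.080)92:0.015):0.010);"
        )
        st = _support_tree(rerooted, sc.groups, sc.query, sc.outgroup)
        call = tp.classify_transfer(st, n_informative_sites=sc.n_informative_sites)
        assert (call.verdict, call.donor, call.support) == ("HGT", "Orchidaceae", 85)

    def test_raising_min_support_is_a_monotone_gate(self):
        for key in syn.default_tree_scenarios():
            determined = []
            for ms in (55, 70, 86, 95):
                call = self._classify(key, min_support=ms)
                determined.append(call.verdict != "undetermined")
            # once undetermined at some threshold, stays undetermined above
            for lo, hi in zip(determined, determined[1:]):
                assert not (hi and not lo)

    def test_missing_query_rejected(self):
        with pytest.raises(tp.TreeError):
            _support_tree(
                "((A,B)90,C);", {"A": "Lamiales", "B": "Lamiales", "C": "outgroup"},
                "Q", "C",
            )

    def test_call_invariants_enforced(self):
        with pytest.raises(ValueError):
            tp.TransferCall("HGT", "Lamiales", 90, "nested_in_other_group")
        with pytest.raises(ValueError):
            tp.TransferCall("undetermined", "Orchidaceae", None, "low_support")


class TestSiteAudit:
    def test_rpl20_single_site_is_fragile(self):
        aln = syn.make_rpl20_alignment(1)
        audit = tp.audit_sites(
            aln, "Ckw_rpl20",
            {"Lamiaceae_1", "Lamiaceae_2"},
            {"Orobanchaceae_1", "Orobanchaceae_2"},
        )
        assert (audit.support_a, audit.support_b) == (1, 0)
        assert audit.fragile
        assert len(audit.pivotal) == 1
        idx, old, new = audit.pivotal[0]
        assert idx == 187 and {old, new} == {"A", "G"}

    def test_ten_concordant_sites_are_robust(self):
        aln = syn.make_consistent_alignment(1, n_support=10)
        audit = tp.audit_sites(aln, "query", {"A_1", "A_2"}, {"B_1", "B_2"})
        assert (audit.support_a, audit.support_b) == (10, 0)
        assert not audit.fragile

    def test_no_informative_columns_counts_zero(self):
        aln = {"q": "ACGTACGT", "a1": "ACGTACGT", "a2": "ACGTACGT",
               "b1": "ACGTACGT", "b2": "ACGTACGT"}
        audit = tp.audit_sites(aln, "q", {"a1", "a2"}, {"b1", "b2"})
        assert (audit.support_a, audit.support_b, audit.informative) == (0, 0, 0)
        assert not audit.fragile

    def test_flip_analysis_agrees_with_scratch_recount(self):
        """Oracle: actually mutate the alignment and recount from scratch."""
        aln = syn.make_rpl20_alignment(1)
        audit = tp.audit_sites(
            aln, "Ckw_rpl20",
            {"Lamiaceae_1", "Lamiaceae_2"},
            {"Orobanchaceae_1", "Orobanchaceae_2"},
        )
        for idx, _, new in audit.pivotal:
            mutated = dict(aln)
            q = list(mutated["Ckw_rpl20"])
            q[idx - 1] = new
            mutated["Ckw_rpl20"] = "".join(q)
            redone = tp.audit_sites(
                mutated, "Ckw_rpl20",
                {"Lamiaceae_1", "Lamiaceae_2"},
                {"Orobanchaceae_1", "Orobanchaceae_2"},
            )
            assert redone.winner != audit.winner

    def test_errors(self):
        aln = {"q": "ACGT", "a": "ACG"}
        with pytest.raises(ValueError, match="ragged"):
            tp.audit_sites(aln, "q", {"a"}, set())
        aln = {"q": "ACGT", "a": "ACGT", "b": "ACGT"}
        with pytest.raises(ValueError, match="overlap"):
            tp.audit_sites(aln, "q", {"a"}, {"a", "b"})

    def test_informative_site_counter(self):
        aln = syn.make_consistent_alignment(1, n_support=10)
        assert tp.count_informative_sites(aln) == 10


class TestNeighborJoining:
    def _additive_alignment(self):
        # p-distances: d(A,B)=d(C,D)=0.04, cross pairs 0.40 -> split AB|CD
        ncol = 100
        base = syn._random_seq(np.random.default_rng(0), ncol)
        rows = {n: list(base) for n in ("A", "B", "C", "D")}
        for j in range(40):  # separate {A,B} from {C,D}
            rows["A"][j] = rows["B"][j] = "G"
            rows["C"][j] = rows["D"][j] = "T"
        for j, name in ((90, "A"), (92, "B"), (94, "C"), (96, "D")):
            rows[name][j] = "C" if rows[name][j] != "C" else "A"
            rows[name][j + 1] = "C" if rows[name][j + 1] != "C" else "A"
        return {n: "".join(r) for n, r in rows.items()}

    def test_recovers_additive_four_taxon_topology(self):
        aln = self._additive_alignment()
        # oracle: the four-point condition over the three pairings
        d = {
            (a, b): tp._p_distance(aln[a], aln[b])
            for a in aln for b in aln if a < b
        }
        sums = {
            frozenset([("A", "B"), ("C", "D")]): d[("A", "B")] + d[("C", "D")],
            frozenset([("A", "C"), ("B", "D")]): d[("A", "C")] + d[("B", "D")],
            frozenset([("A", "D"), ("B", "C")]): d[("A", "D")] + d[("B", "C")],
        }
        oracle_split = min(sums, key=sums.get)
        assert ("A", "B") in oracle_split
        tree = tp.build_nj_tree(aln)
        splits = set()
        for node in tree.preorder_internal_node_iter():
            leaves = frozenset(l.taxon.label for l in node.leaf_iter())
            if len(leaves) == 2:
                splits.add(leaves)
        assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits

    def test_strong_clade_gets_high_bootstrap(self):
        rng = np.random.default_rng(8)
        ncol = 120
        base = syn._random_seq(rng, ncol)
        rows = {n: list(base) for n in ("A1", "A2", "A3", "B1", "B2", "B3")}
        for j in range(50):  # 50 fixed diagnostic columns
            for n in ("A1", "A2", "A3"):
                rows[n][j] = "G"
            for n in ("B1", "B2", "B3"):
                rows[n][j] = "T"
        for i, n in enumerate(rows):  # small unique noise per taxon
            for j in (60 + 3 * i, 61 + 3 * i):
                rows[n][j] = "C" if rows[n][j] != "C" else "A"
        aln = {n: "".join(r) for n, r in rows.items()}
        tree = tp.bootstrap_support(aln, replicates=100, seed=5)
        support = None
        for node in tree.preorder_internal_node_iter():
            leaves = frozenset(l.taxon.label for l in node.leaf_iter())
            if leaves in (frozenset({"A1", "A2", "A3"}), frozenset({"B1", "B2", "B3"})):
                support = int(node.label)
        assert support is not None and support >= 95

    def test_bootstrap_is_seeded(self):
        aln = self._additive_alignment()
        t1 = tp.bootstrap_support(aln, replicates=20, seed=3).as_string(schema="newick")
        t2 = tp.bootstrap_support(aln, replicates=20, seed=3).as_string(schema="newick")
        assert t1 == t2

    def test_errors(self):
        with pytest.raises(ValueError, match=">= 4"):
            tp.build_nj_tree({"A": "ACGT", "B": "ACGT", "C": "ACGT"})
        with pytest.raises(ValueError, match="all-gap"):
            tp.build_nj_tree(
                {"A": "ACGT", "B": "ACGT", "C": "ACGT", "D": "----"}
            )
        with pytest.raises(ValueError, match="replicates"):
            tp.bootstrap_support({"A": "ACGT", "B": "ACGT", "C": "AGGT", "D": "ATGT"}, replicates=0)
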