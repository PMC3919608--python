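import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import DistanceMatrix, TreeNode

from cfampol.domains import DomainHit, resolve_architecture
from cfampol.grouping import (
    GROUPS,
    FeatureVector,
    assign_by_clade,
    bootstrap_support,
    classify_group,
    extract_features,
    kimura_distance_matrix,
    nj_tree,
    tree_to_newick,
)
from cfampol.motifs import MotifReport
from cfampol.synthetic import _mutate, _random_sequence


def _report(clamp_class="canonical", php_intact=True, ctail=False):
    return MotifReport(
        protein_id="p",
        clamp_motif="QLSLF" if clamp_class != "none" else None,
        clamp_class=clamp_class,
        clamp_position=(900, 905) if clamp_class != "none" else None,
        clamp_window_fallback=False,
        hda_like=False,
        php_score=9 if php_intact else 2,
        php_intact=php_intact,
        active_site_intact=True,
        ctail_motif=ctail,
    )


def _hit(domain, start, end, nested_in=None):
    return DomainHit(domain, start, end, 100.0, 1e-6, nested_in=nested_in)


def _polc_arch():
    return resolve_architecture(
        [
            _hit("NTD", 0, 210),
            _hit("OB", 220, 320),
            _hit("PHP", 330, 780),
            _hit("Exo", 470, 650, nested_in="PHP"),
            _hit("Pol3", 790, 1250),
            _hit("HhH", 1260, 1360),
        ],
        1380,
        "p",
    )


def _dnae1_arch(with_ctd=True, with_ob=True):
    hits = [_hit("PHP", 0, 270), _hit("Pol3", 280, 740), _hit("HhH", 750, 850)]
    if with_ob:
        hits.append(_hit("OB", 900, 1000))
    if with_ctd:
        hits.append(_hit("CTD", 1010, 1130))
    return resolve_architecture(hits, 1150, "p")


class TestExtractFeatures:
    def test_polc_style(self):
        f = extract_features(_polc_arch(), _report(), 880, 5.2)
        assert f.ob_position == "upstream_of_PHP"
        assert f.exo_inserted and f.has_NTD and not f.has_CTD

    def test_dnae1_style(self):
        f = extract_features(_dnae1_arch(), _report(), 880, 5.2)
        assert f.has_CTD
        assert f.ob_position == "downstream_of_HhH"
        assert not f.exo_inserted

    def test_ob_absent(self):
        f = extract_features(_dnae1_arch(with_ctd=False, with_ob=False), _report(), 880, 5.2)
        assert f.ob_position == "absent"


def _features(**kwargs):
    defaults = dict(
        has_NTD=False,
        has_CTD=True,
        exo_inserted=False,
        exo_nterminal=False,
        ob_position="downstream_of_HhH",
        clamp_class="canonical",
        php_intact=True,
        ctail_motif=False,
        core_length=880,
        core_pI=5.3,
    )
    defaults.update(kwargs)
    return FeatureVector(**defaults)


class TestClassifyGroup:
    def test_dnae2_hallmarks(self):
        f = _features(has_CTD=False, ctail_motif=True, clamp_class="dnae2_type",
                      php_intact=False)
        call = classify_group(f)
        assert call.label == "DnaE2"
        assert call.confidence == "rule"

    def test_dnae1_canonical(self):
        call = classify_group(_features(clamp_class="canonical_strong", php_intact=True))
        assert call.label == "DnaE1"

    def test_conflicting_evidence_falls_back(self):
        # CTD present, moderately strong Q motif, but a disrupted metal
        # site: the rule set cannot decide and defers to the tree
        call = classify_group(_features(clamp_class="canonical", php_intact=False))
        assert call.label == "DnaEX"
        assert call.confidence == "fallback"

    def test_polc_architecture_wins_over_motifs(self):
        f = _features(
            has_NTD=True, ob_position="upstream_of_PHP", exo_inserted=True,
            has_CTD=False, clamp_class="canonical_strong",
        )
        assert classify_group(f).label == "PolC"

    def test_dnae3_disrupted_site_weak_motif(self):
        call = classify_group(_features(clamp_class="weak", php_intact=False))
        assert call.label == "DnaE3"

    def test_php_disrupted_strong_motif_exception_stays_dnae1(self):
        call = classify_group(
            _features(clamp_class="canonical_strong", php_intact=False, has_CTD=True)
        )
        assert call.label == "DnaE1"
        assert "php_disrupted_exception" in call.evidence

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        has_NTD=st.booleans(),
        has_CTD=st.booleans(),
        exo_inserted=st.booleans(),
        exo_nterminal=st.booleans(),
        ob_position=st.sampled_from(["upstream_of_PHP", "downstream_of_HhH", "absent"]),
        clamp_class=st.sampled_from(["canonical_strong", "canonical", "weak", "dnae2_type", "none"]),
        php_intact=st.booleans(),
        ctail_motif=st.booleans(),
    )
    def test_total_and_deterministic(self, **kwargs):
        f = _features(**kwargs)
        call1 = classify_group(f)
        call2 = classify_group(f)
        assert call1.label in GROUPS
        assert call1.label == call2.label
        assert call1.evidence


def random_tree_and_matrix(rng, n_taxa):
    """Random bifurcating topology with positive branch lengths and its
    additive distance matrix (path lengths)."""
    taxa = [f"t{i}" for i in range(n_taxa)]
    nodes = [TreeNode(name=t) for t in taxa]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = TreeNode()
        a.length = float(rng.uniform(0.1, 1.0))
        b.length = float(rng.uniform(0.1, 1.0))
        parent.extend([a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode()
    nodes[0].length = float(rng.uniform(0.1, 1.0))
    nodes[1].length = float(rng.uniform(0.1, 1.0))
    root.extend(nodes)
    dm = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            d = root.find(taxa[i]).distance(root.find(taxa[j]))
            dm[i, j] = dm[j, i] = d
    return root, DistanceMatrix(dm, ids=taxa)


def bipartitions(tree):
    leaves = frozenset(t.name for t in tree.tips())
    parts = set()
    for node in tree.non_tips(include_self=False):
        clade = frozenset(t.name for t in node.tips())
        if 1 < len(clade) < len(leaves) - 1:
            other = leaves - clade
            parts.add(clade if min(clade) > min(other) else other)
    return parts


class TestNjTree:
    def test_recovers_generating_topology(self, rng):
        for k in range(50):
            n = int(rng.integers(4, 9))
            true_tree, dm = random_tree_and_matrix(rng, n)
            estimate = nj_tree(dm)
            assert bipartitions(estimate) == bipartitions(true_tree), f"case {k}"

    def test_agrees_with_dendropy_on_additive_matrix(self, rng):
        _, dm = random_tree_and_matrix(rng, 7)
        mine = bipartitions(nj_tree(dm))
        pdm_csv = ",".join([""] + list(dm.ids)) + "\n"
        for i, a in enumerate(dm.ids):
            pdm_csv += ",".join([a] + [str(dm[a, b]) for b in dm.ids]) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            io.StringIO(pdm_csv), delimiter=","
        )
        their_tree = pdm.nj_tree()
        theirs = set()
        leaves = frozenset(t.taxon.label for t in their_tree.leaf_node_iter())
        for edge in their_tree.preorder_edge_iter():
            node = edge.head_node
            if node.is_leaf() or node.parent_node is None:
                continue
            clade = frozenset(t.taxon.label for t in node.leaf_iter())
            if 1 < len(clade) < len(leaves) - 1:
                other = leaves - clade
                theirs.add(clade if min(clade) > min(other) else other)
        assert mine == theirs

    def test_three_taxa_ultrametric(self):
        dm = DistanceMatrix(
            [[0.0, 2.0, 2.0], [2.0, 0.0, 2.0], [2.0, 2.0, 0.0]], ids=list("abc")
        )
        tree = nj_tree(dm)
        assert {t.name for t in tree.tips()} == set("abc")

    def test_negative_branch_lengths_clamped(self, rng):
        dm = DistanceMatrix(
            [[0.0, 1.0, 4.0, 4.1], [1.0, 0.0, 4.2, 4.4], [4.0, 4.2, 0.0, 0.3],
             [4.1, 4.4, 0.3, 0.0]],
            ids=list("abcd"),
        )
        tree = nj_tree(dm)
        assert all((n.length or 0.0) >= 0.0 for n in tree.traverse())

    def test_two_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0.0, 1.0], [1.0, 0.0]]), ids=["a", "b"])

    def test_asymmetric_matrix_rejected(self):
        bad = np.array([[0.0, 1.0, 2.0], [1.5, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError):
            nj_tree(bad, ids=list("abc"))


class TestBootstrap:
    def _two_cluster_alignment(self, rng):
        a = _random_sequence(rng, 120)
        b = _random_sequence(rng, 120)
        aln = {}
        for i in range(4):
            aln[f"a{i}"] = _mutate(rng, a, 0.05)
            aln[f"b{i}"] = _mutate(rng, b, 0.05)
        return aln

    def test_separated_clusters_get_high_support(self, rng):
        aln = self._two_cluster_alignment(rng)
        tree = bootstrap_support(aln, n_reps=100, seed=5)
        cluster = frozenset(f"a{i}" for i in range(4))
        complement = frozenset(f"b{i}" for i in range(4))
        supports = {
            frozenset(t.name for t in node.tips()): node.support
            for node in tree.non_tips(include_self=False)
        }
        split_support = max(
            supports.get(cluster, 0.0), supports.get(complement, 0.0)
        )
        assert split_support >= 0.95

    def test_seeded_repeat_identical(self, rng):
        aln = self._two_cluster_alignment(rng)
        t1 = bootstrap_support(aln, n_reps=50, seed=9)
        t2 = bootstrap_support(aln, n_reps=50, seed=9)
        s1 = sorted(n.support for n in t1.non_tips(include_self=False))
        s2 = sorted(n.support for n in t2.non_tips(include_self=False))
        assert s1 == s2

    def test_identical_sequences_give_no_supported_clade(self, rng):
        seq = _random_sequence(rng, 80)
        aln = {f"s{i}": seq for i in range(5)}
        tree = bootstrap_support(aln, n_reps=50, seed=1)
        assert all(
            (node.support or 0.0) <= 0.5 for node in tree.non_tips(include_self=False)
        )

    def test_newick_includes_supports(self, rng):
        aln = self._two_cluster_alignment(rng)
        tree = bootstrap_support(aln, n_reps=20, seed=2)
        text = tree_to_newick(tree)
        assert text.startswith("(") and "a0" in text

    def test_kimura_distance_increases_with_divergence(self, rng):
        base = _random_sequence(rng, 200)
        aln = {
            "x": base,
            "near": _mutate(rng, base, 0.05),
            "far": _mutate(rng, base, 0.4),
        }
        dm = kimura_distance_matrix(aln)
        assert dm["x", "near"] < dm["x", "far"]


class TestAssignByClade:
    def _tree(self, newick, supports):
        tree = TreeNode.read([newick])
        for node in tree.non_tips(include_self=False):
            clade = frozenset(t.name for t in node.tips())
            node.support = supports.get(clade, 0.0)
            node.length = node.length if node.length is not None else 1.0
        return tree

    def test_query_in_supported_unanimous_clade(self):
        tree = self._tree(
            "((q:1,(d1:1,d2:1):1):1,(x1:1,x2:1):1);",
            {frozenset({"q", "d1", "d2"}): 0.9, frozenset({"d1", "d2"}): 0.8,
             frozenset({"x1", "x2"}): 0.9},
        )
        anchors = {"d1": "DnaE3", "d2": "DnaE3", "x1": "DnaE1", "x2": "DnaE1"}
        assert assign_by_clade(tree, anchors, "q") == "DnaE3"

    def test_mixed_anchor_clade_gives_none(self):
        tree = self._tree(
            "((q:1,(d1:1,e1:1):1):1,(x1:1,x2:1):1);",
            {frozenset({"q", "d1", "e1"}): 0.9, frozenset({"d1", "e1"}): 0.95,
             frozenset({"x1", "x2"}): 0.9},
        )
        anchors = {"d1": "DnaE3", "e1": "DnaE1", "x1": "DnaE1", "x2": "DnaE1"}
        assert assign_by_clade(tree, anchors, "q") is None

    def test_all_low_support_gives_none(self):
        tree = self._tree(
            "((q:1,(d1:1,d2:1):1):1,(x1:1,x2:1):1);",
            {},
        )
        anchors = {"d1": "DnaE3", "d2": "DnaE3", "x1": "DnaE1", "x2": "DnaE1"}
        assert assign_by_clade(tree, anchors, "q") is None

    def test_missing_query_raises(self):
        tree = self._tree("((a:1,b:1):1,(c:1,d:1):1);", {})
        with pytest.raises(KeyError):
            assign_by_clade(tree, {}, "zz")
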