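"""Pigeonhole trees: CCF conversion, worked topologies vs exhaustive search,
seeding calls, and the bundled 10-case cohort."""

import itertools

import numpy as np
import pandas as pd
import pytest

from clonality.pigeonhole import (
    CCFClusterSet,
    build_tree,
    ccf_from_vaf,
    classify_seeding,
    cluster_ccf,
    load_ten_case_cohort,
    tree_to_newick,
)
from clonality.simdata import substream


def make_clusters(rows, patient="P"):
    df = pd.DataFrame(rows, columns=["cluster", "n_mutations", "ccf_primary", "ccf_met"])
    return CCFClusterSet(df.set_index("cluster"), patient)


def edges(tree):
    return set(tree.edges())


# --- exhaustive-search oracle over rooted topologies ----------------------


def oracle_trees(clusters: pd.DataFrame, trunk, tolerance=0.1):
    """All rooted trees on the clusters (trunk as root) satisfying the
    pigeonhole constraint in both samples, by brute force over parent maps."""
    others = [c for c in clusters.index if c != trunk]
    valid = []
    for parents in itertools.product(clusters.index, repeat=len(others)):
        pmap = dict(zip(others, parents))
        if any(p == c for c, p in pmap.items()):
            continue
        # must be a tree rooted at trunk (no cycles)
        ok = True
        for c in others:
            seen, cur = set(), c
            while cur != trunk:
                if cur in seen or cur not in pmap:
                    ok = False
                    break
                seen.add(cur)
                cur = pmap[cur]
            if not ok:
                break
        if not ok:
            continue
        for s in ("ccf_primary", "ccf_met"):
            for parent in clusters.index:
                kids = [c for c, p in pmap.items() if p == parent]
                if kids:
                    if sum(clusters.loc[k, s] for k in kids) > clusters.loc[parent, s] + tolerance:
                        ok = False
                if any(clusters.loc[k, s] > clusters.loc[parent, s] + tolerance for k in kids):
                    ok = False
        if ok:
            valid.append(frozenset((p, c) for c, p in pmap.items()))
    return valid


def test_ccf_conversion():
    assert ccf_from_vaf([0.25], purity=1.0)[0] == pytest.approx(0.5)
    assert ccf_from_vaf([0.5], purity=0.5)[0] == 1.0  # clamped
    with pytest.raises(ValueError):
        ccf_from_vaf([0.8])
    with pytest.raises(ValueError):
        ccf_from_vaf([0.1], purity=0.0)


def test_single_cluster_tree():
    cs = make_clusters([("A", 10, 1.0, 1.0)])
    tree = build_tree(cs)
    assert list(tree.nodes) == ["A"] and not edges(tree)
    assert tree.nodes["A"]["branch_length"] == 1.0


def test_forced_chain_matches_exhaustive_search():
    rows = [("A", 40, 1.0, 1.0), ("B", 30, 0.6, 0.9), ("C", 30, 0.5, 0.8)]
    cs = make_clusters(rows)
    tree = build_tree(cs, tolerance=0.1)
    assert edges(tree) == {("A", "B"), ("B", "C")}
    valid = oracle_trees(cs.clusters, "A")
    # the branching topology violates the pigeonhole constraint (B + C
    # exceed A in the metastasis); only nested chains survive, and the
    # builder orients the chain by decreasing CCF
    assert frozenset({("A", "B"), ("A", "C")}) not in valid
    assert frozenset({("A", "B"), ("B", "C")}) in valid
    assert all(("A", "B") in v or ("A", "C") in v for v in valid)
    assert classify_seeding(tree).mode == "monoclonal"


def test_branching_matches_exhaustive_search():
    rows = [("A", 50, 1.0, 1.0), ("B", 30, 0.6, 0.7), ("C", 20, 0.3, 0.2)]
    cs = make_clusters(rows)
    tree = build_tree(cs, tolerance=0.1)
    assert edges(tree) == {("A", "B"), ("A", "C")}
    valid = oracle_trees(cs.clusters, "A")
    # both the branch and the nested chain are consistent; the builder picks
    # the maximally branched one
    assert frozenset({("A", "B"), ("A", "C")}) in valid
    assert len(valid) >= 2
    assert classify_seeding(tree).mode == "polyclonal"


def test_branch_lengths_sum_to_one_and_are_label_invariant():
    rows = [("A", 40, 1.0, 1.0), ("B", 30, 0.6, 0.9), ("C", 30, 0.5, 0.8)]
    tree = build_tree(make_clusters(rows))
    total = sum(tree.nodes[n]["branch_length"] for n in tree.nodes)
    assert total == pytest.approx(1.0)
    renamed = [("X", 40, 1.0, 1.0), ("Y", 30, 0.6, 0.9), ("Z", 30, 0.5, 0.8)]
    tree2 = build_tree(make_clusters(renamed))
    assert sorted(tree.nodes[n]["branch_length"] for n in tree.nodes) == sorted(
        tree2.nodes[n]["branch_length"] for n in tree2.nodes
    )


def test_classify_seeding_cases():
    # only the trunk is present in the metastasis
    cs = make_clusters([("A", 10, 1.0, 1.0), ("B", 5, 0.5, 0.0)])
    assert classify_seeding(build_tree(cs)).mode == "monoclonal"
    # nothing present -> undefined with warning
    cs2 = make_clusters([("A", 10, 1.0, 1.0)])
    tree2 = build_tree(cs2)
    tree2.nodes["A"]["ccf_met"] = 0.0
    with pytest.warns(UserWarning, match="undefined"):
        assert classify_seeding(tree2).mode == "undefined"


def test_seeding_lineages_are_branch_tips():
    rows = [("A", 50, 1.0, 1.0), ("B", 30, 0.6, 0.7), ("C", 20, 0.3, 0.2)]
    call = classify_seeding(build_tree(make_clusters(rows)))
    assert call.seeding_lineages == ["B", "C"]
    assert call.met_present == ["A", "B", "C"]


def test_newick_export():
    rows = [("A", 50, 1.0, 1.0), ("B", 30, 0.6, 0.7), ("C", 20, 0.3, 0.2)]
    nwk = tree_to_newick(build_tree(make_clusters(rows)))
    assert nwk.startswith("(") and nwk.endswith(";")
    assert "B:0.3" in nwk and "A:0.5" in nwk


def test_cluster_ccf_recovers_planted_clusters():
    rng = substream(4, "ccf")
    true = np.array([[1.0, 1.0], [0.6, 0.9], [0.2, 0.05]])
    sizes = [60, 40, 40]
    pts = np.vstack(
        [t + rng.normal(0, 0.02, size=(s, 2)) for t, s in zip(true, sizes)]
    )
    pts = np.clip(pts, 0, 1)
    cs = cluster_ccf(pts[:, 0] / 2, pts[:, 1] / 2, random_state=0)
    assert len(cs.clusters) == 3
    got = cs.clusters.sort_values("ccf_primary", ascending=False)
    assert np.allclose(got[["ccf_primary", "ccf_met"]].to_numpy(), true, atol=0.05)
    assert sorted(got["n_mutations"]) == sorted(sizes)


def test_cluster_ccf_all_clonal_single_trunk():
    vaf = np.full(50, 0.5)
    cs = cluster_ccf(vaf, vaf)
    assert len(cs.clusters) == 1
    assert cs.trunk == cs.clusters.index[0]
    with pytest.raises(ValueError):
        cluster_ccf([], [])


def test_ten_case_cohort_reproduces_six_polyclonal():
    cohort = load_ten_case_cohort()
    assert len(cohort) == 10
    calls = {p: classify_seeding(build_tree(cs)).mode for p, cs in cohort.items()}
    poly = {p for p, m in calls.items() if m == "polyclonal"}
    assert len(poly) == 6
    assert poly == {"P2", "P3", "P5", "P6", "P7", "P9"}


def test_cluster_accuracy_with_ccf_noise():
    """>= 90% mono/poly accuracy on noisy cluster configurations
    (>= 40 mutations per cluster, CCF noise sd 0.05)."""
    rng = substream(8, "noisy-clusters")
    correct = total = 0
    for rep in range(50):
        for mode in ("monoclonal", "polyclonal"):
            if mode == "monoclonal":
                base = [("A", 50, 1.0, 1.0), ("B", 45, 0.6, 0.9), ("C", 40, 0.5, 0.8)]
            else:
                base = [("A", 50, 1.0, 1.0), ("B", 45, 0.55, 0.55), ("C", 40, 0.3, 0.4)]
            rows = [
                (c, n, float(np.clip(p + rng.normal(0, 0.05), 0, 1)),
                 float(np.clip(m + rng.normal(0, 0.05), 0, 1)))
                for c, n, p, m in base
            ]
            rows[0] = ("A", 50, 1.0, 1.0)  # trunk stays clonal
            call = classify_seeding(build_tree(make_clusters(rows)))
            correct += call.mode == mode
            total += 1
    assert correct / total >= 0.9


def test_cluster_set_validation():
    with pytest.raises(ValueError):
        make_clusters([("A", 0, 1.0, 1.0)])
    with pytest.raises(ValueError):
        make_clusters([("A", 5, 1.4, 1.0)])
    cs = make_clusters([("A", 5, 0.4, 0.3)])
    with pytest.raises(ValueError, match="trunk"):
        _ = cs.trunk
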