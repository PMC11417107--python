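"""Subclonal reconstruction from paired primary/metastasis CCF clusters.

Mutations are summarized as clusters of cancer cell fraction (CCF) pairs —
one CCF per sample (primary, metastasis).  The pigeonhole principle
constrains the tree: within every sample, subclones attached to the same
parent cannot jointly exceed the parent's CCF (two siblings whose CCFs sum
above the parent must occupy overlapping cell populations, forcing a nested
chain instead).  Trees are built maximally branched subject to that
constraint; branch lengths are the fraction of all mutations carried by the
cluster.  A metastasis is called monoclonally seeded when every cluster
present in the metastasis lies on a single root-to-leaf path, polyclonally
seeded when the present clusters span two or more distinct branches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "CCFClusterSet",
    "SeedingCall",
    "ccf_from_vaf",
    "cluster_ccf",
    "build_tree",
    "classify_seeding",
    "tree_to_newick",
    "load_ten_case_cohort",
]

SAMPLES = ("ccf_primary", "ccf_met")


@dataclass
class CCFClusterSet:
    """Clusters of mutations with per-sample CCFs for one patient."""

    clusters: pd.DataFrame  # index cluster id; n_mutations, ccf_primary, ccf_met
    patient: str = "patient"
    clonal_threshold: float = 0.8

    def __post_init__(self):
        c = self.clusters
        if c.index.has_duplicates:
            raise ValueError("cluster ids must be unique")
        if (c["n_mutations"] < 1).any():
            raise ValueError("every cluster must carry >= 1 mutation")
        for s in SAMPLES:
            if ((c[s] < 0) | (c[s] > 1 + 1e-9)).any():
                raise ValueError(f"{s} must lie in [0, 1]")

    @property
    def trunk(self):
        c = self.clusters
        clonal = c[(c[list(SAMPLES)] >= self.clonal_threshold).all(axis=1)]
        if clonal.empty:
            raise ValueError(
                f"{self.patient}: no clonal (trunk) cluster with CCF >= "
                f"{self.clonal_threshold} in both samples"
            )
        # estimated clusters can yield several near-clonal groups; the trunk
        # is the largest-CCF one (ties broken by mutation count)
        key = clonal["ccf_primary"] + clonal["ccf_met"] + 1e-9 * clonal["n_mutations"]
        return key.idxmax()


@dataclass
class SeedingCall:
    mode: str  # "monoclonal" | "polyclonal" | "undefined"
    seeding_lineages: list  # maximal metastasis-present branch tips
    met_present: list
    tree: nx.DiGraph = field(repr=False)


def ccf_from_vaf(vaf, purity: float = 1.0) -> np.ndarray:
    """CCF = min(1, 2 VAF / purity): diploid, copy-neutral conversion."""
    if not (0 < purity <= 1):
        raise ValueError("purity must lie in (0, 1]")
    vaf = np.asarray(vaf, dtype=float)
    if ((vaf < 0) | (vaf > 0.5 + 0.1)).any():
        raise ValueError("VAFs must lie in [0, ~0.5] for copy-neutral loci")
    return np.minimum(1.0, 2.0 * vaf / purity)


def cluster_ccf(
    vaf_primary,
    vaf_met,
    purity: tuple[float, float] = (1.0, 1.0),
    max_k: int = 6,
    patient: str = "patient",
    random_state: int = 0,
    min_spread: float = 0.1,
    clonal_threshold: float = 0.8,
    extra_vafs=None,
) -> CCFClusterSet:
    """K-means clustering of (primary, metastasis) CCF pairs with K chosen
    by silhouette; a single cluster is returned when the points span less
    than ``min_spread`` in every dimension.

    ``extra_vafs`` (mutations x additional samples, e.g. per-region VAFs)
    join the clustering space — two branches with identical pooled-primary
    and metastasis CCFs are separable only through such extra samples — but
    the reported cluster CCFs remain (primary, metastasis).
    """
    vaf_primary = np.asarray(vaf_primary, dtype=float)
    vaf_met = np.asarray(vaf_met, dtype=float)
    if vaf_primary.size == 0 or vaf_primary.shape != vaf_met.shape:
        raise ValueError("need matched, non-empty VAF vectors")
    X = np.column_stack(
        [ccf_from_vaf(vaf_primary, purity[0]), ccf_from_vaf(vaf_met, purity[1])]
    )
    feats = X
    if extra_vafs is not None:
        extra = np.atleast_2d(np.asarray(extra_vafs, dtype=float))
        if extra.shape[0] != len(X):
            extra = extra.T
        feats = np.column_stack([X, np.minimum(1.0, 2.0 * extra)])
    n = len(X)
    spread = feats.max(axis=0) - feats.min(axis=0)
    if n == 1 or (spread < min_spread).all():
        labels = np.zeros(n, dtype=int)
    else:
        best = (None, -np.inf)
        for k in range(2, min(max_k, n - 1) + 1):
            km = KMeans(n_clusters=k, n_init=10, random_state=random_state).fit(feats)
            if len(np.unique(km.labels_)) < 2:
                continue
            score = silhouette_score(feats, km.labels_)
            if score > best[1]:
                best = (km.labels_, score)
        labels = best[0] if best[0] is not None else np.zeros(n, dtype=int)
    rows = []
    for lab in np.unique(labels):
        sel = labels == lab
        rows.append(
            {
                "cluster": f"c{lab}",
                "n_mutations": int(sel.sum()),
                "ccf_primary": float(np.clip(X[sel, 0].mean(), 0, 1)),
                "ccf_met": float(np.clip(X[sel, 1].mean(), 0, 1)),
            }
        )
    clusters = pd.DataFrame(rows).set_index("cluster")
    return CCFClusterSet(clusters, patient, clonal_threshold)


def build_tree(cluster_set: CCFClusterSet, tolerance: float = 0.1) -> nx.DiGraph:
    """Pigeonhole tree: every cluster is attached to the shallowest
    (largest-CCF) parent for which, in every sample, the parent's children
    CCFs (including the new child) sum to at most the parent CCF +
    ``tolerance`` — maximally branched subject to the constraint.  A cluster
    with no valid parent is attached to the trunk with a violation flag.
    Branch lengths are mutation proportions and sum to 1."""
    c = cluster_set.clusters
    trunk = cluster_set.trunk
    total = c["n_mutations"].sum()
    tree = nx.DiGraph()
    for cid, row in c.iterrows():
        tree.add_node(
            cid,
            ccf_primary=float(row["ccf_primary"]),
            ccf_met=float(row["ccf_met"]),
            n_mutations=int(row["n_mutations"]),
            branch_length=float(row["n_mutations"] / total),
            violation=False,
        )
    # process in decreasing CCF order so parents are placed before children
    order = c.assign(_key=c[list(SAMPLES)].sum(axis=1)).drop(index=trunk).sort_values(
        "_key", ascending=False, kind="stable"
    )
    placed = [trunk]
    for cid, row in order.iterrows():
        valid = []
        for p in placed:
            ok = True
            for s in SAMPLES:
                child_sum = row[s] + sum(
                    tree.nodes[k][s] for k in tree.successors(p)
                )
                if row[s] > tree.nodes[p][s] + tolerance or child_sum > tree.nodes[p][s] + tolerance:
                    ok = False
                    break
            if ok:
                valid.append(p)
        if valid:
            # shallowest valid parent: largest combined CCF, trunk wins ties
            parent = max(
                valid,
                key=lambda p: (tree.nodes[p]["ccf_primary"] + tree.nodes[p]["ccf_met"], p == trunk),
            )
        else:
            warnings.warn(
                f"{cluster_set.patient}: no pigeonhole-consistent parent for "
                f"cluster {cid}; attached to trunk with violation flag"
            )
            parent = trunk
            tree.nodes[cid]["violation"] = True
        tree.add_edge(parent, cid)
        placed.append(cid)
    _check_pigeonhole(tree, tolerance)
    return tree


def _check_pigeonhole(tree: nx.DiGraph, tolerance: float) -> None:
    for node in tree.nodes:
        if tree.nodes[node].get("violation"):
            continue
        kids = [k for k in tree.successors(node) if not tree.nodes[k].get("violation")]
        for s in SAMPLES:
            child_sum = sum(tree.nodes[k][s] for k in kids)
            assert child_sum <= tree.nodes[node][s] + tolerance + 1e-9, (
                f"pigeonhole constraint violated at {node} in {s}"
            )


def classify_seeding(tree: nx.DiGraph, presence_threshold: float = 0.05) -> SeedingCall:
    """Monoclonal iff the metastasis-present clusters lie on one root-to-leaf
    path; polyclonal iff they span >= 2 branches not in ancestor-descendant
    relation."""
    present = [n for n in tree.nodes if tree.nodes[n]["ccf_met"] > presence_threshold]
    if not present:
        warnings.warn("no metastasis-present cluster: seeding call undefined")
        return SeedingCall("undefined", [], [], tree)
    anc = {n: nx.ancestors(tree, n) | {n} for n in present}
    on_one_path = all(
        (a in anc[b]) or (b in anc[a]) for i, a in enumerate(present) for b in present[i + 1:]
    )
    tips = [n for n in present if not any(m != n and n in anc[m] for m in present)]
    mode = "monoclonal" if on_one_path else "polyclonal"
    return SeedingCall(mode, sorted(tips), sorted(present), tree)


def tree_to_newick(tree: nx.DiGraph) -> str:
    root = [n for n in tree.nodes if tree.in_degree(n) == 0]
    if len(root) != 1:
        raise ValueError("tree must have a single root")

    def rec(node) -> str:
        kids = sorted(tree.successors(node))
        label = f"{node}:{tree.nodes[node]['branch_length']:.6f}"
        if not kids:
            return label
        return "(" + ",".join(rec(k) for k in kids) + ")" + label

    return rec(root[0]) + ";"


def load_ten_case_cohort() -> dict[str, CCFClusterSet]:
    """Bundled 10-patient primary/metastasis cluster cohort (synthetic,
    generated to match the published cluster configurations: 4 monoclonally
    and 6 polyclonally seeded cases).  Keys P1..P10."""
    with resources.files("clonality.fixtures").joinpath("cohort10.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    out = {}
    for patient, grp in df.groupby("patient", sort=False):
        out[str(patient)] = CCFClusterSet(
            grp.set_index("cluster")[["n_mutations", "ccf_primary", "ccf_met"]],
            str(patient),
        )
    return out
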