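"""Cell-pair similarity, tissue heterogeneity, origin tracing and clustering.

The binary pair statistic R compares two cells over the candidate sites:
R = -1 iff at least one site is determinably mutant in one cell and wild
type in the other; R = +1 otherwise (CND is compatible with anything, so a
pair with no informative site is "the same").  The similarity index of a
tissue is the average R over all unordered cell pairs; H is the fraction of
discordant pairs, so index = 1 - 2 H exactly.

Because R is binary it cannot rank candidate source regions, so origin
tracing uses the graded concordance (fraction of informative sites with
equal status) to pick each metastatic cell's best-matching primary cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .cohort_stats import fisher_exact_2x2
from .genotyper import CND, MUT, WT, StatusMatrix

__all__ = [
    "SimilarityResult",
    "TissueHeterogeneity",
    "OriginAssignment",
    "pair_similarity",
    "tissue_heterogeneity",
    "exclude_normal_cells",
    "trace_origin",
    "count_met_lineages",
    "classify_seeding_from_cells",
    "cluster_and_embed",
    "concordance_matrix",
]


@dataclass(frozen=True)
class SimilarityResult:
    R: int  # +1 or -1
    n_informative: int
    concordance: float  # over informative sites; NaN if none


@dataclass
class TissueHeterogeneity:
    similarity_index: float  # mean R over unordered pairs, in [-1, 1]
    H: float  # fraction of discordant pairs
    n_pairs: int
    pair_R: np.ndarray  # per-pair R values (condensed order)


@dataclass
class OriginAssignment:
    assignments: pd.DataFrame  # per met cell: region, concordance, tie, n_informative
    region_counts: pd.Series
    p_value: float  # Fisher 2x2 enrichment of the grouped regions
    grouped_regions: tuple[str, ...]


def pair_similarity(status_a, status_b) -> SimilarityResult:
    """R statistic and graded concordance for one cell pair.

    Inputs are equal-length status code vectors over the same site ordering.
    """
    a = np.asarray(status_a, dtype=np.int8)
    b = np.asarray(status_b, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("mismatched site sets")
    informative = (a != CND) & (b != CND)
    n_inf = int(informative.sum())
    conflict = bool((informative & (a != b)).any())
    conc = float((a[informative] == b[informative]).mean()) if n_inf else float("nan")
    return SimilarityResult(-1 if conflict else 1, n_inf, conc)


def _indicators(codes: np.ndarray):
    return (codes == MUT).astype(np.float64), (codes == WT).astype(np.float64)


def _conflict_matrix(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    """Boolean matrix: pair (i, j) has >= 1 site MUT in one and WT in the other."""
    mut_a, wt_a = _indicators(codes_a)
    mut_b, wt_b = _indicators(codes_b)
    return (mut_a @ wt_b.T + wt_a @ mut_b.T) > 0.5


def concordance_matrix(codes_a: np.ndarray, codes_b: np.ndarray):
    """(concordance, n_informative) matrices between two sets of cells.

    Both statuses must be determinable for a site to be informative; the
    concordance is the fraction of informative sites with equal status.
    """
    mut_a, wt_a = _indicators(codes_a)
    mut_b, wt_b = _indicators(codes_b)
    equal = mut_a @ mut_b.T + wt_a @ wt_b.T
    n_inf = (mut_a + wt_a) @ (mut_b + wt_b).T
    with np.errstate(invalid="ignore"):
        conc = np.where(n_inf > 0, equal / np.maximum(n_inf, 1), np.nan)
    return conc, n_inf.astype(int)


def tissue_heterogeneity(
    status: StatusMatrix, by: str = "tissue"
) -> dict[str, TissueHeterogeneity]:
    """Similarity index and H per tissue (or any cell-metadata grouping)."""
    out: dict[str, TissueHeterogeneity] = {}
    for tissue, group in status.cells.groupby(by, sort=True):
        if len(group) < 2:
            warnings.warn(f"{tissue}: fewer than 2 cells, heterogeneity undefined")
            out[str(tissue)] = TissueHeterogeneity(
                float("nan"), float("nan"), 0, np.empty(0)
            )
            continue
        codes = status.codes[status.cells.index.isin(group.index)]
        conflict = _conflict_matrix(codes, codes)
        iu = np.triu_indices(len(codes), k=1)
        pair_r = np.where(conflict[iu], -1, 1)
        h = float((pair_r == -1).mean())
        out[str(tissue)] = TissueHeterogeneity(
            float(pair_r.mean()), h, len(pair_r), pair_r
        )
    return out


def exclude_normal_cells(
    status: StatusMatrix,
    driver_genes: tuple[str, ...] = ("APC", "TP53"),
    max_normal_burden: int = 2,
) -> tuple[StatusMatrix, list[str]]:
    """Drop presumed normal (stromal/immune) cells: very few mutations AND no
    mutation in a driver gene.  Returns (tumor-cell subset, excluded cells)."""
    if not driver_genes:
        raise ValueError("driver_genes must be non-empty")
    codes = status.codes
    burden = (codes == MUT).sum(axis=1)
    in_driver = status.sites["gene"].isin(driver_genes).to_numpy()
    has_driver_mut = (codes[:, in_driver] == MUT).any(axis=1)
    normal = (burden <= max_normal_burden) & ~has_driver_mut
    excluded = list(status.cells.index[normal])
    return status.subset_cells(status.cells.index[~normal]), excluded


def trace_origin(
    status: StatusMatrix,
    met_tissue: str,
    primary_regions: list[str] | None = None,
    min_informative: int = 5,
    region_grouping: tuple[str, ...] | None = None,
) -> OriginAssignment:
    """Assign each metastatic cell to the primary region of its
    maximum-concordance primary cell.

    Ties across regions are broken by larger informative-site count, then by
    lexicographic region label (tie flag set).  Enrichment of the grouped
    source regions (default: the top region by assignment count) against the
    primary sampling composition is a two-sided Fisher 2x2 test.
    """
    is_met = (status.cells["tissue"] == met_tissue).to_numpy()
    if primary_regions is None:
        if "is_met" in status.cells.columns:
            prim_mask = ~status.cells["is_met"].astype(bool).to_numpy()
        else:
            prim_mask = ~is_met & (status.cells["region"] != met_tissue).to_numpy()
        primary_regions = sorted(status.cells.loc[prim_mask, "region"].unique())
    is_prim = status.cells["region"].isin(primary_regions).to_numpy()
    if not is_prim.any():
        raise ValueError("no primary cells available")
    met_codes = status.codes[is_met]
    prim_codes = status.codes[is_prim]
    prim_regions = status.cells.loc[is_prim, "region"].to_numpy()
    conc, n_inf = concordance_matrix(met_codes, prim_codes)
    conc = np.where(n_inf >= min_informative, conc, np.nan)

    rows = []
    met_cells = status.cells.index[is_met]
    for i, cell in enumerate(met_cells):
        row_conc, row_inf = conc[i], n_inf[i]
        if np.isnan(row_conc).all():
            rows.append((cell, None, np.nan, 0, False))
            continue
        best = np.nanmax(row_conc)
        at_best = np.flatnonzero(np.isclose(row_conc, best, rtol=0, atol=1e-12))
        best_regions = sorted(set(prim_regions[at_best]))
        tie = len(best_regions) > 1
        if tie:
            # larger informative count first, then lexicographic region
            inf_by_region = {
                r: row_inf[at_best][prim_regions[at_best] == r].max() for r in best_regions
            }
            top_inf = max(inf_by_region.values())
            best_regions = sorted(r for r, v in inf_by_region.items() if v == top_inf)
        rows.append((cell, best_regions[0], float(best), int(row_inf[at_best].max()), tie))
    assignments = pd.DataFrame(
        rows, columns=["cell", "region", "concordance", "n_informative", "tie"]
    ).set_index("cell")

    assigned = assignments.dropna(subset=["region"])
    region_counts = (
        assigned["region"].value_counts().reindex(primary_regions, fill_value=0)
    )
    if region_grouping is None:
        region_grouping = (region_counts.idxmax(),) if len(assigned) else ()
    in_group = assigned["region"].isin(region_grouping)
    prim_counts = status.cells.loc[is_prim, "region"].value_counts()
    prim_in = int(prim_counts.reindex(list(region_grouping), fill_value=0).sum())
    table = [
        [int(in_group.sum()), int((~in_group).sum())],
        [prim_in, int(prim_counts.sum() - prim_in)],
    ]
    p = fisher_exact_2x2(table) if len(assigned) else float("nan")
    return OriginAssignment(assignments, region_counts, p, tuple(region_grouping))


def count_met_lineages(
    status: StatusMatrix,
    met_tissue: str,
    distance_threshold: float = 0.15,
    min_cluster_size: int = 2,
) -> int:
    """Number of distinct genetic lineages among metastatic cells.

    Average-linkage clustering on the CND-aware distance 1 - concordance,
    cut at ``distance_threshold``; clusters smaller than ``min_cluster_size``
    (noisy singletons) are not counted as lineages.
    """
    codes = status.codes[(status.cells["tissue"] == met_tissue).to_numpy()]
    if len(codes) < 2:
        return min(len(codes), 1)
    conc, _ = concordance_matrix(codes, codes)
    dist = 1.0 - np.nan_to_num(conc, nan=0.5)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=distance_threshold, criterion="distance")
    sizes = pd.Series(labels).value_counts()
    n = int((sizes >= min_cluster_size).sum())
    return max(n, 1)


def classify_seeding_from_cells(
    status: StatusMatrix,
    met_tissue: str,
    h_tolerance: float = 0.1,
    distance_threshold: float = 0.15,
) -> dict:
    """Mono/polyclonal call for one metastasis from single-cell evidence.

    Polyclonal iff the metastasis contains >= 2 distinct lineages and its H
    is within ``h_tolerance`` of the H of its traced source region (a
    polyclonal metastasis mirrors the heterogeneity of the region that
    seeded it); otherwise monoclonal.
    """
    lineages = count_met_lineages(status, met_tissue, distance_threshold)
    origin = trace_origin(status, met_tissue)
    het = tissue_heterogeneity(status)
    h_met = het[met_tissue].H if met_tissue in het else float("nan")
    source = origin.grouped_regions[0] if origin.grouped_regions else None
    h_src = het[source].H if source in het else float("nan")
    h_close = bool(np.isfinite(h_met) and np.isfinite(h_src) and abs(h_met - h_src) <= h_tolerance)
    mode = "polyclonal" if (lineages >= 2 and h_close) else "monoclonal"
    return {
        "mode": mode,
        "n_lineages": lineages,
        "h_met": h_met,
        "h_source": h_src,
        "source_region": source,
        "origin_p": origin.p_value,
    }


def cluster_and_embed(
    status: StatusMatrix,
    distance: str = "concordance",
    linkage_method: str = "average",
    n_components: int = 2,
):
    """Hierarchical clustering + PCA of the mutation landscape.

    Distance between two cells is 1 - concordance (CND-aware; pairs with no
    informative site get the neutral distance 0.5).  PCA runs on the
    MUT=1/WT=0 encoding with CND imputed to the site mean.  Returns
    (linkage matrix, newick string, PCA coordinates DataFrame).
    """
    codes = status.codes
    if (codes == CND).all():
        raise ValueError("all-CND status matrix cannot be clustered")
    if len(codes) < 3:
        raise ValueError("need >= 3 cells")
    if distance != "concordance":
        raise ValueError(f"unknown distance {distance!r}")
    conc, _ = concordance_matrix(codes, codes)
    dist = 1.0 - np.nan_to_num(conc, nan=0.5)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2
    Z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    newick = _linkage_to_newick(Z, list(status.cells.index))

    X = np.where(codes == CND, np.nan, codes).astype(float)
    col_mean = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=0)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    X = np.where(np.isnan(X), col_mean, X)
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    coords = PCA(n_components=k, random_state=0).fit_transform(X)
    pca = pd.DataFrame(
        coords, index=status.cells.index, columns=[f"PC{i + 1}" for i in range(k)]
    )
    return Z, newick, pca


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6f}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6f}"

    return rec(tree, tree.dist) + ";"
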