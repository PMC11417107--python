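"""R statistic, tissue index vs brute force, normal-cell filter, tracing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster import hierarchy

from clonality.genotyper import CND, MUT, WT
from clonality.heterogeneity import (
    cluster_and_embed,
    count_met_lineages,
    exclude_normal_cells,
    pair_similarity,
    tissue_heterogeneity,
    trace_origin,
)
from tests.conftest import make_status


def test_pair_similarity_rules():
    # rule (a): CND is compatible with anything
    assert pair_similarity([MUT, WT, CND], [MUT, CND, MUT]).R == 1
    # rule (c): MUT vs WT at any site makes the pair different
    assert pair_similarity([MUT, WT], [WT, WT]).R == -1
    # all-CND cell matches anything with no informative sites
    res = pair_similarity([CND, CND], [MUT, WT])
    assert res.R == 1 and res.n_informative == 0 and np.isnan(res.concordance)
    with pytest.raises(ValueError):
        pair_similarity([MUT], [MUT, WT])


def test_pair_similarity_identity_and_symmetry():
    x = [MUT, WT, CND, MUT]
    res = pair_similarity(x, x)
    assert res.R == 1 and res.concordance == 1.0
    a, b = [MUT, WT, WT], [MUT, MUT, CND]
    ra, rb = pair_similarity(a, b), pair_similarity(b, a)
    assert ra == rb


def test_tissue_index_small_examples():
    # 3 identical cells
    het = tissue_heterogeneity(make_status([[MUT, WT]] * 3))
    assert het["T"].similarity_index == 1.0 and het["T"].H == 0.0
    # 2 conflicting cells
    het = tissue_heterogeneity(make_status([[MUT, WT], [WT, WT]]))
    assert het["T"].similarity_index == -1.0 and het["T"].H == 1.0
    # two 2-cell clones: 2 concordant pairs, 4 discordant -> index -1/3
    codes = [[MUT, WT], [MUT, WT], [WT, MUT], [WT, MUT]]
    het = tissue_heterogeneity(make_status(codes))
    assert het["T"].similarity_index == pytest.approx(-1 / 3)
    assert het["T"].H == pytest.approx(2 / 3)
    assert het["T"].n_pairs == 6


def test_single_cell_tissue_is_undefined():
    with pytest.warns(UserWarning, match="fewer than 2"):
        het = tissue_heterogeneity(make_status([[MUT]], tissues=["solo"]))
    assert np.isnan(het["solo"].similarity_index)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_tissue_index_equals_brute_force(data):
    n_cells = data.draw(st.integers(min_value=2, max_value=12))
    n_sites = data.draw(st.integers(min_value=1, max_value=60))
    codes = data.draw(
        st.lists(
            st.lists(st.sampled_from([MUT, WT, CND]), min_size=n_sites, max_size=n_sites),
            min_size=n_cells,
            max_size=n_cells,
        )
    )
    status = make_status(codes)
    het = tissue_heterogeneity(status)["T"]
    # oracle: explicit enumeration of all unordered pairs via pair_similarity
    rs = [
        pair_similarity(codes[i], codes[j]).R
        for i in range(n_cells)
        for j in range(i + 1, n_cells)
    ]
    assert het.similarity_index == pytest.approx(np.mean(rs))
    assert het.H == pytest.approx(np.mean([r == -1 for r in rs]))
    assert het.similarity_index == pytest.approx(1 - 2 * het.H)
    assert het.n_pairs == n_cells * (n_cells - 1) // 2


def test_exclude_normal_cells_conjunction_rule():
    genes = ["APC", "G1", "G2", "G3"]
    codes = [
        [WT, WT, WT, WT],          # 0 mutations, no driver -> excluded
        [MUT, MUT, WT, WT],        # 2 mutations incl. APC -> retained
        [WT, MUT, MUT, CND],       # 2 mutations, no driver -> excluded
        [WT] + [MUT] * 3,          # burden above threshold -> retained
    ]
    status = make_status(codes, genes=genes)
    tumor, excluded = exclude_normal_cells(status, driver_genes=("APC", "TP53"))
    assert excluded == ["cell0", "cell2"]
    assert list(tumor.cells.index) == ["cell1", "cell3"]
    with pytest.raises(ValueError):
        exclude_normal_cells(status, driver_genes=())


def test_trace_origin_exact_match_and_ties():
    tissues = ["region-1", "region-2", "met", "met"]
    codes = [
        [MUT, MUT, WT, WT],
        [WT, WT, MUT, MUT],
        [MUT, MUT, WT, WT],   # identical to the region-1 cell
        [CND, CND, CND, CND],  # uninformative -> unassigned
    ]
    status = make_status(codes, tissues=tissues, regions=tissues)
    origin = trace_origin(status, "met", min_informative=2)
    a = origin.assignments
    assert a.loc["cell2", "region"] == "region-1"
    assert a.loc["cell2", "concordance"] == 1.0
    assert a.loc["cell3", "region"] is None
    # tie: a met cell equally concordant with both regions
    codes_tie = [
        [MUT, WT],
        [WT, MUT],
        [MUT, MUT],
    ]
    status_tie = make_status(codes_tie, tissues=["region-1", "region-2", "met"],
                             regions=["region-1", "region-2", "met"])
    origin_tie = trace_origin(status_tie, "met", min_informative=1)
    row = origin_tie.assignments.iloc[0]
    assert bool(row["tie"]) and row["region"] == "region-1"


def test_trace_origin_recovers_true_regions(poly_case):
    from clonality.genotyper import build_status_matrix

    status = build_status_matrix(poly_case.reads, poly_case.noise, poly_case.cells)
    origin = trace_origin(status, "liver")
    # per-cell truth: the home region of the cell's clone
    prim = poly_case.cells[~poly_case.cells["is_met"]]
    home = {
        c: prim.loc[prim["clone"] == c, "region"].mode().iloc[0]
        for c in set(poly_case.cells.loc[poly_case.cells["is_met"], "clone"])
    }
    met_cells = poly_case.cells[poly_case.cells["is_met"] & (poly_case.cells["tissue"] == "liver")]
    correct = sum(
        origin.assignments.loc[cell, "region"] == home[clone]
        for cell, clone in met_cells["clone"].items()
    )
    assert correct / len(met_cells) >= 0.9


def test_met_lineage_count_discriminates_modes(mono_case, poly_case):
    from clonality.genotyper import build_status_matrix

    s_mono = build_status_matrix(mono_case.reads, mono_case.noise, mono_case.cells)
    s_poly = build_status_matrix(poly_case.reads, poly_case.noise, poly_case.cells)
    assert count_met_lineages(s_mono, "liver") == 1
    assert count_met_lineages(s_poly, "liver") >= 2


def test_cluster_and_embed_duplicates_and_planted_split():
    codes = [
        [MUT, MUT, WT, WT, WT],
        [MUT, MUT, WT, WT, WT],   # duplicate of cell0
        [WT, WT, MUT, MUT, MUT],
        [WT, WT, MUT, MUT, MUT],
    ]
    status = make_status(codes)
    Z, newick, pca = cluster_and_embed(status)
    # duplicates merge first at height zero
    assert Z[0, 2] == 0.0
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    assert labels[0] == labels[1] != labels[2] == labels[3]
    assert newick.endswith(";") and "cell0" in newick
    assert list(pca.columns) == ["PC1", "PC2"]


def test_pca_preserves_rank2_geometry():
    # rank-2 binary matrix: PCA with 2 components is an isometry of the
    # centered encoding, so pairwise distances are reproduced exactly
    codes = [
        [MUT, WT, WT],
        [WT, MUT, WT],
        [MUT, MUT, WT],
        [WT, WT, WT],
    ]
    status = make_status(codes)
    _, _, pca = cluster_and_embed(status, n_components=2)
    X = np.array([[1, 0, 0], [0, 1, 0], [1, 1, 0], [0, 0, 0]], dtype=float)
    Xc = X - X.mean(axis=0)

    def pdists(M):
        return np.linalg.norm(M[:, None, :] - M[None, :, :], axis=-1)

    assert np.allclose(pdists(pca.to_numpy()), pdists(Xc), atol=1e-9)


def test_all_cnd_matrix_refused():
    with pytest.raises(ValueError):
        cluster_and_embed(make_status([[CND, CND]] * 3))
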