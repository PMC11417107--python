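"""ADO-aware genotype model: posterior correctness, status calling, filters."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonality.genotyper import (
    CND,
    MUT,
    WT,
    build_status_matrix,
    call_status,
    filter_snvs,
    genotype_posterior,
    mutation_burden,
    site_fraction_concordance,
)
from clonality.simdata import NoiseRates, simulate_case
from tests.conftest import make_status


def direct_posterior(ref, alt, ado, eps, prior=(1 / 3, 1 / 3, 1 / 3)):
    """Independent evaluation of the stated likelihood (pure python floats)."""

    def binom(k, n, p):
        if p == 0.0:
            return 1.0 if k == 0 else 0.0
        if p == 1.0:
            return 1.0 if k == n else 0.0
        return math.comb(n, k) * p**k * (1 - p) ** (n - k)

    n = ref + alt
    l_rr = binom(alt, n, eps)
    l_aa = binom(ref, n, eps)
    l_ra = (
        (1 - ado) * binom(alt, n, 0.5)
        + ado / 2 * binom(alt, n, eps)
        + ado / 2 * binom(ref, n, eps)
    )
    post = [prior[0] * l_rr, prior[1] * l_ra, prior[2] * l_aa]
    z = sum(post)
    return [p / z for p in post]


def test_posterior_matches_direct_evaluation_on_grid():
    noise = NoiseRates(ado=0.103, fp=0.0, seq_error=0.005)
    for ref in range(0, 26, 5):
        for alt in range(0, 26, 5):
            got = genotype_posterior(ref, alt, noise).probs
            want = direct_posterior(ref, alt, noise.ado, noise.seq_error)
            assert np.allclose(got, want, atol=1e-12, rtol=0)


def test_no_data_returns_prior_exactly():
    prior = np.array([0.5, 0.3, 0.2])
    post = genotype_posterior(0, 0, NoiseRates(), prior=prior)
    assert np.allclose(post.probs, prior, atol=0, rtol=0)


def test_ref_alt_swap_symmetry():
    noise = NoiseRates(ado=0.2, seq_error=0.01)
    a = genotype_posterior(17, 3, noise).probs
    b = genotype_posterior(3, 17, noise).probs
    assert a[0] == pytest.approx(b[2], abs=1e-15)
    assert a[1] == pytest.approx(b[1], abs=1e-15)


def test_reduces_to_standard_caller_without_ado():
    noise = NoiseRates(ado=0.0, seq_error=0.01)
    for ref, alt in [(10, 0), (5, 5), (0, 12), (3, 1)]:
        got = genotype_posterior(ref, alt, noise).probs
        want = direct_posterior(ref, alt, 0.0, 0.01)
        assert np.allclose(got, want, atol=1e-13)


def test_high_depth_reference_calls_are_confident_rr():
    post = genotype_posterior(20, 0, NoiseRates(ado=0.1, seq_error=0.001))
    assert post.map_genotype == 0
    # the ADO term caps RR confidence near 1/(1 + ado/2)
    assert 0.94 < post.map_probability < 0.96


def test_negative_counts_refused():
    with pytest.raises(ValueError):
        genotype_posterior(-1, 2, NoiseRates())


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    ref=st.integers(min_value=0, max_value=500),
    alt=st.integers(min_value=0, max_value=500),
    ado=st.floats(min_value=0, max_value=0.5),
    eps=st.floats(min_value=1e-6, max_value=0.1),
)
def test_posterior_normalization_property(ref, alt, ado, eps):
    post = genotype_posterior(ref, alt, NoiseRates(ado=ado, seq_error=eps))
    assert abs(post.probs.sum() - 1.0) < 1e-12
    assert post.map_probability == pytest.approx(post.probs.max())


def test_call_status_thresholds():
    noise = NoiseRates()
    zero = genotype_posterior(0, 0, noise)
    status, zyg = call_status(zero, min_depth=5)
    assert status == CND and zyg == "unknown"
    het = genotype_posterior(15, 15, noise)
    status, zyg = call_status(het, min_depth=5, min_posterior=0.9)
    assert status == MUT and zyg == "RA"
    # confident RR but below a stricter threshold -> CND
    rr = genotype_posterior(8, 0, NoiseRates(ado=0.4))
    status, _ = call_status(rr, min_depth=5, min_posterior=0.9)
    assert status == CND


def test_filter_snvs_rules():
    # 3 cells x 3 sites: s0 MUT in 2 cells, s1 MUT in 3 cells, s2 in none
    status = make_status(
        [[MUT, MUT, WT], [MUT, MUT, WT], [WT, MUT, WT]]
    )
    support = pd.DataFrame(
        {"tissueA": [0, 0, 12]}, index=status.sites.index
    )
    assert "s0" not in filter_snvs(status, support, rule="OR")
    assert "s0" not in filter_snvs(status, support, rule="AND")
    assert "s1" in filter_snvs(status, support, rule="OR")
    assert "s1" not in filter_snvs(status, support, rule="AND")
    assert "s2" in filter_snvs(status, support, rule="OR")  # tissue reads alone
    with pytest.raises(ValueError):
        filter_snvs(status, None, rule="OR")
    with pytest.raises(ValueError):
        filter_snvs(status, support, rule="XOR")


def test_mutation_burden():
    codes = [[MUT] * 43 + [WT] * 7, [CND] * 50]
    status = make_status(codes)
    burden = mutation_burden(status, callable_mb=50.0)
    assert burden["rate_per_mb"].iloc[0] == pytest.approx(0.86)
    assert burden["n_mutations"].iloc[1] == 0
    assert bool(burden["all_cnd"].iloc[1])
    with pytest.raises(ValueError):
        mutation_burden(status, callable_mb=0)


def test_site_fractions_and_bulk_concordance():
    # 3 sites with single-cell fractions 1/2, 1/3, 1 among determinable cells
    codes = [
        [MUT, MUT, MUT],
        [WT, WT, MUT],
        [MUT, WT, MUT],
        [WT, CND, CND],
    ]
    status = make_status(codes, tissues=["T"] * 4)
    bulk = pd.DataFrame({"T": [0.5, 0.3, 0.9]}, index=status.sites.index)
    table, r = site_fraction_concordance(status, bulk)
    fr = table.set_index("site")["sc_fraction"]
    assert fr["s0"] == pytest.approx(1 / 2)
    assert fr["s1"] == pytest.approx(1 / 3)
    assert fr["s2"] == pytest.approx(1.0)
    # hand-computed Pearson of (0.5, 1/3, 1) against clamped 2x bulk (1, .6, 1)
    x = np.array([1 / 2, 1 / 3, 1.0])
    y = np.clip(np.array([0.5, 0.3, 0.9]) * 2, 0, 1)
    want = ((x - x.mean()) * (y - y.mean())).sum() / (
        np.sqrt(((x - x.mean()) ** 2).sum()) * np.sqrt(((y - y.mean()) ** 2).sum())
    )
    assert r == pytest.approx(want, abs=1e-12)


def test_perfectly_matching_fractions_give_r_one():
    codes = [[MUT, MUT, WT], [WT, MUT, WT], [MUT, CND, WT]]
    status = make_status(codes)
    fr = [2 / 3, 1.0, 0.0]
    bulk = pd.DataFrame({"T": [f / 2 for f in fr]}, index=status.sites.index)
    _, r = site_fraction_concordance(status, bulk)
    assert r == pytest.approx(1.0)


def test_genotype_accuracy_on_simulated_template():
    """>= 99% MAP accuracy at depth >= 20 against the amplified template."""
    case = simulate_case(seed=11, mean_depth=40, noise=NoiseRates(0.103, 2.68e-6, 0.005))
    post = genotype_posterior(case.reads.ref, case.reads.alt, case.noise)
    deep = post.depth >= 20
    acc = (post.map_genotype[deep] == case.template[deep]).mean()
    assert acc >= 0.99


def test_status_matrix_round_trip(tmp_path, poly_case):
    status = build_status_matrix(poly_case.reads, poly_case.noise, poly_case.cells)
    path = tmp_path / "status.tsv"
    status.write(path)
    text = path.read_text()
    assert "MUT" in text and "CND" in text
    from clonality.genotyper import StatusMatrix

    again = StatusMatrix.read(path, poly_case.cells, poly_case.reads.sites)
    assert np.array_equal(again.codes, status.codes)
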