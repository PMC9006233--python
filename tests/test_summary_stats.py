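"""Diversity, differentiation, richness, private alleles and Mantel tests."""

import inspect

import numpy as np
import pytest
from scipy.stats import kstest

from streampop import (
    MISSING,
    allelic_richness,
    bootstrap_fst_ci,
    diversity_stats,
    mantel_test,
    nei_gst,
    pairwise_fst_matrix,
    private_alleles,
    wc_fst,
    wc_fst_components,
)

from conftest import make_matrix, random_matrix


# ---------------------------------------------------------------------------
# scalar reference implementation of the Weir-Cockerham components
# (kept deliberately un-vectorized and independent of the package path)


def wc_components_scalar(genotype_lists):
    """Per-locus (a, b, c) from a list of per-population genotype lists."""
    n_loci = len(genotype_lists[0][0])
    out = []
    for j in range(n_loci):
        stats = []
        for pop in genotype_lists:
            calls = [ind[j] for ind in pop if ind[j] != MISSING]
            if not calls:
                continue
            n = len(calls)
            p = sum(calls) / (2 * n)
            h = sum(1 for c in calls if c == 1) / n
            stats.append((n, p, h))
        r = len(stats)
        if r < 2:
            out.append((0.0, 0.0, 0.0, False))
            continue
        n_sum = sum(s[0] for s in stats)
        nbar = n_sum / r
        nc = (n_sum - sum(s[0] ** 2 for s in stats) / n_sum) / (r - 1)
        if nbar <= 1 or nc <= 0:
            out.append((0.0, 0.0, 0.0, False))
            continue
        pbar = sum(s[0] * s[1] for s in stats) / n_sum
        hbar = sum(s[0] * s[2] for s in stats) / n_sum
        s2 = sum(s[0] * (s[1] - pbar) ** 2 for s in stats) / ((r - 1) * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        out.append((a, b, c, True))
    return out


def _random_instance(rng):
    n_pops = rng.integers(2, 4)
    sizes = rng.integers(1, 7, size=n_pops)
    n_loci = rng.integers(1, 6)
    pops, rows = [], []
    per_pop = []
    for k, size in enumerate(sizes):
        pop_rows = []
        for _ in range(size):
            row = rng.integers(0, 3, size=n_loci).astype(np.int8)
            row[rng.random(n_loci) < 0.2] = MISSING
            pop_rows.append(list(row))
            rows.append(row)
            pops.append(f"pop{k + 1}")
        per_pop.append(pop_rows)
    return make_matrix(pops, np.array(rows)), per_pop


def test_wc_fst_matches_scalar_oracle():
    rng = np.random.default_rng(42)
    checked = 0
    for _ in range(200):
        gm, per_pop = _random_instance(rng)
        expected = wc_components_scalar(per_pop)
        if not any(valid for *_, valid in expected):
            with pytest.raises(ValueError):
                wc_fst_components(gm)
            continue
        a, b, c = wc_fst_components(gm)
        for j, (ea, eb, ec, _) in enumerate(expected):
            assert a[j] == pytest.approx(ea, abs=1e-10)
            assert b[j] == pytest.approx(eb, abs=1e-10)
            assert c[j] == pytest.approx(ec, abs=1e-10)
        denom = sum(ea + eb + ec for ea, eb, ec, _ in expected)
        if denom != 0:
            assert wc_fst(gm) == pytest.approx(
                sum(ea for ea, *_ in expected) / denom, abs=1e-10
            )
            checked += 1
    assert checked > 100  # most random instances are informative


def test_wc_fst_fixed_difference_is_one():
    gm = make_matrix(["p1", "p1", "p2", "p2"], [[2], [2], [0], [0]])
    assert wc_fst(gm) == pytest.approx(1.0)


def test_wc_fst_identical_heterogeneous_pops_nonpositive():
    gm = make_matrix(["p1", "p1", "p2", "p2"], [[2], [0], [2], [0]])
    assert wc_fst(gm) <= 0


def test_wc_fst_requires_two_populations():
    gm = make_matrix(["p1", "p1"], [[0], [2]])
    with pytest.raises(ValueError):
        wc_fst(gm)


def test_wc_fst_no_shared_locus_errors():
    gm = make_matrix(["p1", "p2"], [[1, MISSING], [MISSING, 1]])
    with pytest.raises(ValueError):
        wc_fst(gm)


def test_pairwise_matrix_symmetric_zero_diagonal():
    rng = np.random.default_rng(11)
    gm = random_matrix(rng, n_pops=3, ind_per_pop=5, n_loci=30)
    mat = pairwise_fst_matrix(gm)
    assert np.allclose(mat.values, mat.values.T)
    assert np.allclose(np.diag(mat.values), 0.0)
    pair = wc_fst(gm, populations=["pop1", "pop2"])
    assert mat.loc["pop1", "pop2"] == pytest.approx(pair)


def test_pairwise_matrix_identical_pops_nonpositive():
    block = [[2], [0]]
    gm = make_matrix(
        ["p1", "p1", "p2", "p2", "p3", "p3"], np.array(block * 3)
    )
    mat = pairwise_fst_matrix(gm)
    off = mat.values[~np.eye(3, dtype=bool)]
    assert (off <= 0).all()


# ---------------------------------------------------------------------------
# bootstrap CI


def test_bootstrap_degenerate_loci_collapse_ci():
    # every locus identical -> resampling cannot vary the estimate
    col = np.array([2, 2, 0, 0], dtype=np.int8)
    gm = make_matrix(["p1", "p1", "p2", "p2"], np.tile(col[:, None], 5))
    res = bootstrap_fst_ci(gm, n_boot=200, seed=0)
    assert res.ci_low == pytest.approx(res.estimate)
    assert res.ci_high == pytest.approx(res.estimate)
    assert res.significant


def test_bootstrap_deterministic_and_defaults():
    rng = np.random.default_rng(5)
    gm = random_matrix(rng, n_pops=2, ind_per_pop=6, n_loci=25)
    r1 = bootstrap_fst_ci(gm, n_boot=300, seed=9)
    r2 = bootstrap_fst_ci(gm, n_boot=300, seed=9)
    assert (r1.estimate, r1.ci_low, r1.ci_high) == (r2.estimate, r2.ci_low, r2.ci_high)
    assert r1.ci_low <= r1.ci_high
    sig = inspect.signature(bootstrap_fst_ci)
    assert sig.parameters["n_boot"].default == 10_000
    assert sig.parameters["alpha"].default == 0.05


def test_bootstrap_single_locus_errors():
    gm = make_matrix(["p1", "p2"], [[2], [0]])
    with pytest.raises(ValueError):
        bootstrap_fst_ci(gm, n_boot=10)


def test_bootstrap_ci_covers_model_truth():
    """95% interval contains the Balding-Nichols F in >=90% of datasets."""
    from streampop import SyntheticSpec, generate_stream_dataset

    F = 0.05
    hits = 0
    n_runs = 50
    for seed in range(n_runs):
        spec = SyntheticSpec(
            n_streams=1, sites_per_stream=2, individuals_per_site=10,
            n_loci=300, F_stream=F, F_site=F, missing_rate=0.0, seed=seed,
        )
        gm, _ = generate_stream_dataset(spec)
        res = bootstrap_fst_ci(gm, n_boot=500, seed=1000 + seed)
        hits += res.ci_low <= F <= res.ci_high
    assert hits >= 0.9 * n_runs


# ---------------------------------------------------------------------------
# diversity


def test_diversity_hand_example():
    gm = make_matrix(["p1", "p1"], [[2], [1]])  # {AA, Aa}
    d = diversity_stats(gm)
    assert d.ho[0, 0] == pytest.approx(0.5)
    # unbiased gene diversity: 2pq * 2n/(2n-1) with p=0.75, n=2
    assert d.hs[0, 0] == pytest.approx(0.5)


def test_diversity_monomorphic_fis_missing():
    gm = make_matrix(["p1", "p1"], [[2, 2], [2, 2]])
    d = diversity_stats(gm)
    assert d.ho_mean["p1"] == 0.0
    assert d.hs_mean["p1"] == 0.0
    assert np.isnan(d.fis["p1"])


def test_diversity_identical_pops_hs_matches_ht_up_to_correction():
    block = np.array([[2, 1], [1, 0], [0, 2]], dtype=np.int8)
    gm = make_matrix(["p1"] * 3 + ["p2"] * 3, np.vstack([block, block]))
    d = diversity_stats(gm)
    n = 3
    uncorrected_hs = d.hs * (2 * n - 1) / (2 * n)
    # identical frequencies in both pops: uncorrected H_S equals H_T per locus
    assert np.allclose(uncorrected_hs[0], d.ht)
    assert np.allclose(uncorrected_hs[1], d.ht)


def test_diversity_bounds_on_random_data():
    rng = np.random.default_rng(21)
    gm = random_matrix(rng, n_pops=3, ind_per_pop=8, n_loci=50, missing_rate=0.1)
    d = diversity_stats(gm)
    assert ((d.ho >= 0) & (d.ho <= 1) | np.isnan(d.ho)).all()
    assert ((d.ht >= 0) & (d.ht <= 1)).all()
    assert ((d.fis >= -1) & (d.fis <= 1) | d.fis.isna()).all()


# ---------------------------------------------------------------------------
# Nei G_ST


def test_gst_hand_example():
    assert nei_gst(np.array([[0.2], [0.8]])) == pytest.approx(0.36)


def test_gst_limits():
    assert nei_gst(np.array([[0.4], [0.4]])) == 0.0
    assert nei_gst(np.array([[1.0], [0.0]])) == pytest.approx(1.0)
    assert nei_gst(np.array([[1.0], [1.0]])) == 0.0  # H_T = 0 case


# ---------------------------------------------------------------------------
# allelic richness


def test_richness_hand_example():
    # counts ref 3 / alt 1 in N=4 copies, g=2 -> AR = 1.5
    gm = make_matrix(["p1", "p1"], [[2], [1]])
    res = allelic_richness(gm, g=2)
    assert res.per_locus[0, 0] == pytest.approx(1.5)


def test_richness_monomorphic_and_full_size():
    gm = make_matrix(["p1", "p1"], [[2, 1], [2, 1]])
    res = allelic_richness(gm, g=2)
    assert res.per_locus[0, 0] == pytest.approx(1.0)  # monomorphic
    full = allelic_richness(gm, g=4)
    assert full.per_locus[0, 0] == pytest.approx(1.0)
    assert full.per_locus[0, 1] == pytest.approx(2.0)  # observed allele count


def test_richness_monotone_in_g_and_bounded():
    rng = np.random.default_rng(13)
    gm = random_matrix(rng, n_pops=2, ind_per_pop=8, n_loci=30, missing_rate=0.0)
    values = [allelic_richness(gm, g=g).per_locus for g in (2, 4, 8, 16)]
    assert np.all((values[0] >= 1.0 - 1e-12) & (values[0] <= 2.0 + 1e-12))
    for lo, hi in zip(values, values[1:]):
        assert np.all(hi >= lo - 1e-9)


def test_richness_rejects_tiny_g():
    gm = make_matrix(["p1", "p1"], [[2], [1]])
    with pytest.raises(ValueError):
        allelic_richness(gm, g=1)


# ---------------------------------------------------------------------------
# private alleles


def test_private_alleles_constructed_case():
    gm = make_matrix(
        ["p1", "p1", "p2", "p2"], [[1, 2], [2, 2], [2, 2], [2, 2]]
    )
    res = private_alleles(gm, n_reps=5, seed=0)
    assert res.mean_private["p1"] == pytest.approx(1.0)
    assert res.mean_private["p2"] == pytest.approx(0.0)
    assert np.ptp(res.per_replicate, axis=0).max() == 0  # equal sizes: no variance
    assert inspect.signature(private_alleles).parameters["n_reps"].default == 30


def test_private_alleles_subsampling_deterministic():
    rng = np.random.default_rng(2)
    g = rng.integers(0, 3, size=(9, 12)).astype(np.int8)
    gm = make_matrix(["p1"] * 6 + ["p2"] * 3, g)
    r1 = private_alleles(gm, n_reps=10, seed=4)
    r2 = private_alleles(gm, n_reps=10, seed=4)
    assert np.array_equal(r1.per_replicate, r2.per_replicate)
    assert r1.target_size == 3


# ---------------------------------------------------------------------------
# Mantel


def _random_dist(rng, n):
    x = rng.random((n, 2))
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return d


def test_mantel_identical_matrices():
    rng = np.random.default_rng(0)
    d = _random_dist(rng, 8)
    r, p = mantel_test(d, d.copy(), n_perm=999, seed=1)
    assert r == pytest.approx(1.0)
    assert p == pytest.approx(1 / 1000)


def test_mantel_constant_matrix_errors():
    d = np.ones((4, 4)) - np.eye(4)
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError, match="variance"):
        mantel_test(_random_dist(rng, 4), d, n_perm=99)


def test_mantel_joint_relabeling_invariance():
    rng = np.random.default_rng(3)
    a, b = _random_dist(rng, 7), _random_dist(rng, 7)
    r, _ = mantel_test(a, b, n_perm=49, seed=0)
    perm = rng.permutation(7)
    r2, _ = mantel_test(a[np.ix_(perm, perm)], b[np.ix_(perm, perm)], n_perm=49, seed=0)
    assert r2 == pytest.approx(r)


def test_mantel_label_mismatch_errors():
    import pandas as pd

    rng = np.random.default_rng(5)
    a = pd.DataFrame(_random_dist(rng, 4), index=list("abcd"), columns=list("abcd"))
    b = pd.DataFrame(_random_dist(rng, 4), index=list("abce"), columns=list("abce"))
    with pytest.raises(ValueError, match="labels"):
        mantel_test(a, b)


def test_mantel_agrees_with_skbio():
    skbio_distance = pytest.importorskip("skbio.stats.distance")
    rng = np.random.default_rng(8)
    a, b = _random_dist(rng, 9), _random_dist(rng, 9)
    r_ours, p_ours = mantel_test(a, b, n_perm=999, seed=2)
    r_ref, p_ref, _ = skbio_distance.mantel(a, b, permutations=999, alternative="greater")
    assert r_ours == pytest.approx(r_ref, abs=1e-12)
    assert p_ours == pytest.approx(p_ref, abs=0.05)  # independent permutation draws


def test_mantel_null_p_values_uniform():
    """Under independence the permutation p-value is uniform (KS, alpha=0.01)."""
    rng = np.random.default_rng(17)
    pvals = []
    for i in range(200):
        a, b = _random_dist(rng, 8), _random_dist(rng, 8)
        _, p = mantel_test(a, b, n_perm=99, seed=int(rng.integers(2**31)))
        pvals.append(p)
    assert kstest(pvals, "uniform").pvalue > 0.01
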