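import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tohkit.cluster_tree import (
    ClusterParams,
    allelic_similarity,
    binary_spectral_split,
    build_similarity,
    build_tree,
    extract_regions,
    node_stat,
    positional_similarity,
)
from tohkit.toh_scan import TOH

from _oracles import min_ncut_bipartitions, normalized_cut
from conftest import make_genotypes, make_map


def mk_toh(s, e, subj="s0", chrom="1", spacing=1000, tid=0):
    return TOH(subj, chrom, s, e, (s + 1) * spacing, (e + 1) * spacing, 0, 0, tid)


# ---------------------------------------------------------------- kernels


def test_positional_similarity_values():
    a = mk_toh(0, 99)
    assert positional_similarity(a, mk_toh(0, 99)) == 1.0
    assert positional_similarity(a, mk_toh(200, 300)) == 0.0
    assert positional_similarity(a, mk_toh(500, 600, chrom="2")) == 0.0
    # spans of 100 and 200 SNPs overlapping by 80
    b = mk_toh(20, 219)
    assert positional_similarity(a, b) == pytest.approx(min(0.8, 0.4))
    assert positional_similarity(a, b, kernel="product") == pytest.approx(
        80**2 / (100 * 200)
    )
    # bp mode: closed-interval bp spans at uniform 1 kb spacing
    assert positional_similarity(a, b, length_unit="bp") == pytest.approx(
        79001 / 199001
    )


@settings(derandomize=True, max_examples=80, deadline=None)
@given(
    s1=st.integers(0, 400), l1=st.integers(1, 200),
    s2=st.integers(0, 400), l2=st.integers(1, 200),
)
def test_positional_similarity_bounds_and_symmetry(s1, l1, s2, l2):
    a = mk_toh(s1, s1 + l1 - 1, tid=0)
    b = mk_toh(s2, s2 + l2 - 1, tid=1)
    for kernel in ("min_overlap", "product"):
        s_ab = positional_similarity(a, b, kernel)
        assert 0.0 <= s_ab <= 1.0
        assert s_ab == positional_similarity(b, a, kernel)
    assert positional_similarity(a, a) == 1.0
    if s_ab == 0.0:
        assert min(a.end_idx, b.end_idx) < max(a.start_idx, b.start_idx)


def _pair_fixture(calls_a, calls_b):
    gm = make_genotypes([calls_a, calls_b])
    snp_map = make_map(len(calls_a))
    return gm, snp_map


def test_allelic_similarity_counts_matched_homozygotes():
    n = 100
    gm, snp_map = _pair_fixture(["AA"] * n, ["AA"] * 90 + ["CC"] * 10)
    a = mk_toh(0, n - 1, "S0")
    b = mk_toh(0, n - 1, "S1")
    assert allelic_similarity(a, b, gm, snp_map) == pytest.approx(0.9)
    full = _pair_fixture(["AA"] * n, ["AA"] * n)
    assert allelic_similarity(a, b, *full) == 1.0


def test_allelic_similarity_overlap_gate():
    gm, snp_map = _pair_fixture(["AA"] * 100, ["AA"] * 100)
    a = mk_toh(0, 99, "S0")
    short = mk_toh(60, 99, "S1")  # overlap 40 of a's 100 -> fraction 0.4
    assert allelic_similarity(a, short, gm, snp_map, gamma=0.5) == 0.0
    assert allelic_similarity(a, short, gm, snp_map, gamma=0.4) == 1.0


def test_allelic_similarity_token_order_invariant(rng):
    calls_a = ["AA", "AC", "CC", "A0", "AA", "CC", "AC", "AA"]
    calls_b = ["AA", "CA", "CC", "0A", "CC", "CC", "CA", "AA"]
    gm, snp_map = _pair_fixture(calls_a, calls_b)
    a, b = mk_toh(0, 7, "S0"), mk_toh(0, 7, "S1")
    base = allelic_similarity(a, b, gm, snp_map)
    # permute the two allele tokens of random calls: similarity unchanged
    for _ in range(10):
        gm2, _ = _pair_fixture(list(calls_a), list(calls_b))
        i, j = rng.integers(0, 2), rng.integers(0, 8)
        gm2.alleles[i, j] = gm2.alleles[i, j][::-1]
        assert allelic_similarity(a, b, gm2, snp_map) == base


# ---------------------------------------------------------------- spectral


def test_split_block_diagonal_equals_components(rng):
    for sizes in [(3, 2), (5, 5), (2, 7)]:
        n = sum(sizes)
        S = np.zeros((n, n))
        S[: sizes[0], : sizes[0]] = 1.0
        S[sizes[0] :, sizes[0] :] = 1.0
        a, b = binary_spectral_split(S, seed=int(rng.integers(1 << 30)))
        assert {frozenset(a), frozenset(b)} == {
            frozenset(range(sizes[0])),
            frozenset(range(sizes[0], n)),
        }


def test_split_two_group_example_matches_min_ncut():
    S = np.array(
        [[1, 0.9, 0.1, 0.1], [0.9, 1, 0.1, 0.1], [0.1, 0.1, 1, 0.9], [0.1, 0.1, 0.9, 1]]
    )
    a, b = binary_spectral_split(S, seed=0)
    assert {frozenset(a), frozenset(b)} == {frozenset({0, 1}), frozenset({2, 3})}
    best = min_ncut_bipartitions(S)[0][1]
    assert frozenset(best) in {frozenset(a), frozenset(b)}


def test_split_well_separated_equals_exhaustive_min_ncut(rng):
    """On planted two-block instances of <= 12 members the split is the
    exhaustive minimum-normalized-cut bipartition."""
    for _ in range(10):
        k1 = int(rng.integers(2, 7))
        k2 = int(rng.integers(2, 7))
        n = k1 + k2
        S = np.full((n, n), 0.05)
        S[:k1, :k1] = 0.8 + 0.2 * rng.random((k1, k1))
        S[k1:, k1:] = 0.8 + 0.2 * rng.random((k2, k2))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        a, b = binary_spectral_split(S, seed=int(rng.integers(1 << 30)))
        best = min_ncut_bipartitions(S)[0][1]
        assert frozenset(best) in {frozenset(a), frozenset(b)}


def test_split_near_optimal_on_random_instances(rng):
    """On arbitrary random similarities the split lands within the best two
    bipartitions by normalized-cut value."""
    hits = 0
    for _ in range(10):
        n = int(rng.integers(4, 9))
        S = rng.random((n, n))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        a, _ = binary_spectral_split(S, seed=int(rng.integers(1 << 30)))
        scored = min_ncut_bipartitions(S)
        top2 = {frozenset(side) for _, side in scored[:2]} | {
            frozenset(set(range(n)) - side) for _, side in scored[:2]
        }
        hits += frozenset(a) in top2
    assert hits >= 8


def test_split_deterministic_and_nonempty():
    S = np.ones((6, 6))
    r1 = binary_spectral_split(S, seed=123)
    r2 = binary_spectral_split(S, seed=123)
    assert r1 == r2
    assert len(r1[0]) >= 1 and len(r1[1]) >= 1


def test_split_isolated_members_peeled():
    S = np.eye(4)
    S[0, 1] = S[1, 0] = 0.9
    a, b = binary_spectral_split(S, seed=0)
    assert {frozenset(a), frozenset(b)} == {frozenset({0, 1}), frozenset({2, 3})}
    # fully disjoint members peel deterministically
    a, b = binary_spectral_split(np.eye(3), seed=0)
    assert (a, b) == ([0], [1, 2])


# ---------------------------------------------------------------- tree


def _positional_S(tohs):
    return build_similarity(tohs, "gtoh", ClusterParams())


def test_tree_stop_rules():
    # size rule: 4 members < min_node_size=5
    tohs = [mk_toh(0, 99, tid=i) for i in range(4)]
    tree = build_tree(tohs, "gtoh", ClusterParams())
    assert tree.is_leaf
    # similarity rule: 10 identical members, lower quartile 1.0 > 0.75
    tohs = [mk_toh(0, 99, tid=i) for i in range(10)]
    tree = build_tree(tohs, "gtoh", ClusterParams())
    assert tree.is_leaf and tree.stat_value == 1.0
    # depth rule
    tohs = [mk_toh(100 * i, 100 * i + 50, tid=i) for i in range(6)]
    tree = build_tree(tohs, "gtoh", ClusterParams(max_depth=0))
    assert tree.is_leaf


def test_tree_recovers_planted_groups_and_partitions(rng):
    tohs = [mk_toh(int(100 + rng.integers(-3, 4)), int(249 + rng.integers(-3, 4)), tid=i)
            for i in range(8)]
    tohs += [mk_toh(int(600 + rng.integers(-3, 4)), int(749 + rng.integers(-3, 4)), tid=8 + i)
             for i in range(8)]
    tree = build_tree(tohs, "gtoh", ClusterParams(), seed=17)
    leaves = tree.leaves()
    assert sorted(sum((lf.members for lf in leaves), [])) == list(range(16))
    reported = [lf for lf in leaves if len(lf.members) >= 2 and lf.stat_value >= 0.75]
    assert {frozenset(lf.members) for lf in reported} == {
        frozenset(range(8)),
        frozenset(range(8, 16)),
    }


def test_leaves_partition_on_random_similarity(rng):
    for _ in range(5):
        tohs = [
            mk_toh(int(rng.integers(0, 500)), 0, tid=i) for i in range(12)
        ]
        tohs = [
            TOH("s", "1", t.start_idx, t.start_idx + int(rng.integers(20, 200)),
                0, 0, 0, 0, t.toh_id)
            for t in tohs
        ]
        tohs = [
            TOH("s", "1", t.start_idx, t.end_idx,
                (t.start_idx + 1) * 1000, (t.end_idx + 1) * 1000, 0, 0, t.toh_id)
            for t in tohs
        ]
        tree = build_tree(tohs, "gtoh", ClusterParams(min_node_size=3), seed=1)
        members = sorted(sum((lf.members for lf in tree.leaves()), []))
        assert members == list(range(12))


# ---------------------------------------------------------------- regions


def _leaf_tree(tohs):
    params = ClusterParams(min_node_size=len(tohs) + 1)  # force root leaf
    return build_tree(tohs, "gtoh", params), params


def test_extract_region_boundary_quantiles():
    snp_map = make_map(1000, spacing=10, start=10)
    # member starts {100,110,120,130} bp, ends {900,910,920,930} bp
    tohs = [
        TOH("s%d" % i, "1", (s - 10) // 10, (e - 10) // 10, s, e, 0, 0, i)
        for i, (s, e) in enumerate([(100, 900), (110, 910), (120, 920), (130, 930)])
    ]
    tree, _ = _leaf_tree(tohs)
    params = ClusterParams(min_node_size=10, min_report_size=2, threshold=0.75)
    regions = extract_regions(tree, tohs, "gtoh", params, snp_map)
    assert len(regions) == 1
    # interior mode: Q3 of starts = 122.5 snapped up -> 130;
    # Q1 of ends = 907.5 snapped down -> 900
    assert (regions[0].start_bp, regions[0].end_bp) == (130, 900)
    lit = ClusterParams(min_node_size=10, boundary_mode="literal")
    regions = extract_regions(tree, tohs, "gtoh", lit, snp_map)
    assert (regions[0].start_bp, regions[0].end_bp) == (110, 900)
    assert regions[0].present_subjects == {"s0", "s1", "s2", "s3"}


def test_extract_region_gates():
    snp_map = make_map(1000)
    # similarity below threshold: no region
    tohs = [mk_toh(0, 99, tid=0), mk_toh(300, 399, tid=1)]
    tree, _ = _leaf_tree(tohs)
    params = ClusterParams(min_node_size=10)
    assert extract_regions(tree, tohs, "gtoh", params, snp_map) == []
    # singleton leaf: below min_report_size
    tohs = [mk_toh(0, 99, tid=0)]
    tree, _ = _leaf_tree(tohs)
    assert extract_regions(tree, tohs, "gtoh", params, snp_map) == []
    # reported leaf carries its stat and members
    tohs = [mk_toh(0, 99, tid=i) for i in range(3)]
    tree, _ = _leaf_tree(tohs)
    regions = extract_regions(tree, tohs, "gtoh", params, snp_map)
    assert len(regions) == 1
    assert regions[0].stat_value >= params.threshold
    assert regions[0].n_snps == 100


def test_node_stat_statistics():
    S = np.array([[1, 0.2, 0.4], [0.2, 1, 0.8], [0.4, 0.8, 1]])
    assert node_stat(S, [0, 1, 2], "minimum") == pytest.approx(0.2)
    assert node_stat(S, [0, 1, 2], "mean") == pytest.approx((0.2 + 0.4 + 0.8) / 3)
    assert node_stat(S, [0, 1, 2], "lower_quartile") == pytest.approx(
        np.quantile([0.2, 0.4, 0.8], 0.25)
    )
    assert np.isnan(node_stat(S, [0], "mean"))
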