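"""F_ST, the DR transform, p-distances, NJ and bootstrap support."""

import math

import numpy as np
import pytest

from radpop.differentiation import (bootstrap_support, dr_distance,
                                    fst_weir_cockerham, nj_tree, p_distance,
                                    pairwise_differentiation,
                                    weir_cockerham_components, _bipartitions)
from radpop.matrix import MISSING
from radpop.sim import SimulationConfig, simulate_genotypes

from conftest import make_matrix


# ---------------------------------------------------------------------------
# DR transform

def test_dr_examples():
    assert round(dr_distance(0.075), 3) == 0.078
    assert round(dr_distance(0.007), 3) == 0.007
    assert dr_distance(0.0) == 0.0


def test_dr_domain():
    with pytest.raises(ValueError):
        dr_distance(1.0)
    with pytest.raises(ValueError):
        dr_distance(-0.01)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta

def test_theta_label_swap_and_population_order_invariance(two_pop_truth):
    gm = two_pop_truth.true_genotypes
    t1 = fst_weir_cockerham(gm, "P1", "P2")
    t2 = fst_weir_cockerham(gm, "P2", "P1")
    assert t1 == pytest.approx(t2, abs=1e-12)
    flipped = make_matrix(2 - gm.dosages, populations=list(gm.populations))
    t3 = fst_weir_cockerham(flipped, "P1", "P2")
    assert t1 == pytest.approx(t3, abs=1e-9)


def test_theta_duplicated_population_not_positive():
    rng = np.random.default_rng(2)
    block = rng.integers(0, 3, size=(20, 400)).astype(np.int8)
    gm = make_matrix(np.vstack([block, block]),
                     populations=["A"] * 20 + ["B"] * 20)
    assert fst_weir_cockerham(gm, "A", "B") <= 0


def test_theta_matches_literal_transcription(two_pop_truth):
    """Vectorised components equal a literal per-locus transcription of
    the variance-component formulas."""
    gm = two_pop_truth.true_genotypes
    blocks = [gm.subset_population(p).dosages for p in ("P1", "P2")]
    a, b, c = weir_cockerham_components(blocks)

    r = 2
    for locus in range(0, gm.n_sites, 97):
        ns, ps, hs = [], [], []
        for blk in blocks:
            col = [int(x) for x in blk[:, locus] if x != MISSING]
            ns.append(len(col))
            ps.append(sum(col) / (2 * len(col)))
            hs.append(sum(1 for x in col if x == 1) / len(col))
        nbar = sum(ns) / r
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
        ea = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2 - hbar / 4) / (nbar - 1))
        eb = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 / 2
                                    - (2 * nbar - 1) / (4 * nbar) * hbar)
        ec = hbar / 2
        assert a[locus] == pytest.approx(ea, abs=1e-10)
        assert b[locus] == pytest.approx(eb, abs=1e-10)
        assert c[locus] == pytest.approx(ec, abs=1e-10)


def test_no_shared_sites_raises():
    d = np.array([[0, MISSING], [0, MISSING],
                  [MISSING, 0], [MISSING, 0]], dtype=np.int8)
    gm = make_matrix(d, populations=["A", "A", "B", "B"])
    with pytest.raises(ValueError):
        fst_weir_cockerham(gm, "A", "B")


def test_pairwise_matrix_layout(two_pop_truth):
    pw = pairwise_differentiation(two_pop_truth.true_genotypes)
    frame = pw.to_frame()
    assert frame.loc["P2", "P1"] != ""      # lower triangle: F_ST
    assert frame.loc["P1", "P2"] != ""      # upper triangle: DR
    assert frame.loc["P1", "P1"] == ""
    fst = float(frame.loc["P2", "P1"])
    dr = float(frame.loc["P1", "P2"])
    assert dr == pytest.approx(-math.log(1 - fst), abs=1e-3)


# ---------------------------------------------------------------------------
# p-distance

def test_p_distance_examples():
    d, names = p_distance(["ACGT", "ACGT"])
    assert d[0, 1] == 0
    d, _ = p_distance(["ACGT", "ACGA"])
    assert d[0, 1] == 0.25
    d, _ = p_distance(["A-GT", "ACGA"])
    assert d[0, 1] == pytest.approx(1 / 3)


def test_p_distance_errors():
    with pytest.raises(ValueError):
        p_distance(["ACGT", "ACG"])
    with pytest.raises(ValueError):
        p_distance(["--AA", "AA--"])


# ---------------------------------------------------------------------------
# neighbor joining

def leaf_distances(tree):
    """Path-length distances between all leaf pairs of a TreeNode."""
    paths = {}

    def walk(node, dist_from_root):
        if node.is_leaf():
            paths[node.name] = dist_from_root
        for child, bl in node.children:
            walk(child, dist_from_root + bl)

    # distances via lowest common ancestor on the (rooted) structure
    def pairwise(node):
        out = {}
        if node.is_leaf():
            return {node.name: 0.0}, out
        sub = []
        for child, bl in node.children:
            depths, pairs = pairwise(child)
            out.update(pairs)
            sub.append({k: v + bl for k, v in depths.items()})
        merged = {}
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                for na, da in sub[i].items():
                    for nb, db in sub[j].items():
                        out[frozenset((na, nb))] = da + db
            merged.update(sub[i])
        return merged, out

    _, pairs = pairwise(tree)
    return pairs


def test_nj_three_taxa_closed_form():
    names = ["a", "b", "c"]
    D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    tree = nj_tree(D, names)
    bl = {child.name: l for child, l in tree.children}
    assert bl["a"] == pytest.approx((3 + 4 - 5) / 2)
    assert bl["b"] == pytest.approx((3 + 5 - 4) / 2)
    assert bl["c"] == pytest.approx((4 + 5 - 3) / 2)


def test_nj_recovers_additive_four_taxon_tree():
    # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
    D = np.array([
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0]], dtype=float)
    names = ["A", "B", "C", "D"]
    tree = nj_tree(D, names)
    bips = set(_bipartitions(tree, frozenset(names)))
    assert bips == {frozenset({"C", "D"})} or bips == {frozenset({"A", "B"})}
    pairs = leaf_distances(tree)
    for (i, ni) in enumerate(names):
        for (j, nj) in enumerate(names):
            if i < j:
                assert pairs[frozenset((ni, nj))] == pytest.approx(D[i, j])


def test_nj_matches_skbio_on_additive_matrix():
    from skbio import DistanceMatrix
    from skbio.tree import nj as skbio_nj
    rng = np.random.default_rng(4)
    # random additive tree on 8 taxa via random split metric
    n = 8
    names = [f"t{i}" for i in range(n)]
    # build random binary tree distances by simulating a tree structure
    coords = rng.uniform(0, 1, size=(n, 6))
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.abs(coords[i] - coords[j]).sum()
    mine = nj_tree(D, names)
    ref = skbio_nj(DistanceMatrix(D, ids=names))
    my_pairs = leaf_distances(mine)
    for i in range(n):
        for j in range(i + 1, n):
            ref_d = ref.find(names[i]).distance(ref.find(names[j]))
            # both reconstructions embed the same tree metric
            assert my_pairs[frozenset((names[i], names[j]))] == \
                pytest.approx(ref_d, abs=1e-9)


def test_nj_invariant_under_taxon_permutation():
    rng = np.random.default_rng(9)
    n = 7
    names = [f"x{i}" for i in range(n)]
    base = rng.uniform(0.1, 1.0, size=(n, n))
    D = (base + base.T) / 2
    np.fill_diagonal(D, 0)
    tree1 = nj_tree(D, names)
    perm = rng.permutation(n)
    tree2 = nj_tree(D[np.ix_(perm, perm)], [names[i] for i in perm])
    bips1 = set(_bipartitions(tree1, frozenset(names)))
    bips2 = set(_bipartitions(tree2, frozenset(names)))
    assert bips1 == bips2


def test_nj_input_validation():
    with pytest.raises(ValueError):
        nj_tree(np.zeros((2, 2)), ["a", "b"])
    bad = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], dtype=float)
    with pytest.raises(ValueError):
        nj_tree(bad, ["a", "b", "c"])


# ---------------------------------------------------------------------------
# bootstrap

def cluster_strings(rng, n_per=5, length=200, divergence=0.3):
    """Two diverged clusters of genotype strings."""
    base1 = rng.choice(list("ACGT"), size=length)
    base2 = base1.copy()
    flip = rng.random(length) < divergence
    for i in np.flatnonzero(flip):
        base2[i] = rng.choice([b for b in "ACGT" if b != base2[i]])
    strings = {}
    for k in range(n_per):
        s1 = base1.copy(); s2 = base2.copy()
        for arr in (s1, s2):
            noise = rng.random(length) < 0.01
            for i in np.flatnonzero(noise):
                arr[i] = rng.choice(list("ACGT"))
        strings[f"g1_{k}"] = "".join(s1)
        strings[f"g2_{k}"] = "".join(s2)
    return strings


def test_bootstrap_strong_signal_support_is_full():
    strings = cluster_strings(np.random.default_rng(1))
    tree = bootstrap_support(strings, n_replicates=50, seed=0)
    bips = _bipartitions(tree, frozenset(strings))
    cluster1 = frozenset(n for n in strings if n.startswith("g1"))
    cluster2 = frozenset(n for n in strings if n.startswith("g2"))
    supports = [node.support for bip, node in bips.items()
                if bip in (cluster1, cluster2)]
    assert supports and all(s == 100 for s in supports)


def test_bootstrap_deterministic_under_seed():
    strings = cluster_strings(np.random.default_rng(2))
    t1 = bootstrap_support(strings, n_replicates=20, seed=5)
    t2 = bootstrap_support(strings, n_replicates=20, seed=5)
    assert t1.newick(with_support=True) == t2.newick(with_support=True)


def test_bootstrap_identical_strings_degenerate():
    strings = {f"s{i}": "ACGT" * 20 for i in range(5)}
    with pytest.raises(ValueError):
        bootstrap_support(strings, n_replicates=10, seed=0)


def test_nj_separates_simulated_populations():
    """Mild structure (F = 0.1) yields near-monophyletic population
    clades on the individual NJ tree."""
    cfg = SimulationConfig(n_populations=2, n_individuals_per_pop=15,
                           n_sites=2000, global_fst=0.1,
                           ancestral_freq_beta=(1.0, 1.0), seed=21)
    truth = simulate_genotypes(cfg)
    from radpop.filters import concat_genotype_strings
    strings = concat_genotype_strings(truth.true_genotypes)
    dist, names = p_distance(strings)
    tree = nj_tree(dist, names)
    bips = _bipartitions(tree, frozenset(names))
    pop_of = {n: n.split("_")[0] for n in names}
    best = {"P1": 0, "P2": 0}
    for bip in bips:
        pops = {pop_of[n] for n in bip}
        if len(pops) == 1:
            p = pops.pop()
            best[p] = max(best[p], len(bip))
    frac = (best["P1"] + best["P2"]) / len(names)
    assert frac >= 0.9
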