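"""Diversity indicators against direct evaluation and loop oracles."""

from fractions import Fraction

import numpy as np
import pytest
from sympy.utilities.iterables import multiset_permutations

from radpop.diversity import (drift_coefficient, effective_alleles,
                              expected_heterozygosity, hwe_exact_p,
                              nucleotide_diversity, observed_heterozygosity,
                              pic, population_diversity, summarize)
from radpop.matrix import MISSING

from conftest import make_matrix


@pytest.mark.parametrize("freqs,he", [
    ([0.5, 0.5], 0.5),
    ([1.0], 0.0),
    ([0.9, 0.1], 0.18),
])
def test_expected_heterozygosity_examples(freqs, he):
    assert expected_heterozygosity([freqs])[0] == pytest.approx(he, abs=1e-12)


@pytest.mark.parametrize("freqs,value", [
    ([0.5, 0.5], 0.375),
    ([1.0], 0.0),
    ([0.9, 0.1], 1 - 0.82 - 2 * (0.81 * 0.01)),
])
def test_pic_examples(freqs, value):
    assert pic([freqs])[0] == pytest.approx(value, abs=1e-12)


@pytest.mark.parametrize("freqs,ne", [
    ([0.5, 0.5], 2.0),
    ([1.0], 1.0),
    ([0.9, 0.1], 1 / 0.82),
])
def test_effective_alleles_examples(freqs, ne):
    assert effective_alleles([freqs])[0] == pytest.approx(ne, abs=1e-12)


def test_observed_heterozygosity_examples():
    assert observed_heterozygosity([3], [15])[0] == pytest.approx(0.2)
    assert observed_heterozygosity([0], [15])[0] == 0.0


@pytest.mark.parametrize("n,j,value", [
    (4, 2, 8 / 12),        # brute force: 6 haplotype pairs, 4 differ
    (10, 0, 0.0),
    (30, 3, 162 / 870),
])
def test_nucleotide_diversity_examples(n, j, value):
    assert nucleotide_diversity([n], [j])[0] == pytest.approx(value, abs=1e-12)


def test_nucleotide_diversity_matches_pair_enumeration():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(2, 20))
        j = int(rng.integers(0, n + 1))
        hap = [1] * j + [0] * (n - j)
        diffs = sum(hap[a] != hap[b]
                    for a in range(n) for b in range(a + 1, n))
        expect = diffs / (n * (n - 1) / 2)
        assert nucleotide_diversity([n], [j])[0] == pytest.approx(expect)


def hwe_oracle(n_aa, n_ab, n_bb):
    """Exact HW p value by full enumeration of allele pairings.

    Every distinct ordering of the 2n allele copies is enumerated
    (multiset permutations), consecutive copies are paired into
    genotypes, and the heterozygote-count distribution is accumulated
    in exact rational arithmetic.
    """
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0
    tallies: dict[int, int] = {}
    total = 0
    for perm in multiset_permutations([0] * n_a + [1] * n_b):
        het = sum(perm[i] != perm[i + 1] for i in range(0, len(perm), 2))
        tallies[het] = tallies.get(het, 0) + 1
        total += 1
    probs = {h: Fraction(c, total) for h, c in tallies.items()}
    p_obs = probs[n_ab]
    return float(sum(pr for pr in probs.values() if pr <= p_obs))


@pytest.mark.parametrize("counts,expect", [
    ((1, 0, 1), 1 / 3),
    ((0, 2, 0), 1.0),
    ((15, 0, 0), 1.0),
])
def test_hwe_exact_examples(counts, expect):
    assert hwe_exact_p(*counts) == pytest.approx(expect, abs=1e-12)


@pytest.mark.parametrize("counts", [
    (1, 0, 1), (0, 2, 0), (2, 1, 1), (3, 2, 0), (1, 3, 1),
    (4, 2, 4), (5, 0, 5), (2, 6, 2), (0, 10, 0), (7, 2, 1),
])
def test_hwe_matches_full_enumeration(counts):
    assert hwe_exact_p(*counts) == pytest.approx(hwe_oracle(*counts),
                                                 abs=1e-12)


def oracle_population_diversity(dosages):
    """Literal per-site loops over the printed formulas."""
    n_ind, n_sites = dosages.shape
    he = []; ho = []; pic_v = []; ne = []; pi_v = []; hw = []
    for j in range(n_sites):
        col = [int(d) for d in dosages[:, j] if d != MISSING]
        n = len(col)
        if n == 0:
            continue
        n_alt = sum(col)
        x = n_alt / (2 * n)
        freqs = [1 - x, x]
        he.append(1 - sum(f ** 2 for f in freqs))
        ho.append(sum(1 for d in col if d == 1) / n)
        s1 = sum(f ** 2 for f in freqs)
        cross = 0.0
        for a in range(len(freqs)):
            for b in range(a + 1, len(freqs)):
                cross += 2 * freqs[a] ** 2 * freqs[b] ** 2
        pic_v.append(1 - s1 - cross)
        ne.append(1 / s1)
        nn = 2 * n
        pi_v.append(2 * n_alt * (nn - n_alt) / (nn * (nn - 1)))
        n0 = sum(1 for d in col if d == 0)
        n1 = sum(1 for d in col if d == 1)
        n2 = sum(1 for d in col if d == 2)
        hw.append(hwe_exact_p(n0, n1, n2))
    mean = lambda v: sum(v) / len(v)
    return {"He": mean(he), "Ho": mean(ho), "PIC": mean(pic_v),
            "Ne": mean(ne), "Pi": mean(pi_v), "HW-P": mean(hw)}


def test_population_means_match_loop_oracle():
    rng = np.random.default_rng(3)
    dosages = rng.integers(-1, 3, size=(15, 60)).astype(np.int8)
    dosages[:, 0] = MISSING            # fully-missing site is skipped
    got = population_diversity(dosages)
    expect = oracle_population_diversity(dosages)
    for key, val in expect.items():
        assert got[key] == pytest.approx(val, abs=1e-12), key


def test_site_level_identities():
    """He = 1 - 1/Ne and PIC <= He; biallelic PIC = He - 2 p^2 q^2."""
    rng = np.random.default_rng(7)
    p = rng.uniform(0.01, 0.99, size=200)
    freqs = np.stack([1 - p, p], axis=1)
    he = expected_heterozygosity(freqs)
    ne = effective_alleles(freqs)
    pv = pic(freqs)
    assert np.allclose(he, 1 - 1 / ne, atol=1e-12)
    assert np.all(pv <= he + 1e-12)
    assert np.allclose(pv, he - 2 * (p * (1 - p)) ** 2, atol=1e-12)


def test_drift_coefficient():
    assert drift_coefficient(2.0) == 0.25
    assert drift_coefficient(1.179) == pytest.approx(1 / (2 * 1.179))


def test_excess_heterozygosity_direction():
    """Inflated heterozygote rates push Ho above He."""
    rng = np.random.default_rng(5)
    n, L = 30, 300
    dosages = np.where(rng.random((n, L)) < 0.5, 1,
                       rng.integers(0, 3, size=(n, L))).astype(np.int8)
    stats = population_diversity(dosages)
    assert stats["Ho"] > stats["He"]


def test_summarize_shapes_and_mean_row():
    rng = np.random.default_rng(11)
    d = rng.integers(0, 3, size=(30, 50)).astype(np.int8)
    pops = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
    gm = make_matrix(d, populations=pops)
    table = summarize(gm)
    assert list(table.index) == ["A", "B", "C", "Mean"]
    assert list(table.columns) == ["HW-P", "He", "Ho", "PIC", "Ne", "Pi",
                                   "drift_F"]
    for col in ("He", "Ho", "PIC"):
        assert table[col].between(0, 1).all()
    assert (table["Ne"] >= 1).all()


def test_single_monomorphic_site():
    gm = make_matrix(np.zeros((15, 1), dtype=np.int8))
    stats = population_diversity(gm.dosages)
    assert stats["He"] == 0 and stats["Ho"] == 0
    assert stats["Ne"] == 1 and stats["HW-P"] == 1


def test_empty_population_rejected():
    with pytest.raises(ValueError):
        population_diversity(np.full((5, 3), MISSING, dtype=np.int8))
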