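"""Per-population genetic diversity indicators.

The statistics follow the classical per-site definitions used for
SNP-panel diversity summaries:

* expected heterozygosity  He = 1 - sum_i x_i^2
* observed heterozygosity  Ho = heterozygous individuals / genotyped individuals
* polymorphism information content
  PIC = 1 - sum_i P_i^2 - sum_{i<j} 2 P_i^2 P_j^2  (Botstein's index)
* effective number of alleles  Ne = 1 / sum_i P_i^2  (so He = 1 - 1/Ne per site)
* nucleotide diversity  pi = 2 j (n - j) / (n (n - 1)) for a biallelic
  site with n sampled allele copies of which j are the alternate
  (the unbiased mean pairwise difference)
* HW-P — the exact Hardy–Weinberg test p value, from the conditional
  distribution of the heterozygote count given the allele counts

Population-level values are unweighted means over sites with at least
one called genotype in that population; the drift coefficient
F = 1/(2 Ne) accompanies Ne.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .matrix import GenotypeMatrix


def _as_freq_array(freqs) -> np.ndarray:
    """Coerce per-site frequency vectors to a 2-D (n_sites, k) array."""
    arr = np.atleast_2d(np.asarray(freqs, dtype=np.float64))
    if np.any(arr < -1e-12) or np.any(np.abs(arr.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("allele frequencies must be non-negative and sum to 1")
    return arr


def expected_heterozygosity(freqs) -> np.ndarray:
    """Per-site He = 1 - sum x_i^2."""
    x = _as_freq_array(freqs)
    return 1.0 - (x ** 2).sum(axis=1)


def pic(freqs) -> np.ndarray:
    """Per-site PIC = 1 - sum P_i^2 - sum_{i<j} 2 P_i^2 P_j^2."""
    p2 = _as_freq_array(freqs) ** 2
    s1 = p2.sum(axis=1)
    # sum_{i<j} P_i^2 P_j^2 = ((sum p^2)^2 - sum p^4) / 2
    cross = (s1 ** 2 - (p2 ** 2).sum(axis=1)) / 2.0
    return 1.0 - s1 - 2.0 * cross


def effective_alleles(freqs) -> np.ndarray:
    """Per-site Ne = 1 / sum P_i^2."""
    p2 = _as_freq_array(freqs) ** 2
    return 1.0 / p2.sum(axis=1)


def drift_coefficient(ne: float | np.ndarray) -> float | np.ndarray:
    """Genetic-drift coefficient F = 1/(2 Ne)."""
    return 1.0 / (2.0 * np.asarray(ne, dtype=np.float64))


def observed_heterozygosity(n_het, n_called) -> np.ndarray:
    """Per-site Ho = heterozygote count / genotyped count."""
    n_het = np.asarray(n_het, dtype=np.float64)
    n_called = np.asarray(n_called, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, n_het / n_called, np.nan)


def nucleotide_diversity(n_copies, n_alt) -> np.ndarray:
    """Per-site pi = 2 j (n - j) / (n (n - 1)); nan when n < 2."""
    n = np.asarray(n_copies, dtype=np.float64)
    j = np.asarray(n_alt, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n >= 2, 2.0 * j * (n - j) / (n * (n - 1.0)), np.nan)


@lru_cache(maxsize=100_000)
def _hwe_exact_cached(n_ind: int, n_a: int) -> tuple[tuple[int, float], ...]:
    """Conditional distribution of the heterozygote count.

    For n_ind diploids with n_a copies of allele A (out of 2*n_ind),
    P(n_het | n_ind, n_a) = [n_ind! / (nAA! nAa! naa!)] 2^{nAa}
                            / [ (2 n_ind)! / (n_a! n_b! ) ].
    Returns ((n_het, probability), ...) over feasible het counts.
    """
    n_b = 2 * n_ind - n_a
    rare = min(n_a, n_b)
    log_denom = gammaln(2 * n_ind + 1) - gammaln(n_a + 1) - gammaln(n_b + 1)
    out = []
    for n_het in range(rare % 2, rare + 1, 2):
        n_aa = (n_a - n_het) // 2
        n_bb = (n_b - n_het) // 2
        if n_aa < 0 or n_bb < 0:
            continue
        lp = (gammaln(n_ind + 1) - gammaln(n_aa + 1) - gammaln(n_het + 1)
              - gammaln(n_bb + 1) + n_het * np.log(2.0) - log_denom)
        out.append((n_het, float(np.exp(lp))))
    return tuple(out)


def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy–Weinberg test p value for one biallelic site.

    p = sum of the conditional probabilities of every heterozygote
    configuration no more probable than the observed one; monomorphic
    sites give p = 1.
    """
    n_ind = n_hom_ref + n_het + n_hom_alt
    n_a = 2 * n_hom_ref + n_het
    if n_ind == 0 or n_a == 0 or n_a == 2 * n_ind:
        return 1.0
    dist = _hwe_exact_cached(n_ind, n_a)
    p_obs = dict(dist)[n_het]
    p = sum(pr for _h, pr in dist if pr <= p_obs * (1.0 + 1e-12))
    return min(1.0, p)


def _genotype_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n0 = (dosages == 0).sum(axis=0)
    n1 = (dosages == 1).sum(axis=0)
    n2 = (dosages == 2).sum(axis=0)
    return n0, n1, n2


def population_diversity(dosages: np.ndarray) -> dict[str, float]:
    """All indicators for one population's dosage block (missing = -1),
    as unweighted means over sites with >= 1 called genotype."""
    n0, n1, n2 = _genotype_counts(dosages)
    n_called = n0 + n1 + n2
    ok = n_called > 0
    if not ok.any():
        raise ValueError("population has no called genotypes at any site")
    n0, n1, n2, n_called = n0[ok], n1[ok], n2[ok], n_called[ok]
    n_copies = 2 * n_called
    n_alt = 2 * n2 + n1
    x = n_alt / n_copies
    freqs = np.stack([1.0 - x, x], axis=1)
    he = expected_heterozygosity(freqs)
    ho = observed_heterozygosity(n1, n_called)
    p = pic(freqs)
    ne = effective_alleles(freqs)
    with np.errstate(invalid="ignore"):
        pi_vals = nucleotide_diversity(n_copies, n_alt)
    hw = np.array([hwe_exact_p(int(a), int(b), int(c))
                   for a, b, c in zip(n0, n1, n2)])
    mean_ne = float(np.mean(ne))
    return {
        "HW-P": float(np.mean(hw)),
        "He": float(np.mean(he)),
        "Ho": float(np.mean(ho)),
        "PIC": float(np.mean(p)),
        "Ne": mean_ne,
        "Pi": float(np.nanmean(pi_vals)),
        "drift_F": float(drift_coefficient(mean_ne)),
    }


def summarize(matrix: GenotypeMatrix, decimals: int = 3) -> pd.DataFrame:
    """Per-population diversity table plus a grand-mean row.

    Columns follow the conventional report layout (HW-P, He, Ho, PIC,
    Ne, Pi, plus the drift coefficient); values are rounded half-even
    to ``decimals``.
    """
    rows = {}
    for pop in matrix.population_names:
        block = matrix.dosages[matrix.populations == pop]
        if block.shape[0] == 0:
            raise ValueError(f"empty population {pop!r}")
        rows[pop] = population_diversity(block)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.loc["Mean"] = table.mean(axis=0)
    table.index.name = "Group"
    return table.round(decimals)
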