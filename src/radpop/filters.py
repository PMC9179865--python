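"""SNP retention filters producing the analysis-ready genotype matrix.

Four criteria, applied in order and logged per step:

1. call rate — keep sites genotyped in at least 80% of individuals;
2. minor allele frequency — discard MAF < 0.01 (pooled over the cohort);
3. biallelic — drop sites showing more than two alleles (sequencing or
   clustering artefacts);
4. tag SNP load — drop every SNP on a tag carrying more than two.

Given the pooled MAF definition the filters commute as set operations
on sites; the order only affects the per-step removal tallies.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._seq import HET_CODE
from .matrix import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


def call_rate(matrix: GenotypeMatrix) -> np.ndarray:
    return matrix.called_mask().mean(axis=0)


def filter_call_rate(matrix: GenotypeMatrix,
                     threshold: float = 0.80) -> GenotypeMatrix:
    """Keep sites whose non-missing fraction is >= threshold (inclusive)."""
    keep = np.flatnonzero(call_rate(matrix) >= threshold)
    logger.info("call-rate filter: %d -> %d sites", matrix.n_sites, keep.size)
    return matrix.take_sites(keep)


def minor_allele_frequency(matrix: GenotypeMatrix) -> np.ndarray:
    """Pooled MAF per site over all non-missing calls (0 where uncallable)."""
    d = matrix.dosages.astype(np.float64)
    called = matrix.called_mask()
    n = 2.0 * called.sum(axis=0)
    alt = np.where(called, d, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / n, 0.0)
    return np.minimum(p, 1.0 - p)


def filter_maf(matrix: GenotypeMatrix,
               threshold: float = 0.01) -> GenotypeMatrix:
    """Discard sites with pooled minor allele frequency < threshold."""
    keep = np.flatnonzero(minor_allele_frequency(matrix) >= threshold)
    logger.info("MAF filter: %d -> %d sites", matrix.n_sites, keep.size)
    return matrix.take_sites(keep)


def filter_biallelic(matrix: GenotypeMatrix,
                     n_alleles: np.ndarray | None = None) -> GenotypeMatrix:
    """Keep sites with exactly two observed alleles.

    ``n_alleles`` gives the raw observed allele count per site (from
    base-level tallies upstream); without it, allele count is inferred
    from the dosages (ref and alt each counted if observed).
    """
    if n_alleles is None:
        d = matrix.dosages
        has_ref = ((d == 0) | (d == 1)).any(axis=0)
        has_alt = ((d == 1) | (d == 2)).any(axis=0)
        n_alleles = has_ref.astype(int) + has_alt.astype(int)
    n_alleles = np.asarray(n_alleles)
    keep = np.flatnonzero(n_alleles == 2)
    logger.info("biallelic filter: %d -> %d sites", matrix.n_sites, keep.size)
    return matrix.take_sites(keep)


def filter_tag_snp_count(matrix: GenotypeMatrix,
                         max_per_tag: int = 2) -> GenotypeMatrix:
    """Drop, atomically, all SNPs on tags carrying more than ``max_per_tag``."""
    tags = matrix.sites["tag_id"]
    load = tags.map(tags.value_counts())
    keep = np.flatnonzero((load <= max_per_tag).to_numpy())
    logger.info("tag-load filter: %d -> %d sites", matrix.n_sites, keep.size)
    return matrix.take_sites(keep)


def apply_all(matrix: GenotypeMatrix,
              call_rate_threshold: float = 0.80,
              maf_threshold: float = 0.01,
              max_per_tag: int = 2,
              n_alleles: np.ndarray | None = None) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """The full chain in canonical order; returns per-step site counts."""
    def site_keys(gm: GenotypeMatrix) -> pd.Index:
        return pd.Index(gm.sites["tag_id"].astype(str) + "@"
                        + gm.sites["pos_in_tag"].astype(str))

    allele_counts = (pd.Series(np.asarray(n_alleles), index=site_keys(matrix))
                     if n_alleles is not None else None)
    steps = [("input", matrix)]
    m = filter_call_rate(matrix, call_rate_threshold)
    steps.append(("call_rate", m))
    m = filter_maf(m, maf_threshold)
    steps.append(("maf", m))
    sub_counts = (allele_counts.loc[site_keys(m)].to_numpy()
                  if allele_counts is not None else None)
    m = filter_biallelic(m, sub_counts)
    steps.append(("biallelic", m))
    m = filter_tag_snp_count(m, max_per_tag)
    steps.append(("tag_load", m))
    table = pd.DataFrame({"step": [s for s, _ in steps],
                          "sites": [x.n_sites for _, x in steps]})
    return m, table


def concat_genotype_strings(matrix: GenotypeMatrix,
                            missing_char: str = "-") -> dict[str, str]:
    """One character per site per individual, head-to-tail.

    Homozygotes give the base itself, heterozygotes the IUPAC ambiguity
    code (so het vs hom differs by exactly one character under
    p-distance), missing gives ``missing_char``.
    """
    ref = matrix.sites["ref"].to_numpy()
    alt = matrix.sites["alt"].to_numpy()
    het = np.array([HET_CODE.get(frozenset((r, a)), "N")
                    for r, a in zip(ref, alt)])
    lut = np.stack([ref, het, alt, np.full(matrix.n_sites, missing_char)])
    idx = np.where(matrix.dosages == MISSING, 3, matrix.dosages)
    out = {}
    for i, sample in enumerate(matrix.samples):
        out[sample] = "".join(lut[idx[i], np.arange(matrix.n_sites)])
    return out
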