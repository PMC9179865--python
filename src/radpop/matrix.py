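"""Core containers: genotype matrix and per-population allele frequencies.

Genotypes are stored as alt-allele dosages (0, 1, 2) in an
individuals x sites ``int8`` array with ``-1`` as the missing sentinel,
alongside a site-metadata table and one population label per individual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic sites, alt-allele dosage {0,1,2,-1=missing}.

    ``sites`` carries at least columns ``tag_id``, ``pos_in_tag``,
    ``ref`` and ``alt``; pipeline stages may add ``contig``/``pos``.
    """

    dosages: np.ndarray                      # (n_ind, n_sites) int8
    sites: pd.DataFrame
    samples: list[str]
    populations: np.ndarray                  # (n_ind,) labels

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.populations = np.asarray(self.populations)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x sites)")
        n_ind, n_sites = self.dosages.shape
        if len(self.samples) != n_ind or len(self.populations) != n_ind:
            raise ValueError("sample/population labels must match row count")
        if len(self.sites) != n_sites:
            raise ValueError("site table must match column count")
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or -1 (missing)")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def population_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(str(p), None)
        return list(seen)

    def called_mask(self) -> np.ndarray:
        return self.dosages != MISSING

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[:, index],
                              self.sites.iloc[index].reset_index(drop=True),
                              list(self.samples), self.populations.copy())

    def subset_population(self, name: str) -> "GenotypeMatrix":
        rows = np.flatnonzero(self.populations == name)
        if rows.size == 0:
            raise ValueError(f"no individuals in population {name!r}")
        return GenotypeMatrix(self.dosages[rows],
                              self.sites.copy(),
                              [self.samples[i] for i in rows],
                              self.populations[rows])


@dataclass
class AlleleFrequencyTable:
    """Alt-allele frequency and called-genotype count per population x site."""

    populations: list[str]
    alt_freq: np.ndarray      # (n_pops, n_sites) float, nan where uncallable
    n_called: np.ndarray = field(default=None)  # (n_pops, n_sites) int

    @classmethod
    def from_matrix(cls, matrix: GenotypeMatrix) -> "AlleleFrequencyTable":
        pops = matrix.population_names
        n_sites = matrix.n_sites
        freq = np.full((len(pops), n_sites), np.nan)
        n_called = np.zeros((len(pops), n_sites), dtype=np.int64)
        for k, pop in enumerate(pops):
            rows = matrix.populations == pop
            d = matrix.dosages[rows].astype(np.float64)
            called = d != MISSING
            n = called.sum(axis=0)
            alt = np.where(called, d, 0.0).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                freq[k] = np.where(n > 0, alt / (2.0 * n), np.nan)
            n_called[k] = n
        return cls(pops, freq, n_called)

    def frequencies(self, pop: str) -> np.ndarray:
        """Alt-allele frequencies for one population (nan = no calls)."""
        return self.alt_freq[self.populations.index(pop)]
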