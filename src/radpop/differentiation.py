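"""Pairwise population differentiation and the neighbor-joining tree.

F_ST is the Weir–Cockerham (1984) theta: per-locus variance components
a (among populations), b (among individuals within populations) and
c (within individuals), combined across loci as a ratio of sums
(sum a / sum(a+b+c)).  The companion genetic distance is
DR = -ln(1 - F_ST), the log transform that linearises differentiation
for tree building.  Individual-level trees come from p-distances over
concatenated genotype strings, clustered with Saitou–Nei
neighbor joining and assessed by site-bootstrap support.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix


# ---------------------------------------------------------------------------
# Weir–Cockerham theta

def _pop_stats(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (n called, alt frequency, het fraction) for one block."""
    called = dosages != MISSING
    n = called.sum(axis=0).astype(np.float64)
    alt = np.where(called, dosages, 0).sum(axis=0)
    het = np.where(called, dosages == 1, False).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def weir_cockerham_components(blocks: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus variance components (a, b, c) for r population blocks.

    Loci where any population has no called genotype, or with mean
    sample size <= 1, are set to nan in all three components.
    """
    r = len(blocks)
    if r < 2:
        raise ValueError("need at least two populations")
    stats = [_pop_stats(b) for b in blocks]
    n = np.stack([s[0] for s in stats])          # (r, L)
    p = np.stack([s[1] for s in stats])
    h = np.stack([s[2] for s in stats])
    bad = (n < 1).any(axis=0)
    nbar = n.mean(axis=0)
    bad |= nbar <= 1
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar)
                                 - (r - 1) / r * s2
                                 - hbar / 4.0) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar)
                                   - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
    bad |= nc <= 0
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def fst_weir_cockerham(matrix: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Multi-locus Weir–Cockerham theta between two labelled populations.

    Ratio of sums across loci; loci monomorphic across both populations
    contribute zero to numerator and denominator alike.  The estimator
    can be slightly negative when there is no between-group variance.
    """
    block_a = matrix.subset_population(pop_a).dosages
    block_b = matrix.subset_population(pop_b).dosages
    if block_a.shape[0] < 2 or block_b.shape[0] < 2:
        raise ValueError("each population needs >= 2 genotyped individuals")
    a, b, c = weir_cockerham_components([block_a, block_b])
    ok = ~np.isnan(a)
    if not ok.any():
        raise ValueError(f"no shared informative sites between {pop_a} and {pop_b}")
    denom = (a + b + c)[ok].sum()
    if denom == 0:
        return 0.0
    return float(a[ok].sum() / denom)


def dr_distance(fst: float) -> float:
    """Genetic distance DR = -ln(1 - F_ST); requires 0 <= F_ST < 1."""
    if not (0.0 <= fst < 1.0):
        raise ValueError(f"F_ST must be in [0, 1), got {fst}")
    return -math.log1p(-fst)


@dataclass
class PairwiseMatrix:
    """Population x population table: F_ST in the lower triangle,
    DR in the upper triangle, empty diagonal."""

    populations: list[str]
    fst: np.ndarray           # symmetric storage of theta
    dr: np.ndarray

    def to_frame(self, decimals: int = 3) -> pd.DataFrame:
        k = len(self.populations)
        out = pd.DataFrame("", index=self.populations, columns=self.populations)
        for i in range(k):
            for j in range(k):
                if i > j:
                    out.iat[i, j] = f"{self.fst[i, j]:.{decimals}f}"
                elif i < j:
                    out.iat[i, j] = f"{self.dr[i, j]:.{decimals}f}"
        return out

    def to_tsv(self, path, decimals: int = 3) -> None:
        self.to_frame(decimals).to_csv(path, sep="\t", index_label="Group")


def pairwise_differentiation(matrix: GenotypeMatrix) -> PairwiseMatrix:
    """All pairwise thetas and their DR transforms.

    Negative theta estimates are clamped to zero before the log
    transform (DR is undefined below zero by construction).
    """
    pops = matrix.population_names
    k = len(pops)
    fst = np.zeros((k, k))
    dr = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            theta = fst_weir_cockerham(matrix, pops[i], pops[j])
            fst[i, j] = fst[j, i] = theta
            dr[i, j] = dr[j, i] = dr_distance(max(theta, 0.0))
    return PairwiseMatrix(pops, fst, dr)


# ---------------------------------------------------------------------------
# p-distances and neighbor joining

def p_distance(strings: dict[str, str] | list[str],
               missing_char: str = "-") -> tuple[np.ndarray, list[str]]:
    """Pairwise fraction of differing characters over positions where
    neither sequence is missing.  Raises if any pair has no comparable
    positions or lengths differ."""
    if isinstance(strings, dict):
        names = list(strings)
        seqs = [strings[n] for n in names]
    else:
        names = [f"seq{i}" for i in range(len(strings))]
        seqs = list(strings)
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("genotype strings must have equal length")
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    arr = arr.reshape(len(seqs), -1)
    present = arr != ord(missing_char)
    n = len(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        both = present[i] & present[i + 1:]
        comparable = both.sum(axis=1)
        if (comparable == 0).any():
            j = i + 1 + int(np.flatnonzero(comparable == 0)[0])
            raise ValueError(f"no comparable positions between {names[i]} and {names[j]}")
        diff = (both & (arr[i] != arr[i + 1:])).sum(axis=1)
        dist[i, i + 1:] = dist[i + 1:, i] = diff / comparable
    return dist, names


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> set[str]:
        if self.is_leaf():
            return {self.name}
        out: set[str] = set()
        for child, _bl in self.children:
            out |= child.leaves()
        return out

    def newick(self, with_support: bool = False) -> str:
        return self._nwk(with_support) + ";"

    def _nwk(self, ws: bool) -> str:
        if self.is_leaf():
            return self.name
        inner = ",".join(f"{c._nwk(ws)}:{bl:.6g}" for c, bl in self.children)
        label = ""
        if ws and self.support is not None:
            label = f"{self.support:g}"
        return f"({inner}){label}"


def nj_tree(dist: np.ndarray, names: list[str]) -> TreeNode:
    """Saitou–Nei neighbor joining with the standard Q criterion.

    Ties in Q break toward the pair with the lowest (row, column)
    index in current join order; negative branch lengths are clamped to
    zero with the excess moved to the sister branch.  Returns an
    unrooted tree (trifurcating root) with branch lengths.
    """
    dist = np.asarray(dist, dtype=np.float64)
    n = len(names)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=nm) for nm in names]
    D = dist.copy()
    active = list(range(n))

    def join(i_pos: int, j_pos: int) -> None:
        """Join the clusters at positions i_pos < j_pos of `active`."""
        nonlocal D
        r = len(active)
        R = D.sum(axis=1)
        d_ij = D[i_pos, j_pos]
        li = d_ij / 2.0 + (R[i_pos] - R[j_pos]) / (2.0 * (r - 2)) if r > 2 else d_ij / 2.0
        lj = d_ij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new = TreeNode(children=[(nodes[active[i_pos]], li),
                                 (nodes[active[j_pos]], lj)])
        d_new = (D[i_pos] + D[j_pos] - d_ij) / 2.0
        keep = [k for k in range(r) if k not in (i_pos, j_pos)]
        D2 = np.zeros((len(keep) + 1, len(keep) + 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D = D2
        nodes.append(new)
        new_active = [active[k] for k in keep] + [len(nodes) - 1]
        active[:] = new_active

    while len(active) > 3:
        r = len(active)
        R = D.sum(axis=1)
        Q = (r - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                if best is None or Q[i, j] < Q[best[0], best[1]] - 1e-15:
                    best = (i, j)
        join(*best)

    # final trifurcation
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = max((d01 + d02 - d12) / 2.0, 0.0)
    l1 = max((d01 + d12 - d02) / 2.0, 0.0)
    l2 = max((d02 + d12 - d01) / 2.0, 0.0)
    root = TreeNode(children=[(nodes[active[0]], l0),
                              (nodes[active[1]], l1),
                              (nodes[active[2]], l2)])
    return root


def _bipartitions(tree: TreeNode, all_leaves: frozenset[str]) -> dict[frozenset[str], TreeNode]:
    """Internal bipartitions, keyed canonically by the side not holding
    the lexicographically smallest leaf."""
    anchor = min(all_leaves)
    out: dict[frozenset[str], TreeNode] = {}

    def walk(node: TreeNode) -> None:
        for child, _bl in node.children:
            if not child.is_leaf():
                side = frozenset(child.leaves())
                if anchor in side:
                    side = all_leaves - side
                if 1 < len(side) < len(all_leaves) - 1:
                    out[side] = child
                walk(child)

    walk(tree)
    return out


def bootstrap_support(strings: dict[str, str],
                      n_replicates: int = 1000,
                      seed: int = 0,
                      missing_char: str = "-") -> TreeNode:
    """Site-bootstrap support for the NJ tree of concatenated genotypes.

    Columns are resampled with replacement, the tree rebuilt per
    replicate, and each internal bipartition of the reference tree
    annotated with its replicate frequency (0-100).
    """
    names = list(strings)
    if len(names) < 4:
        raise ValueError("bootstrap support needs >= 4 taxa")
    dist, _ = p_distance(strings, missing_char)
    if dist.max() == 0:
        raise ValueError("all genotype strings identical; tree is degenerate")
    ref = nj_tree(dist, names)
    all_leaves = frozenset(names)
    ref_bips = _bipartitions(ref, all_leaves)
    counts = {bip: 0 for bip in ref_bips}
    L = len(next(iter(strings.values())))
    arr = np.frombuffer("".join(strings[n] for n in names).encode(),
                        dtype=np.uint8).reshape(len(names), L)
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        sample = {nm: arr[i, cols].tobytes().decode() for i, nm in enumerate(names)}
        try:
            d_rep, _ = p_distance(sample, missing_char)
        except ValueError:
            continue
        rep = nj_tree(d_rep, names)
        for bip in _bipartitions(rep, all_leaves):
            if bip in counts:
                counts[bip] += 1
    for bip, node in ref_bips.items():
        node.support = round(100.0 * counts[bip] / n_replicates)
    return ref
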