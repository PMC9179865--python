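"""Read assignment and maximum-likelihood diploid genotyping.

Reads are trimmed to tag length, so alignment reduces to Hamming
comparison against the tag panel (both orientations) with a two-mismatch
budget and no random placement of ambiguous reads: a read matching more
than one tag equally well is discarded.  Per-site allele depths then
feed a three-genotype binomial likelihood — hom-ref: Bin(n_alt | n, e),
het: Bin(n_alt | n, 1/2), hom-alt: Bin(n_alt | n, 1-e) — and the call is
the argmax, or missing below ``min_depth``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from ._seq import revcomp
from .digest import TagPanel
from .matrix import MISSING, GenotypeMatrix
from .qc import Read

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


@dataclass(frozen=True)
class AlignmentPolicy:
    """Mismatch budget and multi-mapping rules for tag assignment."""

    max_mismatches: int = 2
    allow_multi_mapping: bool = False
    report_best_only: bool = True


@dataclass
class BaseCounts:
    """Per individual x tag x position x base depth tallies."""

    counts: np.ndarray          # (n_ind, n_tags, tag_len, 4) uint32
    samples: list[str]
    panel: TagPanel
    unassigned: int = 0
    skipped_length: int = 0


def _encode(seqs: list[str], length: int) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return arr.reshape(len(seqs), length)


def assign_reads(reads_by_sample: dict[str, list[Read]],
                 panel: TagPanel,
                 policy: AlignmentPolicy | None = None) -> BaseCounts:
    """Assign each read to its unique best-matching tag.

    Exact matches (either orientation) resolve by hash; the remainder
    are compared to every tag by vectorised Hamming distance.  Reads
    tying between tags, exceeding the mismatch budget, or of the wrong
    length are dropped and tallied.
    """
    policy = policy or AlignmentPolicy()
    n_tags = len(panel)
    tag_len = len(panel[0].sequence) if n_tags else 0
    samples = list(reads_by_sample)
    counts = np.zeros((len(samples), n_tags, tag_len, 4), dtype=np.uint32)
    fwd = _encode(panel.sequences(), tag_len)
    rev = _encode([revcomp(s) for s in panel.sequences()], tag_len)
    exact: dict[str, tuple[int, str] | None] = {}
    for j, t in enumerate(panel):
        for s, orient in ((t.sequence, "+"), (revcomp(t.sequence), "-")):
            # a sequence seen for two tags is inherently ambiguous
            if s in exact and exact[s] is not None and exact[s][0] != j:
                exact[s] = None
            elif s not in exact:
                exact[s] = (j, orient)
    unassigned = skipped = 0
    for si, sample in enumerate(samples):
        reads = reads_by_sample[sample]
        pending: list[str] = []
        for _name, seq, _qual in reads:
            if len(seq) != tag_len:
                skipped += 1
                continue
            hit = exact.get(seq, -1)
            if hit is None:
                unassigned += 1
            elif hit != -1:
                j, orient = hit
                _tally(counts, si, j, seq, panel[j], orient)
            else:
                pending.append(seq)
        if pending:
            enc = _encode(pending, tag_len)
            for row, seq in zip(enc, pending):
                d_f = (fwd != row).sum(axis=1)
                d_r = (rev != row).sum(axis=1)
                d = np.minimum(d_f, d_r)
                best = int(d.min()) if n_tags else tag_len
                if best > policy.max_mismatches or (d == best).sum() > 1:
                    unassigned += 1
                    continue
                j = int(d.argmin())
                _tally(counts, si, j, seq, panel[j],
                       orient="-" if d_r[j] < d_f[j] else "+")
    return BaseCounts(counts, samples, panel, unassigned, skipped)


def _tally(counts: np.ndarray, si: int, j: int, seq: str, tag,
           orient: str = "+") -> None:
    if orient == "-":
        seq = revcomp(seq)
    for pos, base in enumerate(seq):
        bi = _BASE_INDEX.get(base)
        if bi is not None:
            counts[si, j, pos, bi] += 1


def discover_sites(base_counts: BaseCounts,
                   min_depth: int = 5,
                   min_individuals: int = 2) -> pd.DataFrame:
    """Candidate SNP sites: tag positions where at least
    ``min_individuals`` individuals carry a non-reference base at
    ``min_depth`` or more copies.  The alt allele is the most frequent
    non-reference base across the cohort."""
    panel = base_counts.panel
    rows = []
    for j, tag in enumerate(panel):
        tag_counts = base_counts.counts[:, j]              # (n_ind, L, 4)
        for pos, ref in enumerate(tag.sequence):
            ri = _BASE_INDEX.get(ref)
            if ri is None:
                continue
            nonref = tag_counts[:, pos, :].copy()
            nonref[:, ri] = 0
            support = (nonref >= min_depth).any(axis=1).sum()
            if support >= min_individuals:
                alt_i = int(nonref.sum(axis=0).argmax())
                rows.append({"tag_id": tag.tag_id, "tag_index": j,
                             "pos_in_tag": pos, "contig": tag.contig,
                             "ref": ref, "alt": _BASES[alt_i]})
    return pd.DataFrame(rows, columns=["tag_id", "tag_index", "pos_in_tag",
                                       "contig", "ref", "alt"])


def site_allele_depths(base_counts: BaseCounts,
                       sites: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(n_ref, n_alt) per individual x site; other bases are ignored."""
    n_ind = len(base_counts.samples)
    n_sites = len(sites)
    n_ref = np.zeros((n_ind, n_sites), dtype=np.int64)
    n_alt = np.zeros((n_ind, n_sites), dtype=np.int64)
    for s, row in enumerate(sites.itertuples()):
        c = base_counts.counts[:, row.tag_index, row.pos_in_tag, :]
        n_ref[:, s] = c[:, _BASE_INDEX[row.ref]]
        n_alt[:, s] = c[:, _BASE_INDEX[row.alt]]
    return n_ref, n_alt


def genotype_loglik(n_ref, n_alt, error_rate: float = 0.01) -> np.ndarray:
    """Log-likelihoods of (hom-ref, het, hom-alt), broadcast over inputs."""
    if not (0.0 < error_rate < 0.5):
        raise ValueError("error_rate must be in (0, 0.5)")
    n_ref = np.asarray(n_ref)
    n_alt = np.asarray(n_alt)
    n = n_ref + n_alt
    return np.stack([binom.logpmf(n_alt, n, p)
                     for p in (error_rate, 0.5, 1.0 - error_rate)], axis=-1)


def call_genotype(n_ref, n_alt,
                  error_rate: float = 0.01,
                  min_depth: int = 5) -> np.ndarray:
    """ML genotype call (alt dosage 0/1/2), missing where depth < min_depth.

    Ties resolve toward the lower dosage (argmax of the first maximum),
    which can only occur at degenerate depth-0 input.
    """
    ll = genotype_loglik(n_ref, n_alt, error_rate)
    calls = ll.argmax(axis=-1).astype(np.int8)
    depth = np.asarray(n_ref) + np.asarray(n_alt)
    calls = np.where(depth < min_depth, np.int8(MISSING), calls)
    return calls


def genotype_cohort(base_counts: BaseCounts,
                    populations: np.ndarray | list[str],
                    error_rate: float = 0.01,
                    min_depth: int = 5,
                    min_individuals: int = 2) -> tuple[GenotypeMatrix, np.ndarray, np.ndarray]:
    """Discover sites and call every individual; returns the genotype
    matrix plus the (n_ref, n_alt) depth arrays behind it."""
    sites = discover_sites(base_counts, min_depth, min_individuals)
    n_ref, n_alt = site_allele_depths(base_counts, sites)
    calls = call_genotype(n_ref, n_alt, error_rate, min_depth)
    gm = GenotypeMatrix(calls, sites, list(base_counts.samples),
                        np.asarray(populations))
    return gm, n_ref, n_alt


def write_vcf(matrix: GenotypeMatrix, path,
              n_ref: np.ndarray | None = None,
              n_alt: np.ndarray | None = None) -> None:
    """Plain-text VCF 4.2; sites with no alternate observation are omitted.

    POS is 1-based per VCF convention (tag-relative when no absolute
    coordinates are present).
    """
    if len(set(matrix.samples)) != len(matrix.samples):
        raise ValueError("duplicate sample names")
    gt_map = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    has_ad = n_ref is not None and n_alt is not None
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if has_ad:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        contigs = {}
        for row in matrix.sites.itertuples():
            contigs.setdefault(getattr(row, "contig", row.tag_id), None)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        fmt = "GT:AD:DP" if has_ad else "GT"
        for s, row in enumerate(matrix.sites.itertuples()):
            col = matrix.dosages[:, s]
            if not ((col == 1) | (col == 2)).any():
                continue
            chrom = getattr(row, "contig", row.tag_id)
            pos = getattr(row, "pos", None)
            if pos is None or (isinstance(pos, float) and np.isnan(pos)):
                pos = row.pos_in_tag
            site_id = f"{row.tag_id}@{row.pos_in_tag}"
            fields = [str(chrom), str(int(pos) + 1), site_id, row.ref, row.alt,
                      ".", "PASS", ".", fmt]
            for i in range(matrix.n_individuals):
                g = gt_map[int(col[i])]
                if has_ad:
                    g += f":{int(n_ref[i, s])},{int(n_alt[i, s])}:{int(n_ref[i, s] + n_alt[i, s])}"
                fields.append(g)
            fh.write("\t".join(fields) + "\n")


def read_vcf(path, populations: dict[str, str] | None = None) -> GenotypeMatrix:
    """Load a VCF into a GenotypeMatrix via cyvcf2."""
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosage_cols = []
    rows = []
    for var in vcf:
        gts = var.genotype.array()
        d = gts[:, 0] + gts[:, 1]
        d[(gts[:, 0] < 0) | (gts[:, 1] < 0)] = MISSING
        dosage_cols.append(d.astype(np.int8))
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        tag_id, _, pos_in_tag = vid.partition("@")
        rows.append({"tag_id": tag_id,
                     "pos_in_tag": int(pos_in_tag) if pos_in_tag else 0,
                     "contig": var.CHROM, "pos": var.POS - 1,
                     "ref": var.REF, "alt": var.ALT[0] if var.ALT else "."})
    dosages = (np.stack(dosage_cols, axis=1) if dosage_cols
               else np.zeros((len(samples), 0), dtype=np.int8))
    sites = pd.DataFrame(rows, columns=["tag_id", "pos_in_tag", "contig",
                                        "pos", "ref", "alt"])
    if populations is None:
        pops = np.array([s.split("_")[0] for s in samples])
    else:
        pops = np.array([populations[s] for s in samples])
    return GenotypeMatrix(dosages, sites, samples, pops)
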