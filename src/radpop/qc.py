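"""Read processing: pair merging, trimming, and the three read filters.

The chain mirrors standard 2b-RAD practice: merge overlapping paired-end
reads into single tag-spanning fragments, trim adaptors and the final
three bases (ligation-site artefacts), then drop reads that are
ambiguous (>8% N), poor quality (>=15% of positions below Q30), or
missing the restriction recognition site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ._seq import find_all_overlapping, revcomp
from .digest import RecognitionMotif

PHRED_OFFSET = 33


@dataclass
class QCConfig:
    """Filter thresholds; defaults are the pipeline's canonical values.

    The N rule is a strict "more than 8%"; the quality rule removes a
    read when the fraction of positions below ``low_qual_phred`` is
    >= ``max_lowqual_fraction`` (boundary inclusive — switchable via
    ``lowqual_strict``).
    """

    max_n_fraction: float = 0.08
    low_qual_phred: int = 30
    max_lowqual_fraction: float = 0.15
    lowqual_strict: bool = False     # True -> remove only when fraction > threshold
    trim_terminal: int = 3
    min_length: int = 20
    adaptor_sequences: list[str] = field(default_factory=list)
    require_motif: RecognitionMotif = field(default_factory=RecognitionMotif)


@dataclass
class QCReport:
    input_reads: int = 0
    merged: int = 0
    removed_n: int = 0
    removed_quality: int = 0
    removed_no_site: int = 0
    retained: int = 0

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tcount\n")
            for k, v in vars(self).items():
                fh.write(f"{k}\t{v}\n")


Read = tuple[str, str, str]   # (name, sequence, quality)


def read_fastq(path) -> list[Read]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator
    with open(path) as fh:
        return [(n, s.upper(), q) for n, s, q in FastqGeneralIterator(fh)]


def write_fastq(reads: list[Read], path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def merge_pairs(r1: list[Read], r2: list[Read],
                min_overlap: int = 10,
                max_mismatch_frac: float = 0.1) -> tuple[list[Read], int]:
    """Merge mates by suffix-prefix overlap.

    Mate 2 is reverse-complemented, the longest overlap >= ``min_overlap``
    with mismatch fraction <= ``max_mismatch_frac`` is taken, and each
    overlapped position keeps the higher-quality base.  Unmergeable
    pairs are dropped; returns (merged reads, dropped count).
    """
    if len(r1) != len(r2):
        raise ValueError(f"mate count mismatch: {len(r1)} vs {len(r2)}")
    merged: list[Read] = []
    dropped = 0
    for (n1, s1, q1), (_n2, s2, q2) in zip(r1, r2):
        s2rc = revcomp(s2)
        q2rc = q2[::-1]
        hit = None
        for olen in range(min(len(s1), len(s2rc)), min_overlap - 1, -1):
            a, b = s1[len(s1) - olen:], s2rc[:olen]
            mism = sum(x != y for x, y in zip(a, b))
            if mism / olen <= max_mismatch_frac:
                hit = olen
                break
        if hit is None:
            dropped += 1
            continue
        olen = hit
        seq = list(s1[:len(s1) - olen])
        qual = list(q1[:len(s1) - olen])
        for i in range(olen):
            i1, i2 = len(s1) - olen + i, i
            if ord(q2rc[i2]) > ord(q1[i1]):
                seq.append(s2rc[i2]); qual.append(q2rc[i2])
            else:
                seq.append(s1[i1]); qual.append(q1[i1])
        seq += list(s2rc[olen:])
        qual += list(q2rc[olen:])
        merged.append((n1, "".join(seq), "".join(qual)))
    return merged, dropped


def trim_read(read: Read, config: QCConfig | None = None) -> Read | None:
    """Strip exact adaptor prefixes/suffixes, then the final bases.

    Returns None (caller counts the drop) when the trimmed read falls
    below ``min_length``.
    """
    config = config or QCConfig()
    name, seq, qual = read
    for ad in config.adaptor_sequences:
        if ad and seq.startswith(ad):
            seq, qual = seq[len(ad):], qual[len(ad):]
        if ad and seq.endswith(ad):
            seq, qual = seq[:-len(ad)], qual[:-len(ad)]
    t = config.trim_terminal
    if t > 0:
        seq, qual = seq[:-t], qual[:-t]
    if len(seq) < config.min_length:
        return None
    return (name, seq, qual)


def _has_motif(seq: str, motif: RecognitionMotif) -> bool:
    return bool(re.search(motif.forward_pattern, seq)
                or re.search(motif.reverse_pattern, seq))


def filter_reads(reads: list[Read],
                 config: QCConfig | None = None) -> tuple[list[Read], QCReport]:
    """Apply the three read filters in order: N content, quality, motif.

    The filters are independent predicates — each read is charged to the
    first one it fails — so the retained set does not depend on order.
    """
    config = config or QCConfig()
    report = QCReport(input_reads=len(reads), merged=len(reads))
    retained: list[Read] = []
    thr_q = config.low_qual_phred + PHRED_OFFSET
    for read in reads:
        name, seq, qual = read
        L = len(seq)
        if L == 0:
            report.removed_n += 1
            continue
        if seq.count("N") / L > config.max_n_fraction:
            report.removed_n += 1
            continue
        lowq = sum(ord(c) < thr_q for c in qual) / L
        bad_q = lowq > config.max_lowqual_fraction if config.lowqual_strict \
            else lowq >= config.max_lowqual_fraction
        if bad_q:
            report.removed_quality += 1
            continue
        if not _has_motif(seq, config.require_motif):
            report.removed_no_site += 1
            continue
        retained.append(read)
    report.retained = len(retained)
    return retained, report


def process_reads(r1: list[Read], r2: list[Read] | None = None,
                  config: QCConfig | None = None,
                  min_overlap: int = 10,
                  max_mismatch_frac: float = 0.1) -> tuple[list[Read], QCReport]:
    """Full chain: (optional) merge, trim, filter."""
    config = config or QCConfig()
    n_input = len(r1)
    if r2 is not None:
        merged, _dropped = merge_pairs(r1, r2, min_overlap, max_mismatch_frac)
    else:
        merged = list(r1)
    trimmed = [t for t in (trim_read(r, config) for r in merged) if t is not None]
    retained, report = filter_reads(trimmed, config)
    report.input_reads = n_input
    # `merged` counts reads entering the filters (post-trim), so that
    # retained = merged - removed_n - removed_quality - removed_no_site.
    report.merged = len(trimmed)
    return retained, report
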