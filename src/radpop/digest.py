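"""In-silico type-IIB restriction digestion.

Type-IIB enzymes such as BsaXI recognise a bipartite site (AC-N5-CTCC for
BsaXI) and cut on *both* sides of it, releasing a uniform-length fragment.
2b-RAD exploits this: every copy of the genome yields the same set of
fixed-length tags, which after sequencing serve as the reference windows
for SNP discovery.  This module scans a reference genome for the
recognition motif on both strands and extracts the flanked tag windows.

Coordinates are 0-based half-open throughout; FASTA output headers carry
``contig:start-end:strand``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio import SeqIO

from ._seq import find_all_overlapping, iupac_regex, revcomp

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RecognitionMotif:
    """A bipartite type-IIB recognition site plus tag-window geometry.

    The default is BsaXI: AC, a 5-base spacer, CTCC (11 bp recognised
    span), with 12 bp upstream and 10 bp downstream flanks giving a
    33-bp tag.  The exact duplex cut offsets of BsaXI are configurable
    rather than hard-coded; the 12+11+10 window is this package's
    documented default.
    """

    left_part: str = "AC"
    spacer_length: int = 5
    right_part: str = "CTCC"
    upstream_flank: int = 12
    downstream_flank: int = 10

    @property
    def site_length(self) -> int:
        return len(self.left_part) + self.spacer_length + len(self.right_part)

    @property
    def tag_length(self) -> int:
        return self.upstream_flank + self.site_length + self.downstream_flank

    @property
    def forward_pattern(self) -> str:
        return (iupac_regex(self.left_part)
                + "[ACGT]" * self.spacer_length
                + iupac_regex(self.right_part))

    @property
    def reverse_pattern(self) -> str:
        # motif on the minus strand == reverse complement on the plus strand
        return (iupac_regex(revcomp(self.right_part))
                + "[ACGT]" * self.spacer_length
                + iupac_regex(revcomp(self.left_part)))


@dataclass(frozen=True)
class Tag:
    tag_id: str
    contig: str
    start: int   # 0-based, half-open window on the forward strand
    end: int
    strand: str  # '+' or '-'
    sequence: str


@dataclass
class TagPanel:
    """The digest of a reference: uniform-length tags with coordinates."""

    tags: list[Tag] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.tags)

    def __iter__(self):
        return iter(self.tags)

    def __getitem__(self, i: int) -> Tag:
        return self.tags[i]

    def sequences(self) -> list[str]:
        return [t.sequence for t in self.tags]

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.tags:
                fh.write(f">{t.tag_id}\n{t.sequence}\n")

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.tags:
                fh.write(f"{t.contig}\t{t.start}\t{t.end}\t{t.tag_id}\t0\t{t.strand}\n")


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file into an ordered contig -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def scan_motif(reference: Mapping[str, str] | str,
               motif: RecognitionMotif | None = None) -> list[tuple[str, int, str]]:
    """Find every recognition-site occurrence on both strands.

    Returns ``(contig, start, strand)`` triples where *start* is the
    0-based forward-strand start of the recognised span.  Overlapping
    matches are all reported; order is (contig, start, strand).
    """
    motif = motif or RecognitionMotif()
    if isinstance(reference, str):
        reference = read_fasta(reference)
    if not reference:
        raise ValueError("empty reference")
    fwd = motif.forward_pattern
    rev = motif.reverse_pattern
    hits: list[tuple[str, int, str]] = []
    for contig, seq in reference.items():
        seq = seq.upper()
        per_contig = [(contig, s, "+") for s in find_all_overlapping(fwd, seq)]
        per_contig += [(contig, s, "-") for s in find_all_overlapping(rev, seq)]
        per_contig.sort(key=lambda h: (h[1], h[2]))
        hits.extend(per_contig)
    return hits


def extract_tags(reference: Mapping[str, str] | str,
                 hits: Iterable[tuple[str, int, str]],
                 motif: RecognitionMotif | None = None) -> TagPanel:
    """Cut the flanked tag window around each recognition-site hit.

    Minus-strand tags are reverse-complemented so every tag reads
    5'->3' through the site.  Hits whose window would run off the
    contig are dropped (count logged).
    """
    motif = motif or RecognitionMotif()
    if isinstance(reference, str):
        reference = read_fasta(reference)
    panel = TagPanel()
    dropped = 0
    for contig, start, strand in hits:
        seq = reference[contig]
        if strand == "+":
            w_start = start - motif.upstream_flank
            w_end = start + motif.site_length + motif.downstream_flank
        else:
            # flanks are defined along the tag's own strand
            w_start = start - motif.downstream_flank
            w_end = start + motif.site_length + motif.upstream_flank
        if w_start < 0 or w_end > len(seq):
            dropped += 1
            continue
        window = seq[w_start:w_end].upper()
        if strand == "-":
            window = revcomp(window)
        tag_id = f"{contig}:{w_start}-{w_end}:{strand}"
        panel.tags.append(Tag(tag_id, contig, w_start, w_end, strand, window))
    if dropped:
        logger.info("extract_tags: dropped %d hits with out-of-bounds windows", dropped)
    return panel


def digest(reference: Mapping[str, str] | str,
           motif: RecognitionMotif | None = None) -> TagPanel:
    """Scan + extract in one call."""
    motif = motif or RecognitionMotif()
    if isinstance(reference, str):
        reference = read_fasta(reference)
    return extract_tags(reference, scan_motif(reference, motif), motif)
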