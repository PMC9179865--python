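"""Small sequence helpers shared across modules."""

from __future__ import annotations

import re

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn-",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn-")

# IUPAC letter -> set of concrete bases it stands for. Reference Ns are
# deliberately absent from every set: an N in the subject never matches.
IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

HET_CODE = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_regex(motif: str) -> str:
    """Translate an IUPAC motif into a concrete character class regex."""
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC character {ch!r} in motif")
        bases = IUPAC_SETS[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def iupac_matches(motif: str, window: str) -> bool:
    """Sliding-window IUPAC match: every subject base must be a concrete
    base allowed by the motif letter (subject N never matches)."""
    if len(motif) != len(window):
        return False
    for m, s in zip(motif.upper(), window.upper()):
        if m not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC character {m!r} in motif")
        if s not in IUPAC_SETS[m]:
            return False
    return True


def find_all_overlapping(pattern: str, text: str) -> list[int]:
    """Start positions of all (possibly overlapping) regex matches."""
    return [m.start() for m in re.finditer(f"(?={pattern})", text)]
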