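"""Synthetic 2b-RAD study generator with known ground truth.

Emulates the study design this package targets: five low-diversity carp
populations of fifteen diploids each, genotyped at tens of thousands of
biallelic SNPs carried on 33-bp BsaXI tags.  Three generators cover the
three pipeline entry points:

* :func:`simulate_reference` — a random genome with exactly ``n_sites``
  planted BsaXI recognition sites (and no accidental ones);
* :func:`simulate_genotypes` — Balding–Nichols structured genotypes
  (ancestral frequency ~ Beta, per-population frequency ~ Beta around it
  with spread set by a global F_ST, dosages ~ Binomial(2, p));
* :func:`simulate_reads` — per-individual tag reads at Poisson depth
  with substitution errors and N-masking.

Everything is deterministic given ``SimulationConfig.seed``; the three
generators draw from independent substreams of that seed, so each can be
rerun on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._seq import revcomp
from .digest import RecognitionMotif, TagPanel, digest
from .matrix import AlleleFrequencyTable, GenotypeMatrix

_BASES = np.array(list("ACGT"))

# substream indices off the master seed
_SS_REFERENCE, _SS_GENOTYPES, _SS_READS = 0, 1, 2


@dataclass
class SimulationConfig:
    """Study-design knobs.

    Defaults mirror the target study: 5 populations x 15 diploids,
    ~45,000 tag-SNPs, skewed ancestral frequencies giving expected
    heterozygosity near 0.12, and mild structure (global F_ST 0.05,
    within the 0.007-0.094 pairwise range the study reports).
    """

    n_populations: int = 5
    n_individuals_per_pop: int = 15
    n_sites: int = 45_000
    global_fst: float = 0.05
    ancestral_freq_beta: tuple[float, float] = (0.14, 1.0)
    genome_length: int = 9_000_000
    tag_length: int = 33
    read_error_rate: float = 0.005
    n_rate: float = 0.001
    depth_mean: float = 30.0
    terminal_pad: int = 3        # extra 3' bases mimicking ligation artefacts
    seed: int = 0
    motif: RecognitionMotif = field(default_factory=RecognitionMotif)

    def __post_init__(self) -> None:
        for name in ("n_populations", "n_individuals_per_pop"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        for name in ("global_fst", "read_error_rate", "n_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        a, b = self.ancestral_freq_beta
        if a <= 0 or b <= 0:
            raise ValueError("ancestral_freq_beta shapes must be positive")

    def rng(self, substream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed).spawn(3)[substream])

    def to_dict(self) -> dict:
        d = asdict(self)
        d["motif"] = asdict(self.motif)
        return d


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    true_genotypes: GenotypeMatrix
    true_pop_freqs: AlleleFrequencyTable
    planted_site_coords: list[tuple[str, int, str]] = field(default_factory=list)


def _population_labels(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    pops = [f"P{k + 1}" for k in range(config.n_populations)]
    samples = [f"{p}_{i + 1:02d}" for p in pops
               for i in range(config.n_individuals_per_pop)]
    labels = np.repeat(pops, config.n_individuals_per_pop)
    return samples, labels


def simulate_reference(config: SimulationConfig,
                       contig: str = "chr1") -> tuple[dict[str, str], list[tuple[str, int, str]]]:
    """Random genome containing exactly ``n_sites`` recognition sites.

    Sites are planted non-overlapping on a random strand at recorded
    coordinates; the background is rejection-cleaned so digestion finds
    the planted set and nothing else.  Returns the reference as a
    contig->sequence dict plus ``(contig, site_start, strand)`` triples
    (0-based forward-strand start of the recognised span).
    """
    motif = config.motif
    span = motif.site_length
    tag_len = motif.tag_length
    if config.genome_length < config.n_sites * 2 * tag_len:
        raise ValueError(
            f"genome_length {config.genome_length} cannot pack "
            f"{config.n_sites} non-overlapping {tag_len}-bp tags")
    rng = config.rng(_SS_REFERENCE)
    seq = rng.choice(_BASES, size=config.genome_length)

    protected: list[tuple[int, int]] = []
    planted: list[tuple[str, int, str]] = []

    def rescan() -> list[tuple[int, str]]:
        from .digest import scan_motif
        return [(s, st) for _, s, st in scan_motif({contig: "".join(seq)}, motif)]

    # fixed (non-spacer) offsets within the recognised span, per strand:
    # mutating a spacer base never breaks a match, so target these only
    n_left, n_right = len(motif.left_part), len(motif.right_part)
    fixed_fwd = list(range(n_left)) + list(range(n_left + motif.spacer_length, span))
    fixed_rev = list(range(n_right)) + list(range(n_right + motif.spacer_length, span))

    def scrub() -> None:
        """Mutate away every hit that is not a planted site."""
        want = {(s, st) for _, s, st in planted}
        for _ in range(1000):
            extra = [h for h in rescan() if h not in want]
            if not extra:
                return
            for start, strand in extra:
                offsets = fixed_fwd if strand == "+" else fixed_rev
                for off in offsets:
                    pos = start + off
                    if pos >= len(seq):
                        continue
                    if any(a <= pos < b for a, b in protected):
                        continue
                    choices = [b for b in "ACGT" if b != seq[pos]]
                    seq[pos] = rng.choice(np.array(choices))
                    break
        raise RuntimeError("could not scrub accidental motif sites")

    if config.n_sites > 0:
        # non-overlapping tag windows with >=1 bp gap and tag-length margins
        slot = tag_len + 1
        margin = tag_len
        free = config.genome_length - 2 * margin - config.n_sites * slot
        if free < 0:
            raise ValueError("infeasible packing of planted sites")
        offsets = np.sort(rng.integers(0, free + 1, size=config.n_sites))
        strands = rng.choice(np.array(["+", "-"]), size=config.n_sites)
        spacers = rng.choice(_BASES, size=(config.n_sites, motif.spacer_length))
        for i in range(config.n_sites):
            w_start = margin + offsets[i] + i * slot
            strand = str(strands[i])
            spacer = "".join(spacers[i])
            instance = motif.left_part + spacer + motif.right_part
            if strand == "-":
                site_start = w_start + motif.downstream_flank
                instance = revcomp(instance)
            else:
                site_start = w_start + motif.upstream_flank
            seq[site_start:site_start + span] = list(instance)
            protected.append((site_start, site_start + span))
            planted.append((contig, site_start, strand))
    scrub()
    reference = {contig: "".join(seq)}
    return reference, planted


def simulate_genotypes(config: SimulationConfig) -> GroundTruth:
    """Balding–Nichols structured genotypes for the configured cohort.

    Per site the ancestral alt frequency is Beta(alpha, beta); each
    population's frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) with
    F = ``global_fst`` (exactly p when F = 0); individual dosages are
    Binomial(2, population frequency).
    """
    rng = config.rng(_SS_GENOTYPES)
    a, b = config.ancestral_freq_beta
    n_pops = config.n_populations
    n_ind = config.n_individuals_per_pop
    p_anc = rng.beta(a, b, size=config.n_sites)
    F = config.global_fst
    if F == 0.0:
        pop_freq = np.tile(p_anc, (n_pops, 1))
    else:
        scale = (1.0 - F) / F
        alpha = np.clip(p_anc * scale, 1e-12, None)
        beta = np.clip((1.0 - p_anc) * scale, 1e-12, None)
        pop_freq = rng.beta(alpha, beta, size=(n_pops, config.n_sites))
    dosages = rng.binomial(
        2, np.repeat(pop_freq, n_ind, axis=0)).astype(np.int8)
    samples, labels = _population_labels(config)
    sites = pd.DataFrame({
        "tag_id": [f"site{j:06d}" for j in range(config.n_sites)],
        "pos_in_tag": np.zeros(config.n_sites, dtype=int),
        "ref": "A", "alt": "G",
    })
    gm = GenotypeMatrix(dosages, sites, samples, labels)
    freqs = AlleleFrequencyTable([f"P{k + 1}" for k in range(n_pops)],
                                 pop_freq.copy(),
                                 np.full((n_pops, config.n_sites), n_ind))
    return GroundTruth(gm, freqs, [])


def place_snps_on_tags(panel: TagPanel, config: SimulationConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Assign SNP i to tag i at a random flank position (never inside the
    recognition span, so alt reads keep their restriction site)."""
    motif = config.motif
    flank_positions = (list(range(motif.upstream_flank))
                       + list(range(motif.upstream_flank + motif.site_length,
                                    motif.tag_length)))
    rows = []
    for j, tag in enumerate(panel):
        pos = int(rng.choice(flank_positions))
        ref = tag.sequence[pos]
        alt = str(rng.choice(np.array([b for b in "ACGT" if b != ref])))
        rows.append({"tag_id": tag.tag_id, "tag_index": j, "pos_in_tag": pos,
                     "contig": tag.contig, "ref": ref, "alt": alt})
    return pd.DataFrame(rows)


def simulate_reads(truth: GroundTruth,
                   reference: dict[str, str],
                   config: SimulationConfig) -> tuple[dict[str, list[tuple[str, str, str]]], pd.DataFrame]:
    """Tag-length reads per individual at Poisson depth.

    The reference is digested, SNP j is placed on tag j, and every
    individual x tag pair receives Poisson(depth_mean) reads of the tag
    sequence carrying a sampled allele, with substitution errors at
    ``read_error_rate`` (low quality) and N-masking at ``n_rate``.
    Read names encode ``sample|tag_index|serial`` for truth tracking.

    Returns ``{sample: [(name, sequence, quality), ...]}`` plus the SNP
    placement table (also written into ``truth.true_genotypes.sites``).
    """
    if config.depth_mean <= 0:
        raise ValueError("depth_mean must be > 0")
    rng = config.rng(_SS_READS)
    panel = digest(reference, config.motif)
    gm = truth.true_genotypes
    if len(panel) < gm.n_sites:
        raise ValueError(f"reference provides {len(panel)} tags for {gm.n_sites} sites")
    placement = place_snps_on_tags(panel, config, rng)
    placement = placement.iloc[:gm.n_sites].reset_index(drop=True)
    # graft placement onto the truth's site table
    for col in ("tag_id", "pos_in_tag", "contig", "ref", "alt"):
        gm.sites[col] = placement[col].values
    gm.sites["tag_index"] = placement["tag_index"].values

    qual_hi, qual_err, qual_n = "I", "+", "#"   # Q40 / Q10 / Q2
    reads_by_sample: dict[str, list[tuple[str, str, str]]] = {s: [] for s in gm.samples}
    tag_seqs = [panel[int(t)].sequence for t in placement["tag_index"]]
    for i, sample in enumerate(gm.samples):
        depths = rng.poisson(config.depth_mean, size=gm.n_sites)
        for j in range(gm.n_sites):
            d = int(depths[j])
            if d == 0:
                continue
            dosage = int(gm.dosages[i, j])
            pos = int(placement.at[j, "pos_in_tag"])
            ref, alt = placement.at[j, "ref"], placement.at[j, "alt"]
            if dosage == 0:
                alleles = np.zeros(d, dtype=bool)
            elif dosage == 2:
                alleles = np.ones(d, dtype=bool)
            else:
                alleles = rng.random(d) < 0.5
            base_seq = tag_seqs[j]
            for r in range(d):
                seq = np.array(list(base_seq))
                seq[pos] = alt if alleles[r] else ref
                if config.terminal_pad > 0:
                    pad = rng.choice(_BASES, size=config.terminal_pad)
                    seq = np.concatenate([seq, pad])
                qual = np.full(len(seq), qual_hi)
                err = rng.random(len(seq)) < config.read_error_rate
                if err.any():
                    for ci in np.flatnonzero(err):
                        others = [b for b in "ACGT" if b != seq[ci]]
                        seq[ci] = others[int(rng.integers(0, 3))]
                        qual[ci] = qual_err
                nmask = rng.random(len(seq)) < config.n_rate
                if nmask.any():
                    seq[nmask] = "N"
                    qual[nmask] = qual_n
                name = f"{sample}|{j}|{r}"
                reads_by_sample[sample].append((name, "".join(seq), "".join(qual)))
    return reads_by_sample, placement


def write_fastq(reads: list[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_fasta(reference: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for contig, seq in reference.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
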