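"""End-to-end pipeline orchestration and report generation.

Runs digest -> QC -> genotyping -> SNP filtering -> diversity ->
differentiation -> structure from a single serialisable config, writing
every intermediate artifact (FASTA, FASTQ, VCF, TSV, Newick) plus a
summary text of ranges and means, so that every reported number is
recomputable from the emitted files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as div
from . import filters, qc, sim, structure
from .differentiation import PairwiseMatrix, bootstrap_support, p_distance, pairwise_differentiation
from .digest import RecognitionMotif, digest
from .genotyper import assign_reads, genotype_cohort, read_vcf, write_vcf
from .matrix import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the pipeline needs, YAML round-trippable bit-exactly."""

    out_dir: str = "radpop_out"
    seed: int = 0
    simulate: bool = True
    vcf_path: str | None = None          # skip upstream stages if given
    sim: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    qc: qc.QCConfig = field(default_factory=qc.QCConfig)
    error_rate: float = 0.01
    min_depth: int = 5
    call_rate_threshold: float = 0.80
    maf_threshold: float = 0.01
    max_snps_per_tag: int = 2
    k_values: list[int] = field(default_factory=lambda: list(range(1, 6)))
    cv_replicates: int = 10
    bootstrap_replicates: int = 1000
    pca_components: int = 10

    def __post_init__(self) -> None:
        # keep sub-config seeds slaved to the pipeline seed
        self.sim.seed = self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "sim" in d and isinstance(d["sim"], dict):
            s = dict(d["sim"])
            if "motif" in s and isinstance(s["motif"], dict):
                s["motif"] = RecognitionMotif(**s["motif"])
            if "ancestral_freq_beta" in s:
                s["ancestral_freq_beta"] = tuple(s["ancestral_freq_beta"])
            d["sim"] = sim.SimulationConfig(**s)
        if "qc" in d and isinstance(d["qc"], dict):
            q = dict(d["qc"])
            if "require_motif" in q and isinstance(q["require_motif"], dict):
                q["require_motif"] = RecognitionMotif(**q["require_motif"])
            d["qc"] = qc.QCConfig(**q)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def summarize_ranges(diversity_table: pd.DataFrame,
                     pairwise: PairwiseMatrix | None = None,
                     decimals: int = 3) -> str:
    """Min / max / mean of every diversity indicator at 3 decimals, and
    the extremes of pairwise F_ST and DR, as report text."""
    table = diversity_table.drop(index="Mean", errors="ignore")
    lines = []
    for col in table.columns:
        if col == "drift_F":
            continue
        v = table[col].astype(float)
        lines.append(
            f"{col} ranged from {v.min():.{decimals}f} to "
            f"{v.max():.{decimals}f}, with an average of "
            f"{v.mean():.{decimals}f}.")
    if pairwise is not None and len(pairwise.populations) > 1:
        iu = np.triu_indices(len(pairwise.populations), k=1)
        fst_vals = pairwise.fst[iu]
        dr_vals = pairwise.dr[iu]
        lines.append(f"Pairwise F_ST ranged from {fst_vals.min():.{decimals}f} "
                     f"to {fst_vals.max():.{decimals}f}.")
        lines.append(f"Pairwise DR ranged from {dr_vals.min():.{decimals}f} "
                     f"to {dr_vals.max():.{decimals}f}.")
    return "\n".join(lines)


def range_stats(diversity_table: pd.DataFrame, decimals: int = 3) -> pd.DataFrame:
    """min/max/mean per indicator (rounded half-even), as a frame."""
    table = diversity_table.drop(index="Mean", errors="ignore").astype(float)
    out = pd.DataFrame({"min": table.min(), "max": table.max(),
                        "mean": table.mean()})
    return out.round(decimals)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write all artifacts under ``out_dir``.

    Returns a dict of in-memory results (matrix, tables, tree, models).
    Stages upstream of the genotype matrix are skipped when
    ``vcf_path`` is provided.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    results: dict = {}

    if config.vcf_path:
        matrix = read_vcf(config.vcf_path)
        logger.info("loaded %d sites x %d individuals from %s",
                    matrix.n_sites, matrix.n_individuals, config.vcf_path)
    elif config.simulate:
        sc = config.sim
        reference, planted = sim.simulate_reference(sc)
        sim.write_fasta(reference, out / "reference.fa")
        truth = sim.simulate_genotypes(sc)
        truth.planted_site_coords = planted
        reads_by_sample, placement = sim.simulate_reads(truth, reference, sc)
        placement.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
        results["truth"] = truth
        panel = digest(reference, sc.motif)
        panel.write_fasta(out / "tags.fa")
        panel.write_bed(out / "tags.bed")
        clean_reads: dict[str, list[qc.Read]] = {}
        total_report = qc.QCReport()
        for sample, reads in reads_by_sample.items():
            retained, rep = qc.process_reads(reads, None, config.qc)
            clean_reads[sample] = retained
            for f in dataclasses.fields(qc.QCReport):
                setattr(total_report, f.name,
                        getattr(total_report, f.name) + getattr(rep, f.name))
        total_report.to_tsv(out / "qc_report.tsv")
        results["qc_report"] = total_report
        counts = assign_reads(clean_reads, panel)
        populations = [s.split("_")[0] for s in counts.samples]
        matrix, n_ref, n_alt = genotype_cohort(
            counts, populations, config.error_rate, config.min_depth)
        write_vcf(matrix, out / "genotypes.vcf", n_ref, n_alt)
    else:
        raise ValueError("config must set simulate=True or provide vcf_path")

    filtered, filter_table = filters.apply_all(
        matrix, config.call_rate_threshold, config.maf_threshold,
        config.max_snps_per_tag)
    filter_table.to_csv(out / "filter_counts.tsv", sep="\t", index=False)
    write_vcf(filtered, out / "filtered.vcf")
    results["matrix"] = filtered
    results["filter_table"] = filter_table

    strings = filters.concat_genotype_strings(filtered)
    with open(out / "genotype_strings.txt", "w") as fh:
        for name, s in strings.items():
            fh.write(f">{name}\n{s}\n")

    diversity_table = div.summarize(filtered)
    diversity_table.to_csv(out / "diversity.tsv", sep="\t")
    results["diversity"] = diversity_table

    pops = filtered.population_names
    pairwise = None
    if len(pops) > 1:
        pairwise = pairwise_differentiation(filtered)
        pairwise.to_tsv(out / "pairwise.tsv")
        results["pairwise"] = pairwise

    if filtered.n_individuals >= 4:
        try:
            tree = bootstrap_support(strings, config.bootstrap_replicates,
                                     seed=config.seed)
            (out / "nj_tree.nwk").write_text(tree.newick(with_support=True) + "\n")
            results["tree"] = tree
        except ValueError as exc:
            logger.warning("NJ tree skipped: %s", exc)

    cv = structure.scan_k(filtered, config.k_values,
                          n_replicates=config.cv_replicates, seed=config.seed)
    cv.to_frame().to_csv(out / "cv_errors.tsv", sep="\t", index=False)
    results["cv"] = cv
    best = structure.fit_admixture(filtered, cv.best_k, seed=config.seed)
    pd.DataFrame(best.Q_, index=filtered.samples).to_csv(
        out / f"admixture_Q_K{cv.best_k}.tsv", sep="\t", header=False)
    results["admixture"] = best

    pca_res = structure.pca(filtered, config.pca_components)
    frame = pca_res.to_frame()
    frame.to_csv(out / "pca_scores.tsv", sep="\t")
    with open(out / "pca_variance.tsv", "w") as fh:
        fh.write("component\tvariance_fraction\n")
        for i, v in enumerate(pca_res.explained_variance_ratio):
            fh.write(f"PC{i + 1}\t{v:.6f}\n")
    results["pca"] = pca_res

    summary = summarize_ranges(diversity_table, pairwise)
    summary += f"\nRetained SNPs: {filtered.n_sites}\n"
    summary += f"Optimal K by cross-validation: {cv.best_k}\n"
    (out / "summary.txt").write_text(summary)
    results["summary"] = summary
    return results
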