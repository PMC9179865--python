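# radpop

A 2b-RAD population-genomics pipeline for small, low-diversity cohorts —
the kind of study design used to assess the germplasm status of locally
farmed fish populations (a handful of geographic populations, ~15
diploid individuals each, tens of thousands of tag-SNPs).

2b-RAD reduced-representation sequencing uses a type-IIB restriction
enzyme (here BsaXI, recognition site `AC-N5-CTCC`) that cuts on both
sides of its recognition site, releasing uniform-length genomic tags.
`radpop` implements every step from reference to report:

1. **In-silico digestion** — scan a reference genome for the BsaXI
   site on both strands and extract 33-bp tags (12 bp upstream flank +
   11 bp site + 10 bp downstream, configurable) as the SNP-discovery
   reference.
2. **Read QC** — merge overlapping read pairs, trim adaptors and the
   final 3 bases, then remove reads with >8% N, ≥15% of positions below
   Q30, or no restriction site.
3. **ML genotyping** — assign tag-length reads by Hamming distance
   (≤2 mismatches, unique best hit only) and call diploid genotypes by
   a three-hypothesis binomial likelihood: hom-ref `Bin(n_alt | n, e)`,
   het `Bin(n_alt | n, ½)`, hom-alt `Bin(n_alt | n, 1−e)`.
4. **SNP filtering** — call rate ≥ 80%, MAF ≥ 0.01, biallelic only,
   and ≤ 2 SNPs per tag (tag-atomic removal).
5. **Diversity** — per population: expected heterozygosity
   He = 1 − Σᵢ xᵢ², observed heterozygosity Ho, Botstein's
   PIC = 1 − ΣPᵢ² − Σᵢ<ⱼ 2Pᵢ²Pⱼ², effective allele number
   Ne = 1/ΣPᵢ², nucleotide diversity π = 2j(n−j)/(n(n−1)), the exact
   Hardy–Weinberg test p value, and the drift coefficient F = 1/(2Ne).
6. **Differentiation** — pairwise Weir–Cockerham θ (variance
   components, ratio of sums across loci) and the genetic distance
   DR = −ln(1 − F_ST); individual p-distances over concatenated
   IUPAC genotype strings; Saitou–Nei neighbor joining with
   site-bootstrap support.
7. **Structure** — admixture model (dosage g ~ Bin(2, QF)) fitted by
   EM with a masked-entry cross-validation scan for the optimal K, and
   genotype PCA with the standard 2p̂ / √(2p̂(1−p̂)) dosage scaling.
8. **Synthetic data** — a Balding–Nichols generator (ancestral
   frequency ~ Beta, per-population frequencies ~ Beta around it with
   spread set by a global F_ST, reads at Poisson depth with
   configurable error and N rates) that emulates the target study
   design with known ground truth for every stage.

## Worked example

Run a small synthetic cohort (3 populations × 8 individuals, 80 tags)
end to end:

```python
from radpop import PipelineConfig, SimulationConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="scratch/smoke", seed=3,
    sim=SimulationConfig(n_populations=3, n_individuals_per_pop=8,
                         n_sites=80, genome_length=40_000,
                         depth_mean=25, seed=3),
    cv_replicates=3, bootstrap_replicates=20, k_values=[1, 2, 3])
print(run_pipeline(cfg)["summary"])
```

which prints:

```
HW-P ranged from 0.817 to 0.870, with an average of 0.852.
He ranged from 0.281 to 0.321, with an average of 0.296.
Ho ranged from 0.316 to 0.353, with an average of 0.338.
PIC ranged from 0.227 to 0.255, with an average of 0.238.
Ne ranged from 1.468 to 1.558, with an average of 1.503.
Pi ranged from 0.300 to 0.343, with an average of 0.316.
Pairwise F_ST ranged from -0.002 to 0.061.
Pairwise DR ranged from 0.000 to 0.063.
Retained SNPs: 34
Optimal K by cross-validation: 1
```

Reading the output: of the 80 simulated tag-SNPs, 34 survive the four
retention filters (most of the rest are too rare under the skewed
ancestral-frequency prior). Diversity is moderate in this toy cohort
(He ≈ 0.30 per population); the three populations are weakly diverged
(all pairwise θ ≤ 0.061, i.e. below the conventional 0.05–0.15
"moderate" band for two of three pairs), and the cross-validation scan
accordingly prefers a single ancestral population (K = 1). All
intermediate artifacts (reference FASTA, tag panel, VCFs, TSV tables,
Newick tree) are written under `out_dir`, and every number in the
summary is recomputable from them.

The same stages are available from the shell:

```bash
radpop digest --ref ref.fa --flank-up 12 --flank-down 10
radpop qc --r1 reads_1.fq --r2 reads_2.fq --out clean.fq
radpop genotype --panel tags.fa --reads-dir clean/ --error-rate 0.01
radpop snpfilter --vcf genotypes.vcf --out filtered.vcf
radpop diversity --vcf filtered.vcf
radpop differentiate --vcf filtered.vcf --bootstrap 1000 --seed 42
radpop structure --vcf filtered.vcf --k-min 1 --k-max 10 --seed 42
radpop run --config config.yaml      # full pipeline from YAML
```

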