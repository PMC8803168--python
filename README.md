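# elsplice

Does the splicing of enhancer-associated long noncoding RNAs (elncRNAs)
*cause* changes in enhancer activity and target-gene expression, or is it a
mere by-product of transcription at highly active enhancers? `elsplice`
implements, end to end and on desk-scale synthetic cohorts, the inference
chain that addresses this question in population genomics data:

1. **Annotation** — classify transcripts by the distance of their 5' end to
   intergenic enhancers (elncRNA) or promoters (plncRNA / protein-coding),
   and locate variants that disrupt the GT/AG splice-site dinucleotides of
   multi-exonic elncRNAs.
2. **Splicing quantification** — intron-centric percent-spliced-in
   (PSI\_i = n\_i / Σ\_cluster n, over junction-read clusters sharing splice
   sites) and the completed splicing index
   coSI = j / (j + (b₅+b₃)/2), the ratio of exon–exon junction reads to
   junction plus exon–intron boundary reads.
3. **Motif and evolutionary analyses** — exonic-splicing-enhancer and U1
   hexamer densities in masked splice-site-flanking windows; pairwise
   substitution rates (Jukes–Cantor closed form, d = −¾ ln(1 − 4p̂/3), or a
   two-sequence maximum-likelihood GTR distance) tested against 1,000
   GC/length-matched subsamples of local ancestral repeats with the add-one
   empirical p = (1 + #{d_AR ≤ d_obs}) / (1 + N); derived-allele-frequency
   spectra compared by two-tailed Fisher tests on the DAF < 0.1 contrast.
4. **cis-QTL mapping** — `CisQtlModel.fit()` regresses rank-inverse-normal
   traits on allele dosage within TAD cis-windows (MAF > 5%), calibrates
   gene-level significance against the 95th percentile of 1,000 permutation
   r_max values and applies Benjamini–Hochberg FDR < 5% per TAD.
5. **Causal mediation classification** — for each joint triplet (variant E,
   elncRNA intron PSI A, outcome B), `MediationModel.fit()` assigns one of
   four topologies (independent / causal / reactive / undecided) from
   Fisher-z partial-correlation scores calibrated by a permutation
   empirical null and a local-FDR < 0.1 decision rule.
6. **Synthetic cohorts** — `synthetic_data` plants Hardy–Weinberg
   genotypes, sQTL effects on logit-PSI, mediation topologies, Jukes–Cantor
   sequence divergence and DAF spectra, so every stage above is testable
   against known truth without any external download.

The intended users are regulatory-genomics researchers who want a
transparent, fully seeded re-implementation of this analysis style to probe
its calibration and power, or to adapt it to their own QTL cohorts.

## Worked example

Classify 500 simulated triplets generated under the causal topology
(A = 0.7·E + ε, B = 0.7·A + ε, n = 300 samples):

```python
from elsplice import synthetic_data as sd, MediationModel

cfg = sd.CohortConfig(n_samples=300, seed=1)
scn = sd.MediationScenario(model="causal", beta_EA=0.7, beta_AB=0.7)
d = sd.simulate_mediation_triplets(500, scn, cfg)
print(MediationModel(d.E, d.A, d.B, seed=7).fit().summary())
```

```
Mediation classification
========================================
triplets:       500
lfdr threshold: 0.1
causal          453  (90.6%)
reactive          4  (0.8%)
independent      43  (8.6%)
undecided         0  (0.0%)
```

90.6% of truly causal triplets are recovered; the residual calls fall into
the independent model (the analysis style's known conservative failure
mode), and essentially none are mislabelled reactive.

The same analysis runs from the shell on a full synthetic cohort:

```bash
elsplice simulate --outdir cohort --n-samples 200 --n-loci 50 \
    --causal-fraction 0.6 --seed 1
elsplice classify --gtf cohort/transcripts.gtf --enhancers cohort/enhancers.bed \
    --promoters cohort/promoters.bed --out labels.tsv
elsplice psi --counts cohort/counts.tsv --out psi.tsv
elsplice qtl --phenotypes psi.tsv --kind splicing --genotypes cohort/genotypes.vcf \
    --tads cohort/tads.bed --seed 2 --out sqtl.tsv
elsplice qtl --phenotypes cohort/expression.tsv --kind expression \
    --genotypes cohort/genotypes.vcf --tads cohort/tads.bed \
    --positions cohort/trait_positions.tsv --seed 3 --out eqtl.tsv
elsplice triplets --sqtl sqtl.tsv --outcome-qtl eqtl.tsv \
    --trait-map cohort/intron_gene_map.tsv --classes labels.tsv --out triplets.tsv
elsplice causal --triplets triplets.tsv --genotypes cohort/genotypes.vcf \
    --psi psi.tsv --outcomes cohort/expression.tsv --seed 4 --out calls.tsv
elsplice report --calls calls.tsv --out report.json
```

The final step prints

```
{"model_counts": {"causal": 56, "reactive": 0, "independent": 38, "undecided": 0},
 "causal_elncrna_fraction": 0.5957446808510638}
```

— the pipeline calls 59.6% of elncRNAs causal mediators of their target's
expression, against a planted fraction of 60%.

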