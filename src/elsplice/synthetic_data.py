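"""Synthetic cohorts with the statistical structure the pipeline assumes.

Generators are pure functions of (config, seed) and write the same standard
formats the readers in :mod:`elsplice.io_formats` consume, so the whole
inference chain — genotypes -> junction counts -> PSI -> cis-QTLs ->
joint triplets -> mediation calls — is testable without any external data.

What is emulated: Hardy-Weinberg biallelic genotypes at configurable MAF;
junction counts whose log-proportions shift with a planted sQTL genotype;
expression/chromatin outcomes generated under each of the four mediation
topologies; neutrally evolving vs constrained sequence pairs under
Jukes-Cantor substitution; and derived-allele-frequency spectra with a
configurable excess of rare derived alleles. What is not: linkage maps,
population structure, imputation uncertainty or sequencing error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (GenomicInterval, GenotypeMatrix, IntronClusterTable,
                         PairwiseAlignment, PhenotypeMatrix, TranscriptModel,
                         write_bed, write_genotypes_vcf, write_gtf,
                         write_intron_clusters, write_phenotypes)
from .evolution import FeatureSegment

__all__ = [
    "CohortConfig",
    "MediationScenario",
    "EvolutionScenario",
    "simulate_genotypes",
    "add_ld_copy",
    "simulate_mediation_triplets",
    "simulate_junction_counts",
    "simulate_sequence_pairs",
    "simulate_daf_table",
    "simulate_cohort",
]


@dataclass(frozen=True)
class CohortConfig:
    """Cohort dimensions; the default sample size mirrors a typical European
    lymphoblastoid-cell-line QTL panel (373 individuals)."""

    n_samples: int = 373
    n_variants: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    read_depth: float = 50.0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.read_depth < 0:
            raise ValueError("read_depth must be non-negative")


@dataclass(frozen=True)
class MediationScenario:
    """Generative parameters for one mediation topology.

    Effects are in units of trait SD per allele (beta_EA, beta_EB) or per
    mediator SD (beta_AB); noise_sd scales the independent Gaussian errors.
    """

    model: str
    beta_EA: float = 0.7
    beta_AB: float = 0.7
    beta_EB: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.model not in ("causal", "reactive", "independent", "undecided"):
            raise ValueError(f"unknown mediation model {self.model!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.model == "causal" and self.beta_EB != 0:
            raise ValueError("causal model requires beta_EB = 0")
        if self.model == "independent" and self.beta_AB != 0:
            raise ValueError("independent model requires beta_AB = 0")
        if self.model == "undecided" and (self.beta_EB == 0 or self.beta_AB == 0):
            raise ValueError("undecided model requires beta_EB != 0 and beta_AB != 0")


@dataclass(frozen=True)
class EvolutionScenario:
    """Parameters of the paired-lineage substitution simulation.

    ``neutral_rate`` is the total pairwise divergence (substitutions/site)
    of neutrally evolving sequence; constrained motifs evolve at
    ``neutral_rate * constraint_ratio``. ``n_ar_segments`` ancestral-repeat
    segments (each ``ar_length`` nt) are placed within 1 Mb of every motif.
    """

    neutral_rate: float = 0.5
    constraint_ratio: float = 1.0
    motif_length: int = 60
    n_motifs: int = 20
    n_ar_segments: int = 10
    ar_length: int = 600
    seed: int = 0

    def __post_init__(self):
        if self.neutral_rate < 0:
            raise ValueError("neutral_rate must be >= 0")
        if not (0 <= self.constraint_ratio <= 1):
            raise ValueError("constraint_ratio must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Genotypes


def simulate_genotypes(cfg: CohortConfig, chrom: str = "chr1",
                       positions: np.ndarray | None = None,
                       prefix: str = "v") -> GenotypeMatrix:
    """Hardy-Weinberg biallelic genotypes, Binomial(2, f) per sample.

    Allele frequencies are uniform in ``cfg.maf_range``; dosage coding is
    {0, 1, 2}. Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    f = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_variants)
    dosages = rng.binomial(2, f, size=(cfg.n_samples, cfg.n_variants)).astype(float)
    if positions is None:
        positions = np.arange(cfg.n_variants) * 1000 + 100
    variants = pd.DataFrame({
        "variant_id": [f"{prefix}{i:05d}" for i in range(cfg.n_variants)],
        "chrom": chrom, "pos": np.asarray(positions, dtype=int),
        "ref": "A", "alt": "G"}).set_index("variant_id")
    samples = [f"s{i:04d}" for i in range(cfg.n_samples)]
    return GenotypeMatrix(samples, variants, dosages)


def add_ld_copy(gm: GenotypeMatrix, source_id: str, new_id: str,
                flip_prob: float, pos: int, seed: int = 0) -> GenotypeMatrix:
    """Append a variant in block LD with ``source_id``.

    Each sample's dosage is copied from the source and replaced by an
    independent Hardy-Weinberg draw with probability ``flip_prob`` —
    a minimal LD model supporting best-variant sensitivity analyses.
    """
    rng = np.random.default_rng(seed)
    j = gm.variants.index.get_loc(source_id)
    src = gm.dosages[:, j].copy()
    f = np.nanmean(src) / 2.0
    flip = rng.random(gm.n_samples) < flip_prob
    src[flip] = rng.binomial(2, f, size=int(flip.sum()))
    variants = pd.concat([gm.variants, pd.DataFrame(
        {"chrom": [gm.variants.iloc[j]["chrom"]], "pos": [pos],
         "ref": ["A"], "alt": ["G"]}, index=[new_id])])
    variants.index.name = gm.variants.index.name
    return GenotypeMatrix(gm.samples, variants,
                          np.column_stack([gm.dosages, src]))


# ---------------------------------------------------------------------------
# Mediation triplets


@dataclass
class TripletData:
    """Simulated (E, A, B) draws: arrays of shape (n_triplets, n_samples)."""

    E: np.ndarray
    A: np.ndarray
    B: np.ndarray
    scenario: MediationScenario

    def to_frame(self) -> pd.DataFrame:
        m, n = self.E.shape
        idx = pd.MultiIndex.from_product([range(m), range(n)],
                                         names=["triplet", "sample"])
        return pd.DataFrame({"E": self.E.ravel(), "A": self.A.ravel(),
                             "B": self.B.ravel()}, index=idx)


def simulate_mediation_triplets(n_triplets: int, scenario: MediationScenario,
                                cfg: CohortConfig) -> TripletData:
    """Draw (E, A, B) per sample under the scenario's topology.

    causal:      A = bEA*E + e1,  B = bAB*A + e2
    reactive:    B = bEB*E + e1,  A = bAB*B + e2
    independent: A = bEA*E + e1,  B = bEB*E + e2   (cov(e1, e2) = 0)
    undecided:   A = bEA*E + e1,  B = bAB*A + bEB*E + e2
    """
    rng = np.random.default_rng(cfg.seed)
    f = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=(n_triplets, 1))
    E = rng.binomial(2, f, size=(n_triplets, cfg.n_samples)).astype(float)
    e1 = rng.normal(0, scenario.noise_sd, size=E.shape)
    e2 = rng.normal(0, scenario.noise_sd, size=E.shape)
    s = scenario
    if s.model == "causal":
        A = s.beta_EA * E + e1
        B = s.beta_AB * A + e2
    elif s.model == "reactive":
        B = s.beta_EB * E + e1
        A = s.beta_AB * B + e2
    elif s.model == "independent":
        A = s.beta_EA * E + e1
        B = s.beta_EB * E + e2
    else:  # undecided
        A = s.beta_EA * E + e1
        B = s.beta_AB * A + s.beta_EB * E + e2
    return TripletData(E=E, A=A, B=B, scenario=s)


# ---------------------------------------------------------------------------
# Junction counts


def simulate_junction_counts(psi_base, sqtl_effect, genotypes, depth: float,
                             seed: int = 0, intron_keys: list[str] | None = None,
                             samples: list[str] | None = None,
                             latent_sd: float = 0.0) -> IntronClusterTable:
    """Planted-sQTL junction counts for one intron cluster.

    Per sample, the cluster total is Poisson(``depth``) and the intron split
    is Multinomial with proportions softmax(log(psi_base) + effect*dosage
    [+ latent noise on the first intron]). For two-intron clusters the
    additive shift is exactly a logit-PSI shift of the first intron;
    ``sqtl_effect`` may be a scalar (applied to the first intron) or one
    value per intron. ``depth=0`` yields all-zero counts (PSI missing
    downstream).
    """
    psi_base = np.asarray(psi_base, dtype=float)
    if psi_base.ndim != 1 or np.any(psi_base < 0) or abs(psi_base.sum() - 1.0) > 1e-9:
        raise ValueError("psi_base must be a probability simplex over introns")
    k = psi_base.size
    effect = np.zeros(k)
    eff_in = np.atleast_1d(np.asarray(sqtl_effect, dtype=float))
    if eff_in.size == 1:
        effect[0] = eff_in[0]
    elif eff_in.size == k:
        effect = eff_in
    else:
        raise ValueError("sqtl_effect must be scalar or one value per intron")
    dosage = np.asarray(genotypes, dtype=float).ravel()
    n = dosage.size
    rng = np.random.default_rng(seed)
    logp = np.log(np.clip(psi_base, 1e-12, None))[None, :] + np.outer(dosage, effect)
    if latent_sd > 0:
        logp[:, 0] += rng.normal(0, latent_sd, size=n)
    logp -= logp.max(axis=1, keepdims=True)
    probs = np.exp(logp)
    probs /= probs.sum(axis=1, keepdims=True)
    totals = rng.poisson(depth, size=n) if depth > 0 else np.zeros(n, dtype=int)
    counts = np.vstack([rng.multinomial(t, p) for t, p in zip(totals, probs)]).T
    if intron_keys is None:
        intron_keys = [f"chr1:1000:{2000 + 500 * i}:clu_1" for i in range(k)]
    if samples is None:
        samples = [f"s{i:04d}" for i in range(n)]
    df = pd.DataFrame(counts, index=pd.Index(intron_keys, name="intron"),
                      columns=samples)
    return IntronClusterTable(counts=df)


# ---------------------------------------------------------------------------
# Sequence pairs under Jukes-Cantor


def _random_seq(rng, length: int, gc: float = 0.5) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)


def _jc_mutate(rng, seq: np.ndarray, branch_length: float) -> np.ndarray:
    """One lineage of Jukes-Cantor evolution: per-site substitution with
    probability 3/4 (1 - exp(-4t/3)), uniform over the three other bases."""
    p_sub = 0.75 * (1.0 - np.exp(-4.0 * branch_length / 3.0))
    out = seq.copy()
    hit = rng.random(seq.size) < p_sub
    idx = np.flatnonzero(hit)
    if idx.size:
        bases = np.frombuffer(b"ACGT", dtype="S1")
        cur = np.searchsorted(bases, out[idx])
        shift = rng.integers(1, 4, size=idx.size)
        out[idx] = bases[(cur + shift) % 4]
    return out


def simulate_sequence_pairs(scn: EvolutionScenario) -> tuple[list[FeatureSegment],
                                                             list[FeatureSegment]]:
    """Aligned motif pairs and a local AR catalog under Jukes-Cantor.

    Each motif's ancestor evolves independently down two lineages at total
    divergence ``neutral_rate * constraint_ratio``; each AR segment at
    ``neutral_rate``. ``n_ar_segments`` ARs of ``ar_length`` nt are placed
    within 1 Mb of every motif, so downstream GC/length matching always has
    local candidates.
    """
    rng = np.random.default_rng(scn.seed)
    motifs, ars = [], []
    d_motif = scn.neutral_rate * scn.constraint_ratio
    for i in range(scn.n_motifs):
        offset = i * 2_000_000 + 1_000_000
        anc = _random_seq(rng, scn.motif_length)
        s1 = _jc_mutate(rng, anc, d_motif / 2.0)
        s2 = _jc_mutate(rng, anc, d_motif / 2.0)
        iv = GenomicInterval("chr1", offset, offset + scn.motif_length, "+",
                             f"motif_{i}")
        motifs.append(FeatureSegment(iv, PairwiseAlignment(
            f"motif_{i}", s1.tobytes().decode(), s2.tobytes().decode())))
        for j in range(scn.n_ar_segments):
            astart = offset + (j + 1) * 50_000
            anc_ar = _random_seq(rng, scn.ar_length)
            a1 = _jc_mutate(rng, anc_ar, scn.neutral_rate / 2.0)
            a2 = _jc_mutate(rng, anc_ar, scn.neutral_rate / 2.0)
            aiv = GenomicInterval("chr1", astart, astart + scn.ar_length, "+",
                                  f"ar_{i}_{j}")
            ars.append(FeatureSegment(aiv, PairwiseAlignment(
                f"ar_{i}_{j}", a1.tobytes().decode(), a2.tobytes().decode())))
    return motifs, ars


# ---------------------------------------------------------------------------
# Derived allele frequency tables


def simulate_daf_table(n_snps: dict[str, int], constrained_shift: float,
                       seed: int = 0,
                       constrained_classes: tuple[str, ...] = (
                           "elncRNA-motif", "plncRNA-motif", "pcg-motif"),
                       n_bins: int = 100) -> pd.DataFrame:
    """DAF tables per sequence class.

    The neutral spectrum is the standard 1/x site-frequency spectrum
    discretised on ``n_bins`` bins of (0, 1); constrained classes mix in an
    extra ``constrained_shift`` fraction of mass uniform over DAF < 0.1.
    Output columns (snp_id, snp_class, ref, alt, ancestral, alt_freq, daf)
    round-trip through :func:`elsplice.evolution.daf_spectrum`.
    """
    if constrained_shift < 0 or constrained_shift >= 1:
        raise ValueError("constrained_shift must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    centers = (np.arange(n_bins) + 0.5) / n_bins
    width = 1.0 / n_bins
    neutral = 1.0 / centers
    neutral /= neutral.sum()
    low = centers < 0.1
    uniform_low = low / low.sum()
    rows = []
    for cls, n in n_snps.items():
        w = neutral.copy()
        if cls in constrained_classes and constrained_shift > 0:
            w = (1 - constrained_shift) * neutral + constrained_shift * uniform_low
        bins = rng.choice(n_bins, size=n, p=w)
        daf = centers[bins] + rng.uniform(-width / 2 * 0.99, width / 2 * 0.99, size=n)
        anc_is_ref = rng.random(n) < 0.5
        rows.append(pd.DataFrame({
            "snp_id": [f"{cls}_snp{i}" for i in range(n)],
            "snp_class": cls,
            "ref": "A", "alt": "G",
            "ancestral": np.where(anc_is_ref, "A", "G"),
            "alt_freq": np.where(anc_is_ref, daf, 1.0 - daf),
            "daf": daf,
        }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Full synthetic cohort


@dataclass
class CohortTruth:
    """Planted ground truth of a simulated cohort."""

    causal_fraction: float
    locus_models: dict[str, str]
    sqtl_variant: dict[str, str]
    params: dict = field(default_factory=dict)


def simulate_cohort(outdir, n_samples: int = 373, n_loci: int = 50,
                    causal_fraction: float = 0.6, seed: int = 0,
                    depth: float = 100.0, sqtl_effect: float = 1.0,
                    beta_mediation: float = 1.0, noise_sd: float = 1.0,
                    latent_sd: float = 0.5,
                    with_chromatin: bool = False) -> CohortTruth:
    """Write a complete synthetic cohort for the end-to-end pipeline.

    Each of ``n_loci`` elncRNA loci occupies its own 1-Mb TAD on chr1 with
    an intergenic enhancer, a two-intron alternative-acceptor elncRNA
    starting within 500 bp of it, a protein-coding target gene, a planted
    sQTL variant (effect ``sqtl_effect`` on the logit PSI of the first
    intron) and two null variants. A ``causal_fraction`` of loci generate
    target expression through the splicing mediator (causal topology); the
    rest couple target expression to the variant directly (independent
    topology). elncRNA expression itself is genotype-independent so the
    joint-QTL exclusion rules keep the planted triplets.

    Writes transcripts.gtf, enhancers.bed, promoters.bed, tads.bed,
    genotypes.vcf, counts.tsv, expression.tsv, trait_positions.tsv,
    intron_gene_map.tsv, truth.json (+ chromatin.tsv when requested).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    samples = [f"s{i:04d}" for i in range(n_samples)]
    n_causal = int(round(causal_fraction * n_loci))
    models = ["causal"] * n_causal + ["independent"] * (n_loci - n_causal)

    transcripts, enhancers, promoters, tads = [], [], [], []
    var_rows, dos_cols = [], []
    count_frames = []
    expr_rows, expr_idx = [], []
    chrom_rows, chrom_idx = [], []
    pos_rows, map_rows = [], []
    truth_models, truth_variants = {}, {}

    for i in range(n_loci):
        off = i * 2_000_000
        lid, gid = f"ELNC{i:03d}", f"PCG{i:03d}"
        tads.append(GenomicInterval("chr1", off, off + 1_000_000, ".", f"tad_{i}"))
        enhancers.append(GenomicInterval("chr1", off + 10_000, off + 10_500, ".",
                                         f"enh_{i}"))
        transcripts.append(TranscriptModel(
            lid, "chr1", "+",
            [(off + 10_700, off + 10_900), (off + 11_100, off + 11_600)],
            biotype="lncRNA"))
        transcripts.append(TranscriptModel(
            gid, "chr1", "+", [(off + 200_000, off + 201_000)],
            biotype="protein_coding"))
        promoters.append(GenomicInterval("chr1", off + 199_500, off + 200_500, ".",
                                         f"prom_{i}"))

        f_main = rng.uniform(0.2, 0.4)
        dosage = rng.binomial(2, f_main, size=n_samples).astype(float)
        main_id = f"rs{i:03d}_0"
        var_rows.append((main_id, "chr1", off + 500_000, "A", "G"))
        dos_cols.append(dosage)
        for j in (1, 2):
            var_rows.append((f"rs{i:03d}_{j}", "chr1", off + 500_000 + 100_000 * j,
                             "A", "G"))
            dos_cols.append(rng.binomial(2, rng.uniform(0.2, 0.4),
                                         size=n_samples).astype(float))

        # junction counts: alternative acceptors sharing one donor
        keyA = f"chr1:{off + 10_900}:{off + 11_100}:clu_{i}"
        keyB = f"chr1:{off + 10_900}:{off + 11_400}:clu_{i}"
        latent = rng.normal(0, latent_sd, size=n_samples)
        logitp = np.log(0.7 / 0.3) - sqtl_effect * dosage + latent
        pA = 1.0 / (1.0 + np.exp(-logitp))
        totals = rng.poisson(depth, size=n_samples)
        cA = rng.binomial(totals, pA)
        count_frames.append(pd.DataFrame([cA, totals - cA],
                                         index=[keyA, keyB], columns=samples))
        map_rows.append((keyA, lid))
        map_rows.append((keyB, lid))

        # outcome expression (log-normal RPKM, monotone in the latent trait)
        mediator = -logitp          # higher when splicing of intron A is disrupted
        m_z = (mediator - mediator.mean()) / mediator.std()
        model = models[i]
        if model == "causal":
            raw = beta_mediation * m_z + noise_sd * rng.normal(size=n_samples)
        else:
            e_z = (dosage - dosage.mean()) / max(dosage.std(), 1e-9)
            raw = beta_mediation * e_z + noise_sd * rng.normal(size=n_samples)
        expr_rows.append(np.exp(0.5 * raw + 2.0))
        expr_idx.append(gid)
        # elncRNA expression: genotype-independent
        expr_rows.append(np.exp(rng.normal(1.0, 0.5, size=n_samples)))
        expr_idx.append(lid)
        pos_rows.append((gid, "chr1", off + 200_000))
        pos_rows.append((lid, "chr1", off + 10_700))
        if with_chromatin:
            raw_c = (beta_mediation * m_z + noise_sd * rng.normal(size=n_samples)
                     if model == "causal" else noise_sd * rng.normal(size=n_samples))
            chrom_rows.append(np.exp(0.5 * raw_c + 3.0))
            chrom_idx.append(f"enh_{i}_H3K4me1")
            pos_rows.append((f"enh_{i}_H3K4me1", "chr1", off + 10_250))
        truth_models[lid] = model
        truth_variants[lid] = main_id

    variants = pd.DataFrame(var_rows, columns=["variant_id", "chrom", "pos",
                                               "ref", "alt"]).set_index("variant_id")
    gm = GenotypeMatrix(samples, variants, np.column_stack(dos_cols))
    write_genotypes_vcf(gm, outdir / "genotypes.vcf")
    write_gtf(transcripts, outdir / "transcripts.gtf")
    write_bed(enhancers, outdir / "enhancers.bed")
    write_bed(promoters, outdir / "promoters.bed")
    write_bed(tads, outdir / "tads.bed")
    counts = pd.concat(count_frames)
    counts.index.name = "intron"
    write_intron_clusters(IntronClusterTable(counts=counts), outdir / "counts.tsv")
    expr = PhenotypeMatrix(pd.DataFrame(np.vstack(expr_rows), index=expr_idx,
                                        columns=samples), kind="expression")
    write_phenotypes(expr, outdir / "expression.tsv")
    if with_chromatin:
        chrom = PhenotypeMatrix(pd.DataFrame(np.vstack(chrom_rows), index=chrom_idx,
                                             columns=samples), kind="chromatin")
        write_phenotypes(chrom, outdir / "chromatin.tsv")
    pd.DataFrame(pos_rows, columns=["trait", "chrom", "pos"]).to_csv(
        outdir / "trait_positions.tsv", sep="\t", index=False)
    pd.DataFrame(map_rows, columns=["trait", "gene"]).to_csv(
        outdir / "intron_gene_map.tsv", sep="\t", index=False)
    truth = CohortTruth(causal_fraction=n_causal / n_loci,
                        locus_models=truth_models, sqtl_variant=truth_variants,
                        params={"n_samples": n_samples, "n_loci": n_loci,
                                "seed": seed, "depth": depth,
                                "sqtl_effect": sqtl_effect,
                                "beta_mediation": beta_mediation,
                                "noise_sd": noise_sd, "latent_sd": latent_sd})
    with open(outdir / "truth.json", "w") as fh:
        json.dump({"causal_fraction": truth.causal_fraction,
                   "locus_models": truth.locus_models,
                   "sqtl_variant": truth.sqtl_variant,
                   "params": truth.params}, fh, indent=2)
    return truth
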