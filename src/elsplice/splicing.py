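"""Splicing quantification and splice-site-variant contrast analyses.

Intron-centric percent-spliced-in (PSI) is the fraction of a cluster's
junction reads supporting a given intron's excision; the completed splicing
index (coSI) is the ratio of exon-exon junction reads to junction plus
exon-intron boundary reads (1 = fully spliced). Group contrasts between
carriers of alternative vs reference alleles use the sign-preserving
log10-modulus transform of relative differences against the
reference-genotype median, tested with two-tailed Mann-Whitney U.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomicInterval, IntronClusterTable, TranscriptModel

log = logging.getLogger(__name__)

__all__ = [
    "cluster_introns",
    "compute_psi",
    "compute_cosi",
    "log_modulus_fold_difference",
    "ss_variant_contrast",
    "junction_end_position",
]

DEFAULT_MIN_CLUSTER_READS = 10


def cluster_introns(introns: pd.DataFrame) -> pd.Series:
    """Group introns into clusters sharing a donor or acceptor coordinate.

    ``introns`` needs columns chrom, start, end. Clusters are the connected
    components of the "shares a splice-site coordinate on the same
    chromosome" relation; singletons form their own cluster. Returns a
    Series mapping intron index -> cluster id ("clu_1", "clu_2", ... in
    first-appearance order).
    """
    parent = list(range(len(introns)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    site_map: dict[tuple, int] = {}
    for i, (_, row) in enumerate(introns.iterrows()):
        for site in ((row["chrom"], row["start"]), (row["chrom"], row["end"])):
            if site in site_map:
                union(i, site_map[site])
            else:
                site_map[site] = i

    roots = [find(i) for i in range(len(introns))]
    ids: dict[int, str] = {}
    labels = []
    for r in roots:
        if r not in ids:
            ids[r] = f"clu_{len(ids) + 1}"
        labels.append(ids[r])
    return pd.Series(labels, index=introns.index, name="cluster")


def compute_psi(
    table: IntronClusterTable,
    min_cluster_reads: int = DEFAULT_MIN_CLUSTER_READS,
) -> pd.DataFrame:
    """Per-intron PSI: count / cluster total, per sample.

    A (cluster, sample) cell with fewer than ``min_cluster_reads`` total
    reads yields missing (NaN) PSI for all its introns. Within a defined
    cluster/sample, PSI sums to 1.
    """
    counts = table.counts.to_numpy(dtype=float)
    if (counts < 0).any():
        raise ValueError("negative junction count")
    psi = np.full_like(counts, np.nan)
    cluster_of = table.introns["cluster"].to_numpy()
    for clu in pd.unique(cluster_of):
        rows = np.flatnonzero(cluster_of == clu)
        tot = counts[rows].sum(axis=0)
        ok = tot >= max(min_cluster_reads, 1)
        psi[np.ix_(rows, np.flatnonzero(ok))] = counts[np.ix_(rows, np.flatnonzero(ok))] / tot[ok]
    return pd.DataFrame(psi, index=table.counts.index, columns=table.counts.columns)


@dataclass
class CosiRecord:
    gene_id: str
    cosi: float
    junction_reads: float
    boundary_reads: float


def compute_cosi(table: pd.DataFrame) -> pd.DataFrame:
    """Completed splicing index per intron and read-weighted mean per gene.

    ``table`` needs columns gene_id, j (exon-exon junction reads), b5 and b3
    (5' and 3' exon-intron boundary reads). Per intron,
    coSI = j / (j + (b5 + b3)/2); the two boundary counts are averaged so a
    single partially spliced molecule is not counted twice. The gene-level
    coSI is the mean over introns weighted by each intron's total supporting
    reads; genes whose introns have no supporting reads are missing.
    """
    t = table.copy()
    if (t[["j", "b5", "b3"]].to_numpy() < 0).any():
        raise ValueError("negative read count")
    boundary = (t["b5"] + t["b3"]) / 2.0
    denom = t["j"] + boundary
    t["cosi"] = np.where(denom > 0, t["j"] / denom.replace(0, np.nan), np.nan)
    t["weight"] = denom

    def agg(g):
        w = g["weight"].sum()
        cosi = np.nan if w == 0 else float(np.average(g["cosi"].dropna(),
                                                      weights=g.loc[g["cosi"].notna(), "weight"]))
        return pd.Series({"cosi": cosi, "junction_reads": g["j"].sum(),
                          "boundary_reads": (g["b5"] + g["b3"]).sum()})

    return t.groupby("gene_id").apply(agg, include_groups=False)


def log_modulus_fold_difference(values: np.ndarray, reference: np.ndarray,
                                ratio: bool = False) -> np.ndarray:
    """Sign-preserving log10-modulus statistic vs the reference-group median.

    fd_s = (v_s - median_ref) / median_ref, then sign(fd)*log10(1 + |fd|).
    With ``ratio=True`` the fold difference is v_s / median_ref instead of
    the relative difference (an alternative reading of "fold difference";
    the two differ only by an offset of 1 before the transform).

    Returns NaN for every value when the reference median is zero.
    """
    reference = np.asarray(reference, dtype=float)
    reference = reference[np.isfinite(reference)]
    if reference.size == 0:
        raise ValueError("reference group is empty")
    med = np.median(reference)
    values = np.asarray(values, dtype=float)
    if med == 0:
        log.warning("reference median is zero; statistic undefined")
        return np.full(values.shape, np.nan)
    fd = values / med if ratio else (values - med) / med
    return np.sign(fd) * np.log10(1.0 + np.abs(fd))


def _panel_stats(trait_values: pd.DataFrame, ref_samples, alt_samples):
    """Per-sample mean log-modulus fold difference across a panel's traits."""
    stats_rows = []
    for _, row in trait_values.iterrows():
        ref = row[ref_samples].to_numpy(dtype=float)
        ref = ref[np.isfinite(ref)]
        if ref.size == 0 or np.median(ref) == 0:
            continue
        stats_rows.append(log_modulus_fold_difference(
            row[list(ref_samples) + list(alt_samples)].to_numpy(dtype=float), ref))
    if not stats_rows:
        return None
    arr = np.nanmean(np.vstack(stats_rows), axis=0)
    n_ref = len(ref_samples)
    return arr[:n_ref], arr[n_ref:]


def ss_variant_contrast(
    genotype_dosage: pd.Series,
    panels: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Contrast alternative-allele carriers vs reference homozygotes.

    ``genotype_dosage`` maps sample -> dosage of the splice-site variant;
    the reference group is dosage 0, the alternative group dosage >= 1.
    ``panels`` maps a panel name (e.g. "elncRNA PSI", "target RPKM",
    "enhancer H3K27ac") to a trait x sample value matrix. For each panel the
    per-sample statistic is the mean log10-modulus fold difference across
    the panel's traits relative to the reference-group median, and groups
    are compared with a two-tailed Mann-Whitney U test.

    Panels where either genotype group has fewer than 2 usable samples are
    skipped with a warning; if no reference samples exist at all, raises.
    """
    dosage = genotype_dosage.dropna()
    ref_samples = list(dosage.index[dosage == 0])
    alt_samples = list(dosage.index[dosage >= 1])
    if not ref_samples:
        raise ValueError("no reference-genotype samples")
    rows = []
    for name, values in panels.items():
        cols = [s for s in values.columns if s in dosage.index]
        ref = [s for s in ref_samples if s in cols]
        alt = [s for s in alt_samples if s in cols]
        if len(ref) < 2 or len(alt) < 2:
            log.warning("panel %s skipped: genotype group of size < 2", name)
            continue
        res = _panel_stats(values[cols], ref, alt)
        if res is None:
            log.warning("panel %s skipped: no usable traits", name)
            continue
        ref_stat, alt_stat = res
        ref_stat = ref_stat[np.isfinite(ref_stat)]
        alt_stat = alt_stat[np.isfinite(alt_stat)]
        if len(ref_stat) < 2 or len(alt_stat) < 2:
            log.warning("panel %s skipped: too few finite statistics", name)
            continue
        u, p = stats.mannwhitneyu(alt_stat, ref_stat, alternative="two-sided")
        rows.append({"panel": name, "n_ref": len(ref_stat), "n_alt": len(alt_stat),
                     "median_alt_stat": float(np.median(alt_stat)),
                     "median_ref_stat": float(np.median(ref_stat)),
                     "mwu_p": float(p)})
    return pd.DataFrame(rows).set_index("panel") if rows else pd.DataFrame(
        columns=["n_ref", "n_alt", "median_alt_stat", "median_ref_stat", "mwu_p"])


def junction_end_position(intron: GenomicInterval, transcript: TranscriptModel) -> str:
    """Assign an intron to the 5' or 3' half of its transcript.

    The intron midpoint is compared with the transcript span midpoint,
    strand-aware; a midpoint exactly at half goes to the 5' end by
    convention. Returns "5prime" or "3prime".
    """
    span = transcript.span
    if intron.start < span.start or intron.end > span.end:
        raise ValueError("intron lies outside the transcript span")
    mid = (intron.start + intron.end) / 2.0
    rel = (mid - span.start) / len(span)
    if transcript.strand == "-":
        rel = 1.0 - rel
    return "5prime" if rel <= 0.5 else "3prime"
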