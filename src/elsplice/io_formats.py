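"""Readers and writers for the standard formats the pipeline touches.

All internal coordinates are 0-based half-open (BED convention). GTF input
(1-based, inclusive) and VCF positions (1-based) are converted on read and
back-converted on write.

The genotype TSV dialect accepted alongside VCF has one row per variant with
columns ``variant_id  chrom  pos  ref  alt  <sample1>  <sample2> ...`` where
``pos`` is 0-based and the per-sample entries are allele dosages in
``{0, 1, 2}`` or ``NA`` for missing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GenotypeMatrix",
    "IntronClusterTable",
    "PhenotypeMatrix",
    "PairwiseAlignment",
    "read_gtf",
    "write_gtf",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_vcf",
    "read_intron_clusters",
    "write_intron_clusters",
    "read_phenotypes",
    "write_phenotypes",
    "read_bed",
    "write_bed",
    "read_alignment_pairs",
    "write_alignment_pairs",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def distance_to_point(self, pos: int) -> int:
        """Distance from a point to the nearest interval edge (0 if inside)."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0


@dataclass
class TranscriptModel:
    """Strand-aware exon chain.

    ``exons`` are genomic 0-based half-open (start, end) pairs stored sorted
    5'->3' along the transcript: ascending genomic order on the plus strand,
    descending on the minus strand.
    """

    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    biotype: str = "lncRNA"
    label: str = "unclassified"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"transcript {self.id}: strand must be + or -")
        key = (lambda e: e[0]) if self.strand == "+" else (lambda e: -e[0])
        self.exons = sorted(self.exons, key=key)
        genomic = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"transcript {self.id}: overlapping exons")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def multi_exonic(self) -> bool:
        return self.n_exons >= 2

    @property
    def span(self) -> GenomicInterval:
        starts = [e[0] for e in self.exons]
        ends = [e[1] for e in self.exons]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand, self.id)

    @property
    def tss(self) -> int:
        """Genomic position of the strand-aware 5' terminus (0-based)."""
        return self.span.start if self.strand == "+" else self.span.end - 1

    @property
    def introns(self) -> list[GenomicInterval]:
        """Introns in genomic coordinates, ordered 5'->3' along the transcript."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append(GenomicInterval(self.chrom, e1, s2, self.strand))
            else:
                out.append(GenomicInterval(self.chrom, e2, s1, self.strand))
        return out


class GenotypeMatrix:
    """Samples x variants dosage matrix with variant metadata.

    ``dosages`` is an (n_samples, n_variants) float array with values in
    {0, 1, 2} and NaN for missing calls. ``variants`` is a DataFrame indexed
    by variant id with columns chrom, pos (0-based), ref, alt.
    """

    def __init__(self, samples: list[str], variants: pd.DataFrame, dosages: np.ndarray):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(samples), len(variants)):
            raise ValueError("dosage shape does not match samples x variants")
        self.samples = list(samples)
        self.variants = variants
        self.dosages = dosages

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def maf(self) -> pd.Series:
        """Minor allele frequency per variant from non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f = np.nanmean(self.dosages, axis=0) / 2.0
        maf = np.minimum(f, 1.0 - f)
        return pd.Series(maf, index=self.variants.index, name="maf")

    def drop_all_missing(self) -> "GenotypeMatrix":
        keep = ~np.all(np.isnan(self.dosages), axis=0)
        if not keep.all():
            log.warning("dropping %d all-missing variants", (~keep).sum())
        return self.subset_variants(self.variants.index[keep])

    def subset_variants(self, ids) -> "GenotypeMatrix":
        idx = self.variants.index.get_indexer(ids)
        if (idx < 0).any():
            raise KeyError("unknown variant id(s)")
        return GenotypeMatrix(self.samples, self.variants.loc[ids].copy(), self.dosages[:, idx])

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.samples, columns=self.variants.index)


@dataclass
class IntronClusterTable:
    """LeafCutter-style per-sample junction counts.

    ``counts``: DataFrame indexed by intron key ``chrom:start:end:cluID``
    with one integer column per sample. ``introns``: DataFrame (same index)
    with parsed chrom, start, end, cluster columns.
    """

    counts: pd.DataFrame
    introns: pd.DataFrame = field(default=None)

    def __post_init__(self):
        if self.introns is None:
            self.introns = parse_intron_index(self.counts.index)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative junction count")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def clusters(self) -> pd.core.groupby.DataFrameGroupBy:
        return self.introns.groupby("cluster", sort=False)


def parse_intron_index(index) -> pd.DataFrame:
    rows = []
    for i, key in enumerate(index):
        parts = str(key).split(":")
        if len(parts) != 4:
            raise ValueError(f"malformed intron row key at line {i + 1}: {key!r}")
        chrom, start, end, clu = parts
        try:
            start, end = int(start), int(end)
        except ValueError as exc:
            raise ValueError(f"malformed intron row key at line {i + 1}: {key!r}") from exc
        rows.append((key, chrom, start, end, clu))
    df = pd.DataFrame(rows, columns=["key", "chrom", "start", "end", "cluster"])
    return df.set_index("key")


@dataclass
class PhenotypeMatrix:
    """Trait x sample matrix tagged with its kind.

    kind is one of {"expression", "splicing", "chromatin"} corresponding to
    RPKM, PSI and CPM units respectively.
    """

    values: pd.DataFrame
    kind: str = "expression"

    _KINDS = ("expression", "splicing", "chromatin")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate trait ids")
        vals = self.values.to_numpy(dtype=float)
        if self.kind == "splicing":
            finite = vals[np.isfinite(vals)]
            if finite.size and ((finite < 0) | (finite > 1)).any():
                raise ValueError("PSI values must lie in [0, 1]")
        else:
            finite = vals[np.isfinite(vals)]
            if finite.size and (finite < 0).any():
                raise ValueError("RPKM/CPM values must be non-negative")

    @property
    def traits(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PairwiseAlignment:
    """Two equal-length gapped sequences (e.g. human/mouse)."""

    name: str
    seq1: str
    seq2: str

    def __post_init__(self):
        self.seq1 = self.seq1.upper()
        self.seq2 = self.seq2.upper()
        if len(self.seq1) != len(self.seq2):
            raise ValueError(f"alignment {self.name}: unequal lengths")
        ok = set("ACGTN-")
        if (set(self.seq1) | set(self.seq2)) - ok:
            raise ValueError(f"alignment {self.name}: alphabet outside ACGTN-")

    def __len__(self) -> int:
        return len(self.seq1)

    def ungapped_columns(self) -> np.ndarray:
        a = np.frombuffer(self.seq1.encode(), dtype="S1")
        b = np.frombuffer(self.seq2.encode(), dtype="S1")
        bad = (a == b"-") | (b == b"-") | (a == b"N") | (b == b"N")
        return ~bad

    @property
    def n_ungapped(self) -> int:
        return int(self.ungapped_columns().sum())

    @property
    def gc_fraction(self) -> float:
        """GC of the first (reference) sequence, over non-gap, non-N sites."""
        s = self.seq1.replace("-", "").replace("N", "")
        if not s:
            return float("nan")
        return (s.count("G") + s.count("C")) / len(s)


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path) -> list[TranscriptModel]:
    """Parse exon records of a GTF file into TranscriptModels.

    GTF is 1-based inclusive; exons are converted to 0-based half-open and
    ordered 5'->3' along the strand. Biotype is taken from
    ``transcript_biotype`` or ``gene_biotype`` attributes (default lncRNA).
    """
    exons: dict[str, dict] = {}
    n_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            n_lines += 1
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            chrom, start, end, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
            a = _parse_gtf_attrs(attrs)
            tid = a.get("transcript_id") or a.get("gene_id")
            if tid is None:
                raise ValueError("GTF exon record lacks transcript_id")
            biotype = a.get("transcript_biotype") or a.get("gene_biotype") or "lncRNA"
            if biotype in ("lincRNA", "antisense", "lncRNA"):
                biotype = "lncRNA"
            rec = exons.setdefault(tid, {"chrom": chrom, "strand": strand,
                                         "biotype": biotype, "exons": []})
            rec["exons"].append((start - 1, end))
    if n_lines == 0:
        log.warning("empty GTF file %s", path)
        return []
    out = []
    for tid, rec in exons.items():
        try:
            out.append(TranscriptModel(tid, rec["chrom"], rec["strand"],
                                       rec["exons"], biotype=rec["biotype"]))
        except ValueError as exc:
            raise ValueError(f"GTF parse error for transcript {tid}: {exc}") from exc
    return out


def _parse_gtf_attrs(attrs: str) -> dict:
    out = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " in chunk:
            k, v = chunk.split(" ", 1)
            out[k] = v.strip().strip('"')
    return out


def write_gtf(transcripts: list[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            for s, e in sorted(t.exons):
                attrs = (f'gene_id "{t.id}"; transcript_id "{t.id}"; '
                         f'gene_biotype "{t.biotype}";')
                fh.write("\t".join([t.chrom, "elsplice", "exon", str(s + 1),
                                    str(e), ".", t.strand, ".", attrs]) + "\n")


# ---------------------------------------------------------------------------
# Genotypes


def read_genotypes(path) -> GenotypeMatrix:
    """Read a genotype matrix from a minimal VCF 4.2 (GT only) or TSV dosage file.

    Multi-allelic VCF records are skipped with a warning; variants that are
    missing in every sample are dropped.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##fileformat=VCF") or path.suffix == ".vcf":
        gm = _read_vcf(path)
    else:
        gm = _read_genotype_tsv(path)
    return gm.drop_all_missing()


def _read_vcf(path) -> GenotypeMatrix:
    samples, rows, dosage_rows = None, [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            f = line.split("\t")
            chrom, pos, vid, ref, alt = f[0], int(f[1]), f[2], f[3], f[4]
            if "," in alt:
                log.warning("skipping multi-allelic record %s", vid)
                continue
            fmt = f[8].split(":")
            gt_i = fmt.index("GT")
            dos = []
            for cell in f[9:]:
                gt = cell.split(":")[gt_i].replace("|", "/")
                if "." in gt:
                    dos.append(np.nan)
                else:
                    dos.append(sum(int(x) for x in gt.split("/")))
            rows.append((vid if vid != "." else f"{chrom}_{pos}", chrom, pos - 1, ref, alt))
            dosage_rows.append(dos)
    if samples is None:
        raise ValueError("VCF lacks a #CHROM header line")
    variants = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "ref", "alt"])
    variants = variants.set_index("variant_id")
    dosages = np.array(dosage_rows, dtype=float).T if dosage_rows else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, variants, dosages)


def _read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["variant_id", "chrom", "pos", "ref", "alt"]
    if list(df.columns[:5]) != meta_cols:
        raise ValueError(f"genotype TSV must start with columns {meta_cols}")
    variants = df[meta_cols].set_index("variant_id")
    dosages = df[df.columns[5:]].to_numpy(dtype=float).T
    return GenotypeMatrix(list(df.columns[5:]), variants, dosages)


def write_genotypes_tsv(gm: GenotypeMatrix, path) -> None:
    df = gm.variants.reset_index()
    for i, s in enumerate(gm.samples):
        df[s] = gm.dosages[i]
    df.to_csv(path, sep="\t", index=False, na_rep="NA",
              float_format="%g")


def write_genotypes_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype fields (phasing not kept)."""
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for j, (vid, row) in enumerate(gm.variants.iterrows()):
            cells = []
            for i in range(gm.n_samples):
                d = gm.dosages[i, j]
                cells.append("./." if np.isnan(d) else gt_of[int(d)])
            fh.write("\t".join([str(row["chrom"]), str(int(row["pos"]) + 1), str(vid),
                                str(row["ref"]), str(row["alt"]), ".", ".", ".", "GT"]
                               + cells) + "\n")


# ---------------------------------------------------------------------------
# Intron cluster counts (LeafCutter dialect)


def read_intron_clusters(path) -> IntronClusterTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    introns = parse_intron_index(df.index)
    counts = df.astype(int)
    return IntronClusterTable(counts=counts, introns=introns)


def write_intron_clusters(table: IntronClusterTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="intron")


# ---------------------------------------------------------------------------
# Phenotypes


def read_phenotypes(path, kind: str = "expression") -> PhenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return PhenotypeMatrix(values=df, kind=kind)


def write_phenotypes(pm: PhenotypeMatrix, path) -> None:
    pm.values.to_csv(path, sep="\t", index_label="trait")


# ---------------------------------------------------------------------------
# BED


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into GenomicIntervals (0-based half-open, as on disk)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            name = f[3] if len(f) > 3 else ""
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, strand, name))
    return out


def write_bed(intervals: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Aligned FASTA pairs


def read_alignment_pairs(path) -> list[PairwiseAlignment]:
    """Read pairwise alignments from FASTA: records come in consecutive pairs
    named ``<name>/1`` and ``<name>/2``."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2:
        raise ValueError("aligned FASTA must contain an even number of records")
    out = []
    for r1, r2 in zip(records[::2], records[1::2]):
        name = r1.id.rsplit("/", 1)[0]
        if r2.id.rsplit("/", 1)[0] != name:
            raise ValueError(f"unpaired records {r1.id} / {r2.id}")
        out.append(PairwiseAlignment(name, str(r1.seq), str(r2.seq)))
    return out


def write_alignment_pairs(alignments: list[PairwiseAlignment], path) -> None:
    records = []
    for aln in alignments:
        records.append(SeqRecord(Seq(aln.seq1), id=f"{aln.name}/1", description=""))
        records.append(SeqRecord(Seq(aln.seq2), id=f"{aln.name}/2", description=""))
    SeqIO.write(records, str(path), "fasta")
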