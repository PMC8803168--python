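"""Transcript classification and splice-site variant discovery.

Transcripts are assigned to regulatory classes by the distance between their
strand-aware 5' terminus and enhancer/promoter intervals: lncRNAs starting
within ``window`` bp of an intergenic enhancer are enhancer-associated
lncRNAs (elncRNA); transcripts starting within ``window`` bp of a promoter
are promoter-associated lncRNAs (plncRNA) or protein-coding genes (pcg) by
biotype. Enhancers left without an assigned transcript are treated as
bidirectional eRNA-producing enhancers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, TranscriptModel

log = logging.getLogger(__name__)

__all__ = ["classify_transcripts", "find_splice_site_variants", "SpliceSiteVariant"]


@dataclass(frozen=True)
class SpliceSiteVariant:
    """A variant overlapping a donor GT or acceptor AG intronic dinucleotide."""

    variant_id: str
    transcript_id: str
    site_kind: str          # "donor" | "acceptor"
    intron_index: int       # 0-based, 5'->3' along the transcript
    position: int           # genomic 0-based position of the variant


def _min_edge_distance(pos: int, chrom: str, intervals: list[GenomicInterval]) -> int:
    dists = [iv.distance_to_point(pos) for iv in intervals if iv.chrom == chrom]
    return min(dists) if dists else np.iinfo(np.int64).max


def classify_transcripts(
    transcripts: list[TranscriptModel],
    enhancers: list[GenomicInterval],
    promoters: list[GenomicInterval],
    window: int = 500,
) -> tuple[list[TranscriptModel], list[GenomicInterval]]:
    """Label transcripts as elncRNA / plncRNA / pcg / unclassified.

    The distance is measured from the strand-aware 5' end to the nearest
    interval edge, inclusive of overlap (distance 0) and of the window
    boundary itself. For lncRNAs an enhancer match takes precedence over a
    promoter match. Returns the labelled transcripts (labels set in place)
    and the enhancers with no assigned transcript (the eRNA class).

    Transcripts on chromosomes absent from both annotation sets are left
    unclassified with a warning.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    annotated_chroms = {iv.chrom for iv in enhancers} | {iv.chrom for iv in promoters}
    used_enhancers: set[int] = set()
    for t in transcripts:
        if t.chrom not in annotated_chroms:
            log.warning("transcript %s on unannotated chromosome %s", t.id, t.chrom)
            t.label = "unclassified"
            continue
        pos = t.tss
        near_enh = [i for i, iv in enumerate(enhancers)
                    if iv.chrom == t.chrom and iv.distance_to_point(pos) <= window]
        near_prom = _min_edge_distance(pos, t.chrom, promoters) <= window
        if t.biotype == "lncRNA" and near_enh:
            t.label = "elncRNA"
            used_enhancers.update(near_enh)
        elif near_prom:
            t.label = "pcg" if t.biotype == "protein_coding" else "plncRNA"
        else:
            t.label = "unclassified"
    erna_enhancers = [iv for i, iv in enumerate(enhancers) if i not in used_enhancers]
    return transcripts, erna_enhancers


def labels_frame(transcripts: list[TranscriptModel]) -> pd.DataFrame:
    rows = [(t.id, t.chrom, t.span.start, t.span.end, t.strand, t.biotype,
             t.label, t.n_exons, t.multi_exonic) for t in transcripts]
    return pd.DataFrame(rows, columns=["transcript_id", "chrom", "start", "end",
                                       "strand", "biotype", "label", "n_exons",
                                       "multi_exonic"]).set_index("transcript_id")


def _donor_acceptor_positions(intron: GenomicInterval, strand: str):
    """Genomic positions of the donor GT and acceptor AG dinucleotides.

    On the plus strand the donor is the first two intronic bases and the
    acceptor the last two; on the minus strand the donor dinucleotide sits at
    the genomic *end* of the intron (the 5' side in transcript orientation).
    """
    left = (intron.start, intron.start + 1)
    right = (intron.end - 2, intron.end - 1)
    if strand == "+":
        return left, right
    return right, left


def find_splice_site_variants(
    variants: pd.DataFrame,
    transcripts: list[TranscriptModel],
) -> list[SpliceSiteVariant]:
    """Find variants that overlap donor GT / acceptor AG dinucleotides.

    ``variants`` must have columns chrom and pos (0-based) and a variant-id
    index. Only multi-exonic enhancer-associated lncRNAs are scanned;
    variants on contigs without any such transcript are silently excluded.
    """
    hits: list[SpliceSiteVariant] = []
    targets = [t for t in transcripts if t.label == "elncRNA" and t.multi_exonic]
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in targets:
        by_chrom.setdefault(t.chrom, []).append(t)
    for vid, row in variants.iterrows():
        for t in by_chrom.get(str(row["chrom"]), []):
            for i, intron in enumerate(t.introns):
                donor, acceptor = _donor_acceptor_positions(intron, t.strand)
                pos = int(row["pos"])
                if pos in donor:
                    hits.append(SpliceSiteVariant(str(vid), t.id, "donor", i, pos))
                elif pos in acceptor:
                    hits.append(SpliceSiteVariant(str(vid), t.id, "acceptor", i, pos))
    return hits
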