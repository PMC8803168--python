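"""Splice-site-flanking window extraction, hexamer scanning and GC profiles.

Exonic splicing enhancer (ESE) scans use the 50 exonic nt flanking each
splice site of internal exons longer than 100 nt, with the 5 nt immediately
adjacent to the splice site masked to avoid splice-site-associated
composition bias. U1 snRNP binding-site scans use a 9-nt window per 5'
splice site (3 exonic + 6 intronic nt). Matching is exact hexamer identity
at every offset (overlaps allowed); density is matches per unmasked nt.

The canonical U1 hexamers (DNA form GGTAAG, GGTGAG, GTGAGT) ship exactly.
The two ESE hexamer collections bundled under ``data/`` are deterministic
synthetic stand-ins for the published 238-motif and 54-motif sets (which
are external supplementary data); they preserve set sizes and the
purine-rich composition typical of ESEs but not the published sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .io_formats import TranscriptModel

log = logging.getLogger(__name__)

__all__ = ["MotifSet", "ScanWindow", "load_motif_set", "extract_windows",
           "scan_hexamers", "gc_profile", "U1_HEXAMERS"]

U1_HEXAMERS = ("GGTAAG", "GGTGAG", "GTGAGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSet:
    name: str
    hexamers: tuple[str, ...]

    def __post_init__(self):
        for m in self.hexamers:
            if len(m) != 6 or set(m) - set("ACGT"):
                raise ValueError(f"motif {m!r} is not a DNA hexamer")


def load_motif_set(name: str) -> MotifSet:
    """Load a named hexamer set: "ESE238", "ESE54" (synthetic stand-ins) or "U1"."""
    if name == "U1":
        return MotifSet("U1", U1_HEXAMERS)
    files = {"ESE238": "ese238_synthetic.txt", "ESE54": "ese54_synthetic.txt"}
    if name not in files:
        raise ValueError(f"unknown motif set {name!r}")
    text = resources.files("elsplice.data").joinpath(files[name]).read_text()
    hexamers = tuple(l.strip().upper() for l in text.splitlines()
                     if l.strip() and not l.startswith("#"))
    return MotifSet(name, hexamers)


@dataclass
class ScanWindow:
    """A sequence window in transcript orientation with per-base masking."""

    transcript_id: str
    site_kind: str                 # "ese_acceptor" | "ese_donor" | "u1_5ss"
    seq: str
    mask: np.ndarray = field(default=None)

    def __post_init__(self):
        self.seq = self.seq.upper()
        if self.mask is None:
            self.mask = np.zeros(len(self.seq), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (len(self.seq),):
            raise ValueError("mask length differs from sequence length")

    @property
    def effective_length(self) -> int:
        return int((~self.mask).sum())


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end] from a dict of strings or pyfaidx.Fasta."""
    seq = genome[chrom]
    if hasattr(seq, "__getitem__") and not isinstance(seq, str):
        return str(seq[start:end]).upper()
    return seq[start:end].upper()


def _exon_seq(t: TranscriptModel, genome, exon: tuple[int, int]) -> str:
    s = _fetch(genome, t.chrom, exon[0], exon[1])
    return s if t.strand == "+" else revcomp(s)


def extract_windows(t: TranscriptModel, genome, kind: str,
                    flank: int = 50, mask_adjacent: int = 5) -> list[ScanWindow]:
    """Extract ESE or U1 scan windows for one transcript.

    kind="ESE": internal exons longer than 100 nt contribute two windows,
    the first ``flank`` nt (acceptor side) and the last ``flank`` nt (donor
    side) in transcript orientation, with the ``mask_adjacent`` nt nearest
    the splice site masked. Exons shorter than the window are truncated.

    kind="U1": one 9-nt window per 5' splice site (last 3 exonic nt + first
    6 intronic nt of each intron). Minus-strand sequences come out
    reverse-complemented, so all windows read 5'->3' along the transcript.
    """
    windows: list[ScanWindow] = []
    if kind == "ESE":
        for i, exon in enumerate(t.exons):
            if i == 0 or i == t.n_exons - 1:
                continue
            if exon[1] - exon[0] <= 100:
                continue
            seq = _exon_seq(t, genome, exon)
            w = min(flank, len(seq))
            left = seq[:w]
            lm = np.zeros(w, dtype=bool)
            lm[:min(mask_adjacent, w)] = True   # 5 nt nearest the acceptor
            windows.append(ScanWindow(t.id, "ese_acceptor", left, lm))
            right = seq[-w:]
            rm = np.zeros(w, dtype=bool)
            rm[max(0, w - mask_adjacent):] = True  # 5 nt nearest the donor
            windows.append(ScanWindow(t.id, "ese_donor", right, rm))
    elif kind == "U1":
        introns = t.introns
        for i, exon in enumerate(t.exons[:-1]):
            exon_seq = _exon_seq(t, genome, exon)
            intron = introns[i]
            iseq = _fetch(genome, t.chrom, intron.start, intron.end)
            if t.strand == "-":
                iseq = revcomp(iseq)
            win = exon_seq[-3:] + iseq[:6]
            windows.append(ScanWindow(t.id, "u1_5ss", win))
    else:
        raise ValueError("kind must be 'ESE' or 'U1'")
    return windows


def scan_hexamers(window: ScanWindow, motif_set: MotifSet) -> tuple[int, float]:
    """Count perfect hexamer matches (overlaps allowed) and their density.

    A match must not touch a masked position; N never matches. Density is
    count per unmasked nt (0 when the window is fully masked).
    """
    seq = window.seq
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence alphabet outside {A,C,G,T,N}")
    motifs = set(motif_set.hexamers)
    count = 0
    for off in range(len(seq) - 5):
        if window.mask[off:off + 6].any():
            continue
        if seq[off:off + 6] in motifs:
            count += 1
    eff = window.effective_length
    return count, (count / eff if eff else 0.0)


def scan_density(windows: list[ScanWindow], motif_set: MotifSet) -> float:
    """Pooled density over windows: total matches / total unmasked length."""
    total, eff = 0, 0
    for w in windows:
        c, _ = scan_hexamers(w, motif_set)
        total += c
        eff += w.effective_length
    return total / eff if eff else 0.0


def _gc(seq: str) -> float:
    s = seq.replace("N", "")
    return (s.count("G") + s.count("C")) / len(s) if s else float("nan")


def gc_profile(t: TranscriptModel, genome, flank_gap: int = 500) -> dict[str, float]:
    """GC fraction of the first exon, remaining exons, introns and flanks.

    The two intergenic flanks each mirror the transcript span length and
    start ``flank_gap`` nt away from the annotation (the immediately
    adjacent sequence is excluded); flanks running off the contig are
    truncated with a warning. Requires a multi-exonic transcript.
    """
    if not t.multi_exonic:
        raise ValueError("GC profile requires a multi-exonic transcript")
    first = _exon_seq(t, genome, t.exons[0])
    rest = "".join(_exon_seq(t, genome, e) for e in t.exons[1:])
    intr = "".join(_fetch(genome, t.chrom, iv.start, iv.end) for iv in t.introns)
    span = t.span
    contig_len = len(genome[t.chrom])
    L = len(span)
    up_end = span.start - flank_gap
    up_start = up_end - L
    if up_start < 0:
        log.warning("upstream flank truncated at contig start for %s", t.id)
        up_start = 0
    down_start = span.end + flank_gap
    down_end = down_start + L
    if down_end > contig_len:
        log.warning("downstream flank truncated at contig end for %s", t.id)
        down_end = contig_len
    flank_seq = ""
    if up_end > up_start:
        flank_seq += _fetch(genome, t.chrom, up_start, up_end)
    if down_end > down_start:
        flank_seq += _fetch(genome, t.chrom, down_start, down_end)
    return {
        "first_exon": _gc(first),
        "other_exons": _gc(rest),
        "introns": _gc(intr),
        "flank": _gc(flank_seq),
    }
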