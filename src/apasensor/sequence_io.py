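"""Genome/annotation I/O and the shared coordinate model.

Conventions used throughout the package:

* Genomic intervals are 0-based, half-open ``[start, end)`` — the convention of
  BED and of pysam-style APIs.
* Offsets around a poly(A) site are *inclusive on both ends* and counted in
  transcript (5'->3') orientation, with the cleavage nucleotide at offset 0.
  Upstream offsets are negative, downstream positive.
* Sequences handed to callers are always transcript-oriented: minus-strand
  windows are reverse-complemented on extraction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "PolyASite",
    "GeneModel",
    "FlankSequence",
    "load_fasta",
    "write_fasta",
    "load_gtf",
    "write_gtf",
    "load_bed6",
    "write_bed6",
    "extract_flank",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """A set of chromosome sequences with bounds-checked lookup.

    Sequences are upper-cased on construction; alphabet {A,C,G,T,N}.
    """

    def __init__(self, records: dict[str, str]):
        self._seqs = {name: s.upper() for name, s in records.items()}

    @property
    def chrom_names(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return [start, end) of *chrom* (plus strand); reject out-of-bounds."""
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome {chrom!r}")
        n = len(self._seqs[chrom])
        if start < 0 or end > n or start > end:
            raise ValueError(
                f"window [{start}, {end}) outside chromosome {chrom!r} bounds [0, {n})"
            )
        return self._seqs[chrom][start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeSequence) and self._seqs == other._seqs


@dataclass(frozen=True)
class PolyASite:
    """A cleavage/polyadenylation site.

    ``cleavage_pos`` is the 0-based genomic coordinate of the last transcribed
    nucleotide (offset 0 in flank coordinates).
    """

    chrom: str
    strand: str
    cleavage_pos: int
    gene_id: str = ""
    label: str = ""  # proximal / distal / intronic

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class GeneModel:
    """A gene: sorted non-overlapping exons plus its pA sites.

    Introns are always derived from the exon list, never stored.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    pa_sites: list[PolyASite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        self.exons = sorted(tuple(e) for e in self.exons)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(
                    f"{self.gene_id}: overlapping exons ({s0},{e0}) and ({s1},{e1})"
                )
        for (s, e) in self.exons:
            if s >= e:
                raise ValueError(f"{self.gene_id}: empty exon ({s},{e})")
        span = self.span
        for pa in self.pa_sites:
            if not (span[0] <= pa.cleavage_pos < span[1]):
                raise ValueError(
                    f"{self.gene_id}: pA at {pa.cleavage_pos} outside gene span {span}"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Genomic intron intervals in *transcript* order.

        For a minus-strand gene intron 0 sits between the transcript's first
        and second exons, i.e. at the genomically 3'-most gap.
        """
        gaps = [
            (e0[1], e1[0]) for e0, e1 in zip(self.exons, self.exons[1:])
        ]
        return gaps if self.strand == "+" else gaps[::-1]

    @property
    def exons_tx_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else self.exons[::-1]

    @property
    def three_prime_exon(self) -> tuple[int, int]:
        return self.exons_tx_order[-1]

    def tx_position(self, genomic_pos: int) -> int:
        """Genomic coordinate -> 5'->3' orientation key (larger = more 3')."""
        return genomic_pos if self.strand == "+" else -genomic_pos

    def pa_sites_tx_order(self) -> list[PolyASite]:
        return sorted(self.pa_sites, key=lambda p: self.tx_position(p.cleavage_pos))

    @property
    def first_pa_index(self) -> int:
        """Index (in tx order) of the most proximal pA inside the 3'-most exon."""
        lo, hi = self.three_prime_exon
        for i, pa in enumerate(self.pa_sites_tx_order()):
            if lo <= pa.cleavage_pos < hi:
                return i
        raise ValueError(f"{self.gene_id}: no pA in the 3'-most exon")


@dataclass
class FlankSequence:
    """A transcript-oriented window around a pA with its offset map.

    ``offsets[i]`` is the transcript-space offset of ``seq[i]``; ``mask[i]`` is
    True where the window ran off the chromosome end (sequence padded with N).
    """

    site: PolyASite
    seq: str
    offsets: np.ndarray
    mask: np.ndarray

    def at_offset(self, offset: int) -> str:
        idx = np.where(self.offsets == offset)[0]
        if idx.size == 0:
            raise KeyError(f"offset {offset} not in window")
        return self.seq[int(idx[0])]

    def region(self, lo: int, hi: int) -> str:
        """Subsequence covering offsets lo..hi inclusive (must be in-window)."""
        sel = (self.offsets >= lo) & (self.offsets <= hi)
        if sel.sum() != hi - lo + 1:
            raise ValueError(f"region {lo}..{hi} not fully inside window")
        return "".join(np.array(list(self.seq))[sel])


def extract_flank(
    genome: GenomeSequence, site: PolyASite, upstream: int, downstream: int
) -> FlankSequence:
    """Extract offsets -upstream..+downstream around a pA, transcript-oriented.

    Offset 0 is the cleavage nucleotide. Windows running off a chromosome end
    are clipped and padded with ``N``; the pad is recorded in ``mask``, never
    silently shortened.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream/downstream must be >= 0")
    n = genome.length(site.chrom)
    if site.strand == "+":
        g_start = site.cleavage_pos - upstream
        g_end = site.cleavage_pos + downstream + 1
    else:
        g_start = site.cleavage_pos - downstream
        g_end = site.cleavage_pos + upstream + 1
    lo = max(g_start, 0)
    hi = min(g_end, n)
    if lo >= hi:
        raise ValueError("window entirely off chromosome")
    core = genome.fetch(site.chrom, lo, hi)
    left_pad = lo - g_start
    right_pad = g_end - hi
    seq = "N" * left_pad + core + "N" * right_pad
    mask = np.zeros(len(seq), dtype=bool)
    if left_pad:
        mask[:left_pad] = True
    if right_pad:
        mask[-right_pad:] = True
    if site.strand == "-":
        seq = reverse_complement(seq)
        mask = mask[::-1].copy()
    offsets = np.arange(-upstream, downstream + 1)
    return FlankSequence(site=site, seq=seq, offsets=offsets, mask=mask)


# ---------------------------------------------------------------------------
# FASTA


def load_fasta(path) -> GenomeSequence:
    records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return GenomeSequence(records)


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome.chrom_names):
            fh.write(f">{name}\n")
            s = genome.fetch(name, 0, genome.length(name))
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF (exon records, attributes gene_id / transcript_id)

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def write_gtf(genes: Iterable[GeneModel], path, source: str = "apasensor") -> None:
    genes = sorted(genes, key=lambda g: (g.chrom, g.span[0], g.gene_id))
    with open(path, "w") as fh:
        for g in genes:
            for start, end in g.exons:
                attrs = f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";'
                fh.write(
                    "\t".join(
                        [
                            g.chrom,
                            source,
                            "exon",
                            str(start + 1),  # GTF is 1-based inclusive
                            str(end),
                            ".",
                            g.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def load_gtf(path) -> list[GeneModel]:
    """Parse exon records into GeneModels (one transcript per gene assumed).

    Malformed lines are reported with their line numbers.
    """
    exons: dict[str, dict] = {}
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                errors.append(f"line {lineno}: expected 9 fields, got {len(parts)}")
                continue
            chrom, _src, feature, start, end, _score, strand, _frame, attr = parts
            if feature != "exon":
                continue
            attrs = dict(_ATTR_RE.findall(attr))
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                errors.append(f"line {lineno}: missing gene_id attribute")
                continue
            try:
                s, e = int(start) - 1, int(end)
            except ValueError:
                errors.append(f"line {lineno}: non-integer coordinates")
                continue
            if s >= e:
                errors.append(f"line {lineno}: start > end")
                continue
            rec = exons.setdefault(gene_id, {"chrom": chrom, "strand": strand, "exons": []})
            if rec["chrom"] != chrom or rec["strand"] != strand:
                errors.append(f"line {lineno}: inconsistent chrom/strand for {gene_id}")
                continue
            rec["exons"].append((s, e))
    if errors:
        raise ValueError("malformed GTF:\n" + "\n".join(errors))
    genes = []
    for gene_id, rec in exons.items():
        genes.append(
            GeneModel(gene_id=gene_id, chrom=rec["chrom"], strand=rec["strand"], exons=rec["exons"])
        )
    return sorted(genes, key=lambda g: (g.chrom, g.span[0], g.gene_id))


# ---------------------------------------------------------------------------
# BED6 for pA sites (name = gene:index, score = 0)


def write_bed6(sites: Iterable[PolyASite], path) -> None:
    sites = sorted(sites, key=lambda s: (s.chrom, s.cleavage_pos, s.strand))
    with open(path, "w") as fh:
        for s in sites:
            name = f"{s.gene_id}:{s.label}" if s.gene_id else (s.label or ".")
            fh.write(
                f"{s.chrom}\t{s.cleavage_pos}\t{s.cleavage_pos + 1}\t{name}\t0\t{s.strand}\n"
            )


def load_bed6(path) -> list[PolyASite]:
    sites = []
    errors = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                errors.append(f"line {lineno}: expected 6 BED fields")
                continue
            chrom, start, end, name, _score, strand = parts[:6]
            try:
                s, e = int(start), int(end)
            except ValueError:
                errors.append(f"line {lineno}: non-integer coordinates")
                continue
            if s >= e:
                errors.append(f"line {lineno}: start >= end")
                continue
            gene_id, _, label = name.partition(":")
            sites.append(
                PolyASite(chrom=chrom, strand=strand, cleavage_pos=s, gene_id=gene_id, label=label)
            )
    if errors:
        raise ValueError("malformed BED6:\n" + "\n".join(errors))
    return sites
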