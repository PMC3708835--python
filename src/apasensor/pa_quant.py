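"""3'-end sequencing (3'READS-style) quantification.

Reads arrive as tabular alignment records already converted to
sense-of-transcript orientation; each carries the genomic position of its
transcript-3'-most aligned base (the inferred cleavage site) and the number of
non-genomic T (poly(A)-tail-derived) bases. Only PASS reads — more than 2
non-genomic Ts — evidence a genuine poly(A) junction and are quantified.
PASS read 3' ends are clustered along each (chrom, strand) by single linkage,
clusters are assigned to genes, and per-(gene, pA) per-sample counts form the
isoform count table downstream statistics consume.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .sequence_io import GeneModel

__all__ = [
    "AlignedRead3p",
    "PolyASiteCluster",
    "PASS_MIN_NONGENOMIC_T",
    "CLUSTER_WINDOW_DEFAULT",
    "classify_pass",
    "call_pa_clusters",
    "assign_clusters_to_genes",
    "gene_expression",
    "read_alignment_table",
    "write_alignment_table",
]

# "more than 2 non-genomic Ts": a PASS read has >= 3
PASS_MIN_NONGENOMIC_T = 3
CLUSTER_WINDOW_DEFAULT = 24

_TABLE_COLUMNS = ["read_id", "chrom", "strand", "mapped_3p_pos", "nongenomic_T", "sample_id"]


@dataclass(frozen=True)
class AlignedRead3p:
    read_id: str
    chrom: str
    strand: str
    mapped_3p_pos: int
    nongenomic_T: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.nongenomic_T < 0:
            raise ValueError("nongenomic_T must be >= 0")


@dataclass
class PolyASiteCluster:
    chrom: str
    strand: str
    representative_pos: int  # modal member position; ties -> 5'-most (tx sense)
    span: tuple[int, int]  # half-open genomic interval covering members
    read_count: dict[str, int]  # per sample
    gene_id: str = ""

    @property
    def total(self) -> int:
        return sum(self.read_count.values())


def classify_pass(read: AlignedRead3p) -> bool:
    """True iff the read has more than 2 non-genomic Ts."""
    return read.nongenomic_T > 2


def call_pa_clusters(
    pass_reads: Iterable[AlignedRead3p], cluster_window: int = CLUSTER_WINDOW_DEFAULT
) -> list[PolyASiteCluster]:
    """Single-linkage clustering of read 3' ends per (chrom, strand).

    Consecutive positions at most *cluster_window* nt apart join one cluster.
    The representative is the modal position; on a tie the transcript-5'-most
    position wins (smallest coordinate on plus, largest on minus). Output is
    independent of input order.
    """
    by_key: dict[tuple[str, str], list[AlignedRead3p]] = defaultdict(list)
    for r in pass_reads:
        by_key[(r.chrom, r.strand)].append(r)

    clusters: list[PolyASiteCluster] = []
    for (chrom, strand), reads in sorted(by_key.items()):
        reads.sort(key=lambda r: r.mapped_3p_pos)
        group: list[AlignedRead3p] = []
        for r in reads:
            if group and r.mapped_3p_pos - group[-1].mapped_3p_pos > cluster_window:
                clusters.append(_finish_cluster(chrom, strand, group))
                group = []
            group.append(r)
        if group:
            clusters.append(_finish_cluster(chrom, strand, group))
    return clusters


def _finish_cluster(chrom: str, strand: str, members: list[AlignedRead3p]) -> PolyASiteCluster:
    counts = Counter(r.mapped_3p_pos for r in members)
    max_count = max(counts.values())
    modal = [pos for pos, c in counts.items() if c == max_count]
    representative = min(modal) if strand == "+" else max(modal)
    per_sample: Counter[str] = Counter(r.sample_id for r in members)
    positions = sorted(counts)
    return PolyASiteCluster(
        chrom=chrom,
        strand=strand,
        representative_pos=representative,
        span=(positions[0], positions[-1] + 1),
        read_count=dict(sorted(per_sample.items())),
    )


def assign_clusters_to_genes(
    clusters: Sequence[PolyASiteCluster],
    gene_models: Sequence[GeneModel],
    downstream_extension: int = 0,
) -> tuple[pd.DataFrame, list[tuple[PolyASiteCluster, str]]]:
    """Assign clusters to genes and build the isoform count table.

    A cluster belongs to the gene whose span (extended *downstream_extension*
    nt past the transcript 3' end) contains its representative on the same
    strand. Clusters matching no gene or more than one gene are set aside with
    a reason, not counted.

    Returns (table, unassigned). The table is indexed by (gene_id, pa_index)
    with pa_index numbering the gene's clusters 0,1,... in 5'->3' transcript
    order; columns are sample ids; values PASS-read counts.
    """
    spans: list[tuple[GeneModel, int, int]] = []
    for g in gene_models:
        lo, hi = g.span
        if g.strand == "+":
            hi += downstream_extension
        else:
            lo -= downstream_extension
        spans.append((g, lo, hi))

    assigned: dict[str, list[PolyASiteCluster]] = defaultdict(list)
    unassigned: list[tuple[PolyASiteCluster, str]] = []
    for cl in clusters:
        hits = [
            g
            for g, lo, hi in spans
            if g.chrom == cl.chrom and g.strand == cl.strand and lo <= cl.representative_pos < hi
        ]
        if len(hits) == 1:
            cl.gene_id = hits[0].gene_id
            assigned[hits[0].gene_id].append(cl)
        elif not hits:
            unassigned.append((cl, "no overlapping gene"))
        else:
            unassigned.append((cl, "ambiguous: " + ",".join(g.gene_id for g in hits)))

    genes_by_id = {g.gene_id: g for g in gene_models}
    samples = sorted({s for cl in clusters for s in cl.read_count})
    index: list[tuple[str, int]] = []
    rows: list[list[int]] = []
    for gene_id in sorted(assigned):
        gene = genes_by_id[gene_id]
        ordered = sorted(
            assigned[gene_id], key=lambda c: gene.tx_position(c.representative_pos)
        )
        for i, cl in enumerate(ordered):
            index.append((gene_id, i))
            rows.append([cl.read_count.get(s, 0) for s in samples])
    table = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["gene_id", "pa_index"])
        if index
        else pd.MultiIndex.from_arrays([[], []], names=["gene_id", "pa_index"]),
        columns=samples,
        dtype=int,
    )
    return table, unassigned


def gene_expression(table: pd.DataFrame) -> pd.DataFrame:
    """Per-gene totals per sample (column sums within gene)."""
    return table.groupby(level="gene_id").sum()


# ---------------------------------------------------------------------------
# Tabular alignment I/O


def read_alignment_table(path) -> list[AlignedRead3p]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        AlignedRead3p(
            read_id=str(r.read_id),
            chrom=str(r.chrom),
            strand=str(r.strand),
            mapped_3p_pos=int(r.mapped_3p_pos),
            nongenomic_T=int(r.nongenomic_T),
            sample_id=str(r.sample_id),
        )
        for r in df.itertuples(index=False)
    ]


def write_alignment_table(reads: Iterable[AlignedRead3p], path) -> None:
    df = pd.DataFrame([r.__dict__ for r in reads], columns=_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
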