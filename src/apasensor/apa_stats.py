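"""Statistical layer: APA regulation, differential expression, RUD, and
set-level comparisons.

The APA test follows the two-isoform design: per gene, the top two expressed
pA isoforms (by summed PASS counts across both conditions) enter a 2x2 Fisher
exact test of isoform-by-condition counts; a gene is called regulated when
p < 0.05 and the isoform-fraction change exceeds 5 percentage points.
Differential gene expression uses a gene-vs-rest-of-library 2x2 Fisher test
with p < 0.01 and library-size-normalized fold change > 1.5.

RUD (Relative expression of isoforms Using Distal pAs) is the read density of
the alternative 3'UTR (between the first and distal pA of the 3'-most exon)
over that of the constitutive 3'UTR (upstream of the first pA); the per-sample
median over qualifying genes indexes global 3'UTR length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ApaTestResult",
    "RudRecord",
    "test_apa_top2",
    "test_gene_expression",
    "compute_rud",
    "isoform_ratio",
    "correlate_ratio_vs_rud",
    "concordance_chi2",
    "ks_geneset_shift",
    "APA_P_THRESHOLD",
    "APA_DELTA_THRESHOLD",
    "DE_P_THRESHOLD",
    "DE_FOLD_THRESHOLD",
    "MIN_CUTR_READS_DEFAULT",
]

APA_P_THRESHOLD = 0.05
APA_DELTA_THRESHOLD = 0.05  # >5% change in isoform abundance
DE_P_THRESHOLD = 0.01
DE_FOLD_THRESHOLD = 1.5
MIN_CUTR_READS_DEFAULT = 10


@dataclass
class ApaTestResult:
    gene_id: str
    proximal_idx: int
    distal_idx: int
    counts: tuple[tuple[int, int], tuple[int, int]]  # (isoform x condition): ((pA,pB),(dA,dB))
    p_value: float
    delta_abundance: float  # distal fraction, condition B - condition A
    call: str  # distal_up / proximal_up / not_significant


@dataclass
class RudRecord:
    gene_id: str
    cutr_density: float
    autr_density: float
    rud: float
    qualifies: bool


def test_apa_top2(
    table: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    p_threshold: float = APA_P_THRESHOLD,
    delta_threshold: float = APA_DELTA_THRESHOLD,
) -> tuple[list[ApaTestResult], list[str]]:
    """Two-isoform APA regulation test per gene.

    *table* is an isoform count table indexed by (gene_id, pa_index) with
    columns including *cond_a* and *cond_b*. Top two isoforms are chosen by
    summed count over both conditions (ties: the more 5' isoform first).
    delta_abundance is the change (B - A) in the distal isoform's fraction of
    the tested pair. Genes with fewer than two expressed isoforms are skipped
    and returned in the second element.
    """
    results: list[ApaTestResult] = []
    skipped: list[str] = []
    for gene_id, sub in table.groupby(level="gene_id", sort=True):
        sub = sub.droplevel("gene_id")
        totals = sub[cond_a] + sub[cond_b]
        expressed = totals[totals > 0]
        if len(expressed) < 2:
            skipped.append(f"{gene_id}: fewer than 2 expressed isoforms")
            continue
        # stable sort: descending count, ascending pa_index breaks ties 5'-first
        order = expressed.sort_index().sort_values(ascending=False, kind="stable")
        top2 = sorted(order.index[:2])
        prox_idx, dist_idx = int(top2[0]), int(top2[1])
        pa_, pb = int(sub.at[prox_idx, cond_a]), int(sub.at[prox_idx, cond_b])
        da, db = int(sub.at[dist_idx, cond_a]), int(sub.at[dist_idx, cond_b])
        tot_a, tot_b = pa_ + da, pb + db
        if tot_a == 0 or tot_b == 0:
            skipped.append(f"{gene_id}: a condition has no reads on the top two isoforms")
            continue
        _, p = stats.fisher_exact([[pa_, pb], [da, db]], alternative="two-sided")
        delta = db / tot_b - da / tot_a
        if p < p_threshold and abs(delta) > delta_threshold:
            call = "distal_up" if delta > 0 else "proximal_up"
        else:
            call = "not_significant"
        results.append(
            ApaTestResult(
                gene_id=str(gene_id),
                proximal_idx=prox_idx,
                distal_idx=dist_idx,
                counts=((pa_, pb), (da, db)),
                p_value=float(p),
                delta_abundance=float(delta),
                call=call,
            )
        )
    return results, skipped


def test_gene_expression(
    totals_a: Mapping[str, int],
    totals_b: Mapping[str, int],
    library_sizes: tuple[int, int] | None = None,
    p_threshold: float = DE_P_THRESHOLD,
    fold_threshold: float = DE_FOLD_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene differential expression by gene-vs-rest Fisher exact test.

    The 2x2 is (gene reads, other library reads) x condition. Fold change is
    the library-size-normalized B/A ratio (continuity +0.5 applied only for
    reporting when one side is zero, never inside the test). A gene is called
    when p < 0.01 and fold change > 1.5 in either direction.
    """
    genes = sorted(set(totals_a) | set(totals_b))
    if library_sizes is None:
        lib_a = sum(totals_a.values())
        lib_b = sum(totals_b.values())
    else:
        lib_a, lib_b = library_sizes
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    rows = []
    for g in genes:
        a = int(totals_a.get(g, 0))
        b = int(totals_b.get(g, 0))
        if a == 0 and b == 0:
            continue
        _, p = stats.fisher_exact([[a, b], [lib_a - a, lib_b - b]], alternative="two-sided")
        if a > 0 and b > 0:
            fold = (b / lib_b) / (a / lib_a)
        else:
            fold = ((b + 0.5) / lib_b) / ((a + 0.5) / lib_a)  # report-only continuity
        effect = max(fold, 1.0 / fold)
        called = p < p_threshold and effect > fold_threshold
        call = "up" if (called and fold > 1) else "down" if called else "not_significant"
        rows.append((g, a, b, fold, p, call))
    return pd.DataFrame(
        rows, columns=["gene_id", "count_a", "count_b", "fold_change", "p_value", "call"]
    )


def compute_rud(
    region_counts: Mapping[str, tuple[int, int]],
    region_lengths: Mapping[str, tuple[int, int]],
    min_cutr_reads: int = MIN_CUTR_READS_DEFAULT,
) -> tuple[list[RudRecord], float]:
    """RUD per gene and the sample's median RUD over qualifying genes.

    *region_counts* maps gene_id -> (cUTR reads, aUTR reads);
    *region_lengths* maps gene_id -> (cUTR nt, aUTR nt). A gene qualifies when
    its cUTR has at least *min_cutr_reads* reads; zero-length aUTRs are
    excluded. The median is over qualifying genes only (NaN if none).
    """
    records: list[RudRecord] = []
    for gene_id in sorted(region_counts):
        c_reads, a_reads = region_counts[gene_id]
        c_len, a_len = region_lengths[gene_id]
        if c_len <= 0:
            raise ValueError(f"{gene_id}: non-positive cUTR length")
        if a_len <= 0:
            continue  # no alternative UTR: RUD undefined for this gene
        c_density = c_reads / c_len
        a_density = a_reads / a_len
        qualifies = c_reads >= min_cutr_reads
        rud = a_density / c_density if c_density > 0 else math.nan
        records.append(
            RudRecord(
                gene_id=gene_id,
                cutr_density=c_density,
                autr_density=a_density,
                rud=rud,
                qualifies=qualifies,
            )
        )
    vals = [r.rud for r in records if r.qualifies and not math.isnan(r.rud)]
    median = float(np.median(vals)) if vals else math.nan
    return records, median


def utr_region_lengths(gene_model) -> tuple[int, int]:
    """(cUTR, aUTR) lengths from a gene model's 3'-most-exon pA partition.

    cUTR runs from the 3'-most exon's transcript start to the first pA
    (inclusive of the cleavage nucleotide); aUTR from there to the distal pA.
    """
    exon_lo, exon_hi = gene_model.three_prime_exon
    pas = [
        p
        for p in gene_model.pa_sites_tx_order()
        if exon_lo <= p.cleavage_pos < exon_hi
    ]
    if len(pas) < 2:
        raise ValueError(f"{gene_model.gene_id}: need >= 2 pAs in the 3'-most exon")
    first, distal = pas[0], pas[-1]
    if gene_model.strand == "+":
        cutr = first.cleavage_pos - exon_lo + 1
        autr = distal.cleavage_pos - first.cleavage_pos
    else:
        cutr = exon_hi - first.cleavage_pos
        autr = first.cleavage_pos - distal.cleavage_pos
    return cutr, autr


def isoform_ratio(
    short_count: float, long_count: float, short_region_len: float, long_region_len: float
) -> float:
    """Length-normalized short/long isoform expression ratio.

    Counts are divided by the lengths of the isoform-specific regions before
    taking the ratio. Zero long-isoform signal is undefined.
    """
    if short_region_len <= 0 or long_region_len <= 0:
        raise ValueError("region lengths must be positive")
    long_density = long_count / long_region_len
    if long_density == 0:
        raise ValueError("zero long-isoform signal: ratio undefined")
    return (short_count / short_region_len) / long_density


def correlate_ratio_vs_rud(
    ratios: Sequence[float], median_ruds: Sequence[float]
) -> dict[str, float]:
    """Pearson correlation of per-sample isoform ratios with median RUDs.

    Returns pearson_r, r_squared, and the least-squares line (slope,
    intercept). Requires >= 3 samples and non-degenerate variance.
    """
    x = np.asarray(ratios, dtype=float)
    y = np.asarray(median_ruds, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    r, _p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return {
        "pearson_r": float(r),
        "r_squared": float(r * r),
        "slope": float(slope),
        "intercept": float(intercept),
    }


def concordance_chi2(n_consistent: int, n_opposite: int) -> tuple[float, float]:
    """1-df goodness-of-fit chi-squared against a 50:50 split."""
    c, o = int(n_consistent), int(n_opposite)
    if c < 0 or o < 0 or c + o == 0:
        raise ValueError("need a positive total of concordant + opposite genes")
    e = (c + o) / 2.0
    chi2 = (c - e) ** 2 / e + (o - e) ** 2 / e
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def ks_geneset_shift(
    changes_in_set: Sequence[float], changes_in_rest: Sequence[float]
) -> dict[str, object]:
    """Two-sample Kolmogorov-Smirnov comparison of expression-change
    distributions between a gene set and the remaining genes.

    Returns D, the asymptotic p, and both empirical CDFs (sorted values and
    cumulative fractions) for plotting.
    """
    a = np.sort(np.asarray(changes_in_set, dtype=float))
    b = np.sort(np.asarray(changes_in_rest, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return {
        "D": float(res.statistic),
        "p": float(res.pvalue),
        "cdf_set": (a, np.arange(1, a.size + 1) / a.size),
        "cdf_rest": (b, np.arange(1, b.size + 1) / b.size),
    }
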