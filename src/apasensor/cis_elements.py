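"""Pentamer enrichment around poly(A) sites.

Flanking sequences are compared between two pA sets over four disjoint
windows in transcript coordinates around the cleavage site (offset 0):
-100..-41, -40..-1, +1..+40 and +41..+100. A sequence counts as containing a
k-mer only when at least one occurrence lies *fully* inside the window
(presence/absence, not occurrence counts). Each k-mer gets a one-sided Fisher
exact p for enrichment in set A over set B; results are ranked by p.
K-mers are matched in DNA space and reported in RNA (U for T).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from typing import Sequence

from scipy import stats

from .sequence_io import FlankSequence

__all__ = [
    "CANONICAL_REGIONS",
    "EnrichmentResult",
    "count_kmer_presence",
    "enrich_pentamers",
    "all_kmers",
    "to_rna",
    "to_dna",
]

CANONICAL_REGIONS: tuple[tuple[int, int], ...] = (
    (-100, -41),
    (-40, -1),
    (1, 40),
    (41, 100),
)


def to_rna(kmer: str) -> str:
    return kmer.upper().replace("T", "U")


def to_dna(kmer: str) -> str:
    return kmer.upper().replace("U", "T")


def all_kmers(k: int = 5) -> list[str]:
    return ["".join(p) for p in product("ACGT", repeat=k)]


@dataclass
class EnrichmentResult:
    kmer: str  # RNA alphabet
    region: tuple[int, int]
    a_with: int
    a_without: int
    b_with: int
    b_without: int
    p_value: float
    rank: int = 0


def _region_subseq(flank: FlankSequence, region: tuple[int, int]) -> str:
    return flank.region(region[0], region[1])


def _check_region(region: tuple[int, int], k: int, custom_region: bool) -> None:
    lo, hi = region
    if not custom_region and region not in CANONICAL_REGIONS:
        raise ValueError(
            f"region {region} is not one of the canonical windows {CANONICAL_REGIONS}; "
            "pass custom_region=True to override"
        )
    if hi - lo + 1 < k:
        raise ValueError(f"k-mer of length {k} cannot fit inside region {region}")


def count_kmer_presence(
    flanks: Sequence[FlankSequence],
    kmer: str,
    region: tuple[int, int],
    custom_region: bool = False,
) -> tuple[int, int]:
    """(n_with, n_without): sequences with >= 1 fully-contained occurrence.

    Full containment means all k positions of the occurrence have offsets
    inside [lo, hi]; occurrences straddling a window boundary count for no
    window.
    """
    kd = to_dna(kmer)
    _check_region(region, len(kd), custom_region)
    n_with = 0
    for f in flanks:
        if kd in _region_subseq(f, region):
            n_with += 1
    return n_with, len(flanks) - n_with


@lru_cache(maxsize=200_000)
def _fisher_greater(a_with: int, a_without: int, b_with: int, b_without: int) -> float:
    _, p = stats.fisher_exact([[a_with, b_with], [a_without, b_without]], alternative="greater")
    return float(p)


def enrich_pentamers(
    set_a_flanks: Sequence[FlankSequence],
    set_b_flanks: Sequence[FlankSequence],
    region: tuple[int, int],
    k: int = 5,
    custom_region: bool = False,
) -> list[EnrichmentResult]:
    """Rank all 4^k k-mers by one-sided (greater-in-A) Fisher exact p.

    Sorted ascending by p; ties broken by descending a_with, then by k-mer.
    """
    if not set_a_flanks or not set_b_flanks:
        raise ValueError("both flank sets must be non-empty")
    _check_region(region, k, custom_region)
    # one pass per set: collect the k-mer presence sets per sequence
    counts_a: dict[str, int] = {}
    counts_b: dict[str, int] = {}
    for flanks, counts in ((set_a_flanks, counts_a), (set_b_flanks, counts_b)):
        for f in flanks:
            sub = _region_subseq(f, region)
            seen = {sub[i : i + k] for i in range(len(sub) - k + 1)}
            for km in seen:
                counts[km] = counts.get(km, 0) + 1
    n_a, n_b = len(set_a_flanks), len(set_b_flanks)
    results = []
    for km in all_kmers(k):
        aw = counts_a.get(km, 0)
        bw = counts_b.get(km, 0)
        p = _fisher_greater(aw, n_a - aw, bw, n_b - bw)
        results.append(
            EnrichmentResult(
                kmer=to_rna(km),
                region=region,
                a_with=aw,
                a_without=n_a - aw,
                b_with=bw,
                b_without=n_b - bw,
                p_value=p,
            )
        )
    results.sort(key=lambda r: (r.p_value, -r.a_with, r.kmer))
    for i, r in enumerate(results):
        r.rank = i + 1
    return results
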