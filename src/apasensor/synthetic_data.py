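"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator emulates one class of input the analyses consume:

* intron populations with parameterized (log-normal) size and (normal)
  splice-site-score distributions, coupled through a Gaussian copula with a
  chosen correlation — the input of the observed/expected density map;
* two-condition 3'-end read sets over two-pA genes with an abundance shift
  planted in a chosen gene subset, PASS-like poly(A) tails and non-PASS
  decoys — the input of quantification and the APA test;
* pA flanking sequences with a pentamer planted at different rates in two
  sets — the input of cis-element enrichment;
* CLIP reads with deletion-marked cross-link positions at differing
  densities around two pA sets — the input of the binding comparison;
* per-gene cUTR/aUTR read counts with a planted global-lengthening parameter
  — the input of the RUD statistic.

Every generator is fully determined by its seed (one root seed, a named
stream per output) and returns a :class:`SyntheticTruth` sidecar whose ids
resolve against the emitted annotations.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .sequence_io import FlankSequence, GeneModel, GenomeSequence, PolyASite
from .clip_binding import ClipRecord
from .pa_quant import AlignedRead3p

__all__ = [
    "SyntheticTruth",
    "ApaExperiment",
    "generate_intron_population",
    "generate_apa_experiment",
    "generate_flank_sets",
    "generate_clip_reads",
    "generate_rud_cohort",
    "make_pa_sets",
    "stream_rng",
]


def stream_rng(seed: int, name: str) -> np.random.Generator:
    """A named, order-independent random stream derived from one root seed."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


@dataclass
class SyntheticTruth:
    """Ground-truth sidecar: what was planted, under which seed.

    ``extras`` carries generator-specific records (e.g. per-gene planted PASS
    counts) that downstream truth-comparisons consume.
    """

    seed: int
    regulated_gene_ids: set[str] = field(default_factory=set)
    delta_abundance: float = 0.0
    planted_pentamer: str = ""
    planted_region: tuple[int, int] | None = None
    binding_rate_up: float = 0.0
    binding_rate_dn: float = 0.0
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["regulated_gene_ids"] = sorted(self.regulated_gene_ids)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True, default=str)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            doc = json.load(fh)
        doc["regulated_gene_ids"] = set(doc["regulated_gene_ids"])
        if doc.get("planted_region") is not None:
            doc["planted_region"] = tuple(doc["planted_region"])
        return cls(**doc)


# ---------------------------------------------------------------------------
# Intron populations


def generate_intron_population(
    n: int,
    size_dist_params: tuple[float, float] = (7.3, 1.2),  # log-nt mean, sd
    score_dist_params: tuple[float, float] = (8.0, 2.0),
    dependence: float = 0.0,
    seed: int = 0,
) -> list[tuple[int, float, float]]:
    """(intron_size, 5'SS score, 3'SS score) triples.

    Sizes are log-normal (rounded, floor 1 nt); scores normal. *dependence*
    is the Gaussian-copula correlation between log-size and the 5'SS score:
    0 makes them independent, 1 couples their ranks perfectly. The 3'SS score
    is an independent draw from the same score distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not -1.0 <= dependence <= 1.0:
        raise ValueError(f"dependence must be in [-1, 1], got {dependence}")
    mu, sigma = size_dist_params
    s_mean, s_sd = score_dist_params
    rng = stream_rng(seed, "intron_population")
    z_size = rng.standard_normal(n)
    z_indep = rng.standard_normal(n)
    rho = float(dependence)
    z_score = rho * z_size + np.sqrt(max(0.0, 1.0 - rho * rho)) * z_indep
    sizes = np.maximum(1, np.rint(np.exp(mu + sigma * z_size))).astype(int)
    fivess = s_mean + s_sd * z_score
    threess = s_mean + s_sd * rng.standard_normal(n)
    return [(int(s), float(f), float(t)) for s, f, t in zip(sizes, fivess, threess)]


# ---------------------------------------------------------------------------
# Two-condition 3'-end read experiment


@dataclass
class ApaExperiment:
    """A two-condition 3'READS-style experiment over two-pA genes."""

    genes: list[GeneModel]
    pa_sites: list[PolyASite]
    reads_a: list[AlignedRead3p]
    reads_b: list[AlignedRead3p]
    truth: SyntheticTruth


_GENE_SPACING = 3000
_GENE_LEN = 2300
_PROX_OFFSET = 1499  # proximal cleavage position within the gene
_DIST_OFFSET = 2299  # distal cleavage position (last gene nt)
_CHROM = "chrSim"


def _make_apa_genes(n_genes: int) -> tuple[list[GeneModel], list[PolyASite]]:
    genes, sites = [], []
    for i in range(n_genes):
        gid = f"gene{i:04d}"
        start = 100 + i * _GENE_SPACING
        prox = PolyASite(_CHROM, "+", start + _PROX_OFFSET, gene_id=gid, label="proximal")
        dist = PolyASite(_CHROM, "+", start + _DIST_OFFSET, gene_id=gid, label="distal")
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=_CHROM,
                strand="+",
                exons=[(start, start + _GENE_LEN)],
                pa_sites=[prox, dist],
            )
        )
        sites.extend([prox, dist])
    return genes, sites


def generate_apa_experiment(
    n_genes: int,
    n_regulated: int,
    delta_abundance: float,
    depth_per_gene: int,
    pass_tail_model: tuple[int, int] = (3, 10),
    proximal_fraction: float = 0.5,
    decoy_fraction: float = 0.1,
    jitter: int = 2,
    seed: int = 0,
) -> ApaExperiment:
    """Plant an APA shift in *n_regulated* of *n_genes* two-pA genes.

    Every gene has a proximal and a distal pA in its single (3'-most) exon.
    In condition A each read is proximal with probability *proximal_fraction*;
    in condition B regulated genes use *proximal_fraction* + *delta_abundance*
    while unregulated genes are unchanged. Reads carry non-genomic T counts
    drawn uniformly on *pass_tail_model* = (min_T, max_T); a *decoy_fraction*
    of reads instead carries 0-2 Ts (non-PASS). 3'-end positions jitter
    uniformly within +/- *jitter* nt of the cleavage site.

    The truth sidecar records the regulated gene ids and, in ``extras``,
    the planted per-gene per-condition PASS counts of each isoform.
    """
    if not 0 < delta_abundance < 1:
        raise ValueError("delta_abundance must be in (0, 1)")
    if n_regulated > n_genes:
        raise ValueError("n_regulated cannot exceed n_genes")
    if depth_per_gene < 1:
        raise ValueError("depth_per_gene must be >= 1")
    if not 0 <= decoy_fraction < 1:
        raise ValueError("decoy_fraction must be in [0, 1)")
    min_t, max_t = pass_tail_model
    if min_t <= 2 or max_t < min_t:
        raise ValueError("pass_tail_model must satisfy 2 < min_T <= max_T")
    shifted = proximal_fraction + delta_abundance
    if not 0 <= shifted <= 1 or not 0 <= proximal_fraction <= 1:
        raise ValueError(
            f"delta pushes the proximal fraction to {shifted}, outside [0, 1]"
        )

    genes, sites = _make_apa_genes(n_genes)
    rng = stream_rng(seed, "apa_experiment")
    regulated = set(
        f"gene{i:04d}" for i in rng.choice(n_genes, size=n_regulated, replace=False)
    )

    truth_counts: dict[str, dict[str, list[int]]] = {}
    reads: dict[str, list[AlignedRead3p]] = {"condA": [], "condB": []}
    for gene in genes:
        prox_pa, dist_pa = gene.pa_sites
        counts = {"condA": [0, 0], "condB": [0, 0]}
        for sample, p_prox in (
            ("condA", proximal_fraction),
            (
                "condB",
                shifted if gene.gene_id in regulated else proximal_fraction,
            ),
        ):
            is_prox = rng.random(depth_per_gene) < p_prox
            is_decoy = rng.random(depth_per_gene) < decoy_fraction
            jit = rng.integers(-jitter, jitter + 1, size=depth_per_gene)
            t_pass = rng.integers(min_t, max_t + 1, size=depth_per_gene)
            t_decoy = rng.integers(0, 3, size=depth_per_gene)
            for k in range(depth_per_gene):
                pa = prox_pa if is_prox[k] else dist_pa
                n_t = int(t_decoy[k] if is_decoy[k] else t_pass[k])
                reads[sample].append(
                    AlignedRead3p(
                        read_id=f"{gene.gene_id}.{sample}.r{k}",
                        chrom=gene.chrom,
                        strand=gene.strand,
                        mapped_3p_pos=int(pa.cleavage_pos + jit[k]),
                        nongenomic_T=n_t,
                        sample_id=sample,
                    )
                )
                if n_t > 2:
                    counts[sample][0 if is_prox[k] else 1] += 1
        truth_counts[gene.gene_id] = counts

    truth = SyntheticTruth(
        seed=seed,
        regulated_gene_ids=regulated,
        delta_abundance=delta_abundance,
        extras={
            "proximal_fraction": proximal_fraction,
            "decoy_fraction": decoy_fraction,
            "pass_isoform_counts": truth_counts,
            "samples": ["condA", "condB"],
        },
    )
    return ApaExperiment(
        genes=genes,
        pa_sites=sites,
        reads_a=reads["condA"],
        reads_b=reads["condB"],
        truth=truth,
    )


def synthetic_genome_for(genes: Sequence[GeneModel], seed: int = 0) -> GenomeSequence:
    """Random uniform-base chromosomes covering the given gene models."""
    rng = stream_rng(seed, "genome")
    lengths: dict[str, int] = {}
    for g in genes:
        lengths[g.chrom] = max(lengths.get(g.chrom, 0), g.span[1] + 100)
    return GenomeSequence(
        {
            chrom: "".join(rng.choice(list("ACGT"), size=n))
            for chrom, n in sorted(lengths.items())
        }
    )


# ---------------------------------------------------------------------------
# pA flank sets with a planted pentamer


def generate_flank_sets(
    n_a: int,
    n_b: int,
    planted_pentamer: str = "TGTGT",
    rate_a: float = 0.6,
    rate_b: float = 0.1,
    region: tuple[int, int] = (-40, -1),
    flank_len: int = 100,
    seed: int = 0,
) -> tuple[list[FlankSequence], list[FlankSequence], SyntheticTruth]:
    """Two sets of pA flanks (-flank_len..+flank_len, offset 0 = cleavage).

    Background is i.i.d. uniform over {A,C,G,T}; with probability rate_x a
    sequence gets the planted pentamer written at a uniform position fully
    inside *region*. U in the pentamer is accepted and mapped to T.
    """
    pent = planted_pentamer.upper().replace("U", "T")
    if any(b not in "ACGT" for b in pent):
        raise ValueError(f"invalid pentamer {planted_pentamer!r}")
    lo, hi = region
    if hi - lo + 1 < len(pent):
        raise ValueError(f"pentamer longer than region {region}")
    if not (0 <= rate_a <= 1 and 0 <= rate_b <= 1):
        raise ValueError("rates must be in [0, 1]")
    if not (-flank_len <= lo <= hi <= flank_len):
        raise ValueError("region outside the flank window")

    def make_set(name: str, n: int, rate: float) -> list[FlankSequence]:
        rng = stream_rng(seed, f"flanks_{name}")
        out = []
        offsets = np.arange(-flank_len, flank_len + 1)
        for i in range(n):
            chars = rng.choice(list("ACGT"), size=2 * flank_len + 1)
            if rng.random() < rate:
                start_off = int(rng.integers(lo, hi - len(pent) + 2))
                idx = start_off + flank_len
                chars[idx : idx + len(pent)] = list(pent)
            site = PolyASite(
                chrom=f"synthetic_{name}",
                strand="+",
                cleavage_pos=flank_len + i * (2 * flank_len + 2),
                gene_id=f"{name}{i:04d}",
                label="",
            )
            out.append(
                FlankSequence(
                    site=site,
                    seq="".join(chars),
                    offsets=offsets.copy(),
                    mask=np.zeros(offsets.size, dtype=bool),
                )
            )
        return out

    set_a = make_set("A", n_a, rate_a)
    set_b = make_set("B", n_b, rate_b)
    truth = SyntheticTruth(
        seed=seed,
        planted_pentamer=pent,
        planted_region=region,
        extras={"rate_a": rate_a, "rate_b": rate_b, "n_a": n_a, "n_b": n_b},
    )
    return set_a, set_b, truth


# ---------------------------------------------------------------------------
# CLIP reads around two pA sets


def make_pa_sets(
    n_up: int, n_dn: int, spacing: int = 1000, chrom: str = "chrClip"
) -> tuple[list[PolyASite], list[PolyASite]]:
    """Deterministic, well-separated synthetic pA sets on one chromosome."""
    up = [
        PolyASite(chrom, "+", 500 + i * spacing, gene_id=f"up{i:04d}", label="up")
        for i in range(n_up)
    ]
    dn = [
        PolyASite(
            chrom, "+", 500 + (n_up + i) * spacing, gene_id=f"dn{i:04d}", label="dn"
        )
        for i in range(n_dn)
    ]
    return up, dn


def uniform_profile(lo: int = -100, hi: int = 100) -> np.ndarray:
    n = hi - lo + 1
    return np.full(n, 1.0 / n)


def concentrated_profile(
    lo: int = -100, hi: int = 100, core: tuple[int, int] = (-10, 40)
) -> np.ndarray:
    """A positional profile with all mass uniform over *core*."""
    p = np.zeros(hi - lo + 1)
    c_lo, c_hi = core
    p[c_lo - lo : c_hi - lo + 1] = 1.0
    return p / p.sum()


def generate_clip_reads(
    pa_set_up: Sequence[PolyASite],
    pa_set_dn: Sequence[PolyASite],
    rate_up: float,
    rate_dn: float,
    positional_profile: np.ndarray | None = None,
    nondeletion_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[list[ClipRecord], SyntheticTruth]:
    """Deletion-marked CLIP reads around two pA sets.

    Per pA the read count is Poisson(rate); each read's cross-link offset
    (transcript-oriented, -100..+100) is drawn from *positional_profile*.
    A *nondeletion_fraction* of additional reads carries no deletion (they
    are dropped by the cross-link filter). Returns one record pool plus the
    truth sidecar.
    """
    if rate_up < 0 or rate_dn < 0:
        raise ValueError("rates must be >= 0")
    profile = uniform_profile() if positional_profile is None else np.asarray(positional_profile)
    if abs(float(profile.sum()) - 1.0) > 1e-9:
        raise ValueError("positional_profile must sum to 1 within 1e-9")
    half = (profile.size - 1) // 2
    if profile.size != 2 * half + 1:
        raise ValueError("positional_profile must have odd length (offsets -h..+h)")
    rng = stream_rng(seed, "clip_reads")
    offsets_domain = np.arange(-half, half + 1)

    records: list[ClipRecord] = []
    for label, pa_set, rate in (("up", pa_set_up, rate_up), ("dn", pa_set_dn, rate_dn)):
        for j, pa in enumerate(pa_set):
            n_reads = int(rng.poisson(rate))
            if n_reads == 0:
                continue
            offs = rng.choice(offsets_domain, size=n_reads, p=profile)
            for k, off in enumerate(offs):
                g_pos = pa.cleavage_pos + (int(off) if pa.strand == "+" else -int(off))
                records.append(
                    ClipRecord(
                        read_id=f"{label}{j:04d}.r{k}",
                        chrom=pa.chrom,
                        strand=pa.strand,
                        crosslink_pos=g_pos,
                        has_deletion=True,
                    )
                )
    n_del = len(records)
    if nondeletion_fraction > 0 and n_del > 0:
        n_extra = int(rng.poisson(n_del * nondeletion_fraction / (1 - nondeletion_fraction)))
        all_pas = list(pa_set_up) + list(pa_set_dn)
        for k in range(n_extra):
            pa = all_pas[int(rng.integers(0, len(all_pas)))]
            off = int(rng.integers(-half, half + 1))
            records.append(
                ClipRecord(
                    read_id=f"nodel.r{k}",
                    chrom=pa.chrom,
                    strand=pa.strand,
                    crosslink_pos=pa.cleavage_pos + off,
                    has_deletion=False,
                )
            )
    truth = SyntheticTruth(
        seed=seed,
        binding_rate_up=rate_up,
        binding_rate_dn=rate_dn,
        extras={
            "n_deletion_reads": n_del,
            "n_records": len(records),
            "profile_half_window": half,
        },
    )
    return records, truth


# ---------------------------------------------------------------------------
# RUD cohort with a planted global-lengthening parameter


def generate_rud_cohort(
    n_genes: int,
    lengthening: float,
    depth: float = 50.0,
    seed: int = 0,
) -> tuple[dict[str, tuple[int, int]], dict[str, tuple[int, int]], SyntheticTruth]:
    """Per-gene (cUTR, aUTR) read counts with aUTR/cUTR density ratio
    *lengthening* in expectation.

    cUTR lengths are uniform 300-800 nt, aUTR lengths uniform 500-1500 nt;
    cUTR counts are Poisson(depth), aUTR counts Poisson(depth * lengthening *
    aUTR_len / cUTR_len), so each gene's expected RUD equals *lengthening*.
    Returns (region_counts, region_lengths, truth) ready for compute_rud.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if lengthening < 0:
        raise ValueError("lengthening must be >= 0")
    rng = stream_rng(seed, "rud_cohort")
    counts: dict[str, tuple[int, int]] = {}
    lengths: dict[str, tuple[int, int]] = {}
    for i in range(n_genes):
        gid = f"rgene{i:04d}"
        c_len = int(rng.integers(300, 801))
        a_len = int(rng.integers(500, 1501))
        c_reads = int(rng.poisson(depth))
        a_reads = int(rng.poisson(depth * lengthening * a_len / c_len))
        counts[gid] = (c_reads, a_reads)
        lengths[gid] = (c_len, a_len)
    truth = SyntheticTruth(seed=seed, extras={"lengthening": lengthening, "depth": depth})
    return counts, lengths, truth
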