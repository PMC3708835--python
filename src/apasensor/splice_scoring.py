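"""Splice-site strength scoring.

Donor (5'SS) sites are modeled over a 9-nt window, -3..+6 around the
exon/intron boundary (3 exonic + 6 intronic nt); acceptor (3'SS) sites over a
25-nt window, -22..+2 (22 intronic + 2 exonic nt). A position-specific scoring
matrix (PSSM) gives log2-odds scores against a background model; scores are
ranked as the percent of a reference score set that is strictly lower.

A second donor-strength measure is the free energy of the gap-free antiparallel
duplex between the 9-nt donor window (read as RNA) and the 5' end of U1 snRNA
(5'-ACUUACCUG-3'), summing nearest-neighbor stack terms over consecutive paired
positions. Watson-Crick and G·U wobble pairs pair; anything else breaks the
stack. More negative means stronger annealing. The stack table uses
Turner-style Watson-Crick values with a flat weak value for wobble-containing
stacks; the contract is ordering (perfect complement is minimal, lost pairs
monotonically weaken), not equivalence to a full folding model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import GeneModel, GenomeSequence, reverse_complement

__all__ = [
    "WindowSpec",
    "FIVE_SS_WINDOW",
    "THREE_SS_WINDOW",
    "Pssm",
    "build_pssm",
    "score_sequence",
    "percentile_rank",
    "u1_duplex_energy",
    "extract_splice_windows",
    "SpliceSiteScore",
    "U1_5P_SEQUENCE",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class WindowSpec:
    label: str  # "5SS" or "3SS"
    exonic_nt: int
    intronic_nt: int

    @property
    def length(self) -> int:
        return self.exonic_nt + self.intronic_nt


FIVE_SS_WINDOW = WindowSpec(label="5SS", exonic_nt=3, intronic_nt=6)  # -3..+6
THREE_SS_WINDOW = WindowSpec(label="3SS", exonic_nt=2, intronic_nt=22)  # -22..+2


def _encode(seq: str, where: str = "sequence") -> np.ndarray:
    s = seq.upper().replace("U", "T")
    try:
        return np.array([_BASE_INDEX[b] for b in s], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"{where}: non-ACGT character {exc.args[0]!r}") from None


@dataclass
class Pssm:
    """Per-position nucleotide probabilities over a fixed window.

    ``matrix`` is L x 4 (columns A, C, G, T), each row summing to 1;
    ``background`` is a length-4 probability vector.
    """

    window_spec: WindowSpec
    matrix: np.ndarray
    background: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape != (self.window_spec.length, 4):
            raise ValueError(
                f"matrix shape {self.matrix.shape} != ({self.window_spec.length}, 4)"
            )
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PSSM rows must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Pssm)
            and self.window_spec == other.window_spec
            and np.array_equal(self.matrix, other.matrix)
            and np.array_equal(self.background, other.background)
            and self.pseudocount == other.pseudocount
        )


def build_pssm(
    aligned_windows: Sequence[str],
    window_spec: WindowSpec,
    pseudocount: float = 0.25,
    background: Sequence[float] | None = None,
) -> Pssm:
    """Estimate a PSSM from aligned fixed-length windows.

    matrix[i, b] = (count(b at i) + pseudocount) / (n + 4 * pseudocount).
    Background defaults to the pooled base frequencies across all positions of
    the training windows; pass ``background=[0.25]*4`` for a uniform null.
    """
    if len(aligned_windows) == 0:
        raise ValueError("need at least one training window")
    L = window_spec.length
    counts = np.zeros((L, 4), dtype=float)
    for idx, w in enumerate(aligned_windows):
        if len(w) != L:
            raise ValueError(f"window {idx}: length {len(w)} != {L}")
        enc = _encode(w, where=f"window {idx}")
        counts[np.arange(L), enc] += 1.0
    n = len(aligned_windows)
    matrix = (counts + pseudocount) / (n + 4.0 * pseudocount)
    if background is None:
        pooled = counts.sum(axis=0)
        bg = pooled / pooled.sum()
        if (bg == 0).any():
            # avoid log(0) backgrounds on tiny training sets
            bg = (pooled + pseudocount) / (pooled.sum() + 4.0 * pseudocount)
    else:
        bg = np.asarray(background, dtype=float)
    return Pssm(window_spec=window_spec, matrix=matrix, background=bg, pseudocount=pseudocount)


def score_sequence(pssm: Pssm, seq: str) -> float:
    """Log2-odds score sum_i log2(matrix[i, seq_i] / background[seq_i]).

    A zero-probability cell (possible only with pseudocount 0) yields -inf,
    with a warning.
    """
    enc = _encode(seq)
    if enc.size != pssm.window_spec.length:
        raise ValueError(
            f"sequence length {enc.size} != window length {pssm.window_spec.length}"
        )
    p = pssm.matrix[np.arange(enc.size), enc]
    q = pssm.background[enc]
    if (p == 0).any():
        warnings.warn("zero-probability PSSM cell; score is -inf", RuntimeWarning)
        return float("-inf")
    return float(np.log2(p / q).sum())


def percentile_rank(score: float, reference_scores: Sequence[float]) -> float:
    """Percent of reference scores strictly lower than *score* (0..100)."""
    ref = np.asarray(reference_scores, dtype=float)
    if ref.size == 0:
        raise ValueError("reference score set is empty")
    return 100.0 * float((ref < score).sum()) / ref.size


# ---------------------------------------------------------------------------
# U1 duplex energy

U1_5P_SEQUENCE = "ACUUACCUG"  # 5'->3'; pairs antiparallel with the donor window

# Watson-Crick nearest-neighbor stack free energies (kcal/mol, 37 C),
# Turner-style values, keyed by the two 5'SS-strand bases of the stack
# (RNA alphabet, 5'->3') given that both positions form Watson-Crick pairs
# with U1. A stack in which either pair is a G·U wobble gets WOBBLE_STACK_DG.
_WC_STACK_DG = {
    ("A", "A"): -0.93,
    ("A", "C"): -2.24,
    ("A", "G"): -2.08,
    ("A", "U"): -1.10,
    ("C", "A"): -2.11,
    ("C", "C"): -3.26,
    ("C", "G"): -2.36,
    ("C", "U"): -2.08,
    ("G", "A"): -2.35,
    ("G", "C"): -3.42,
    ("G", "G"): -3.26,
    ("G", "U"): -2.24,
    ("U", "A"): -1.33,
    ("U", "C"): -2.35,
    ("U", "G"): -2.11,
    ("U", "U"): -0.93,
}
WOBBLE_STACK_DG = -0.5  # flat, weaker than the weakest Watson-Crick stack

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def u1_duplex_energy(fivess_window: str) -> float:
    """Free energy (kcal/mol) of the gap-free 5'SS:U1 antiparallel duplex.

    Position i of the 9-nt donor window pairs with position 8-i of
    5'-ACUUACCUG-3'. Consecutive paired positions contribute one
    nearest-neighbor stack; an unpairable position contributes nothing and
    breaks the stacks on both sides. T and U are interchangeable on input.
    """
    s = fivess_window.upper().replace("T", "U")
    if len(s) != len(U1_5P_SEQUENCE):
        raise ValueError(f"donor window must be {len(U1_5P_SEQUENCE)} nt, got {len(s)}")
    if any(b not in "ACGU" for b in s):
        raise ValueError(f"invalid alphabet in {fivess_window!r}")
    partner = U1_5P_SEQUENCE[::-1]  # partner[i] pairs with s[i]
    kind = []  # 0 unpaired, 1 WC, 2 wobble
    for a, b in zip(s, partner):
        if (a, b) in _WC:
            kind.append(1)
        elif (a, b) in _WOBBLE:
            kind.append(2)
        else:
            kind.append(0)
    dg = 0.0
    for i in range(len(s) - 1):
        if kind[i] and kind[i + 1]:
            if kind[i] == 1 and kind[i + 1] == 1:
                dg += _WC_STACK_DG[(s[i], s[i + 1])]
            else:
                dg += WOBBLE_STACK_DG
    return dg


# ---------------------------------------------------------------------------
# Window extraction from gene models


def extract_splice_windows(
    gene_models: Iterable[GeneModel],
    genome: GenomeSequence,
    min_intron_length: int = 28,
    gt_ag_only: bool = True,
) -> tuple[list[dict], list[str]]:
    """Per-intron donor/acceptor windows, transcript-oriented.

    Returns (records, skipped): each record has intron_id, gene_id,
    intron_length, fivess_window (last 3 exonic + first 6 intronic nt) and
    threess_window (last 22 intronic + first 2 exonic nt). Introns shorter
    than *min_intron_length* (windows would overlap) are skipped with a
    reason; with *gt_ag_only*, non-GT..AG introns are skipped too.
    """
    records: list[dict] = []
    skipped: list[str] = []
    for gene in gene_models:
        exons_tx = gene.exons_tx_order
        for k, (i_start, i_end) in enumerate(gene.introns):
            intron_id = f"{gene.gene_id}.intron{k + 1}"
            length = i_end - i_start
            if length < min_intron_length:
                skipped.append(f"{intron_id}: intron length {length} < {min_intron_length}")
                continue
            up_exon = exons_tx[k]
            dn_exon = exons_tx[k + 1]
            if gene.strand == "+":
                five = genome.fetch(gene.chrom, up_exon[1] - 3, up_exon[1]) + genome.fetch(
                    gene.chrom, i_start, i_start + 6
                )
                three = genome.fetch(gene.chrom, i_end - 22, i_end) + genome.fetch(
                    gene.chrom, dn_exon[0], dn_exon[0] + 2
                )
                intron_seq_ends = (
                    genome.fetch(gene.chrom, i_start, i_start + 2),
                    genome.fetch(gene.chrom, i_end - 2, i_end),
                )
            else:
                # tx orientation runs genome-right to genome-left: the upstream
                # exon sits at higher coordinates, windows are revcomped.
                five = reverse_complement(
                    genome.fetch(gene.chrom, i_end - 6, up_exon[0] + 3)
                )
                three = reverse_complement(
                    genome.fetch(gene.chrom, dn_exon[1] - 2, i_start + 22)
                )
                intron_seq_ends = (
                    reverse_complement(genome.fetch(gene.chrom, i_end - 2, i_end)),
                    reverse_complement(genome.fetch(gene.chrom, i_start, i_start + 2)),
                )
            if gt_ag_only and (intron_seq_ends[0] != "GT" or intron_seq_ends[1] != "AG"):
                skipped.append(
                    f"{intron_id}: non-GT..AG boundaries {intron_seq_ends[0]}..{intron_seq_ends[1]}"
                )
                continue
            records.append(
                {
                    "intron_id": intron_id,
                    "gene_id": gene.gene_id,
                    "intron_length": length,
                    "fivess_window": five,
                    "threess_window": three,
                }
            )
    return records, skipped


@dataclass
class SpliceSiteScore:
    intron_id: str
    fivess_score: float
    threess_score: float
    fivess_percentile: float
    threess_percentile: float
    duplex_dG: float
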