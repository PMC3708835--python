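"""PSSM construction/scoring, percentile ranking, U1 duplex energy, windows."""

import itertools
import math

import numpy as np
import pytest

from apasensor.sequence_io import GeneModel, GenomeSequence, reverse_complement
from apasensor.splice_scoring import (
    FIVE_SS_WINDOW,
    THREE_SS_WINDOW,
    U1_5P_SEQUENCE,
    WindowSpec,
    build_pssm,
    extract_splice_windows,
    percentile_rank,
    score_sequence,
    u1_duplex_energy,
)

TOY = WindowSpec(label="5SS", exonic_nt=1, intronic_nt=1)  # L = 2


def toy_pssm():
    return build_pssm(["AC", "AC", "AG", "AT"], TOY, pseudocount=0.0,
                      background=[0.25] * 4)


class TestBuildPssm:
    def test_hand_counted_frequencies(self):
        p = toy_pssm()
        assert np.allclose(p.matrix[0], [1.0, 0.0, 0.0, 0.0])
        assert np.allclose(p.matrix[1], [0.0, 0.5, 0.25, 0.25])

    def test_pseudocount_formula_single_window(self):
        p = build_pssm(["AA"], TOY, pseudocount=0.25)
        # (1 + 0.25) / (1 + 4*0.25) = 0.625 for A; 0.25/2 = 0.125 for others
        assert np.allclose(p.matrix, [[0.625, 0.125, 0.125, 0.125]] * 2)

    def test_order_invariance(self):
        a = build_pssm(["AC", "AG", "AT", "AC"], TOY, pseudocount=0.25)
        b = build_pssm(["AT", "AC", "AC", "AG"], TOY, pseudocount=0.25)
        assert a == b

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError, match="length"):
            build_pssm(["ACG"], TOY)
        with pytest.raises(ValueError, match="window 1"):
            build_pssm(["AC", "AX"], TOY)
        with pytest.raises(ValueError, match="at least one"):
            build_pssm([], TOY)

    def test_sampling_recovers_matrix(self):
        """A PSSM rebuilt from 100k sequences sampled from itself matches within 0.01."""
        rng = np.random.default_rng(0)
        spec = WindowSpec("5SS", 3, 6)
        target = rng.dirichlet(np.ones(4), size=spec.length)
        draws = np.stack(
            [rng.choice(4, size=100_000, p=row) for row in target], axis=1
        )
        seqs = ["".join("ACGT"[b] for b in row) for row in draws]
        rebuilt = build_pssm(seqs, spec, pseudocount=0.25)
        assert np.abs(rebuilt.matrix - target).max() < 0.01


class TestScoreSequence:
    def test_hand_arithmetic(self):
        # uniform background: log2(1/.25) + log2(.5/.25) = 2 + 1 = 3
        assert score_sequence(toy_pssm(), "AC") == pytest.approx(3.0)

    def test_consensus_maximal_exhaustive_toy(self):
        # uniform background: the per-position argmax sequence maximizes the score
        p = build_pssm(["AC", "AC", "AG", "AT"], TOY, pseudocount=0.25,
                       background=[0.25] * 4)
        scores = {s: score_sequence(p, s) for s in
                  ("".join(t) for t in itertools.product("ACGT", repeat=2))}
        assert max(scores, key=scores.get) == p.consensus

    def test_uniform_matrix_scores_zero(self):
        p = build_pssm(
            ["AA", "CC", "GG", "TT"], TOY, pseudocount=0.0, background=[0.25] * 4
        )
        for s in ("AC", "GT", "TA"):
            assert score_sequence(p, s) == pytest.approx(0.0)

    def test_zero_cell_gives_minus_inf_with_warning(self):
        p = toy_pssm()
        with pytest.warns(RuntimeWarning):
            assert score_sequence(p, "CC") == -math.inf

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        """Implementation equals the explicit per-position log-ratio sum, 1e-12."""
        rng = np.random.default_rng(0)
        spec = WindowSpec("5SS", 3, 6)
        train = ["".join(rng.choice(list("ACGT"), size=spec.length)) for _ in range(50)]
        pssm = build_pssm(train, spec, pseudocount=0.25)
        for _ in range(1000):
            seq = "".join(rng.choice(list("ACGT"), size=spec.length))
            expected = sum(
                math.log2(
                    pssm.matrix[i]["ACGT".index(b)] / pssm.background["ACGT".index(b)]
                )
                for i, b in enumerate(seq)
            )
            assert score_sequence(pssm, seq) == pytest.approx(expected, abs=1e-12)


class TestPercentileRank:
    def test_strict_rule_and_boundaries(self):
        ref = [1, 2, 3, 4]
        assert percentile_rank(3, ref) == 50.0
        assert percentile_rank(0, ref) == 0.0
        assert percentile_rank(9, ref) == 100.0
        assert percentile_rank(2, [2, 2, 2]) == 0.0  # ties: strict inequality

    def test_members_in_half_open_range_and_monotone(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(size=500)
        pct = [percentile_rank(x, ref) for x in sorted(ref)]
        assert all(0 <= p < 100 for p in pct)
        assert pct == sorted(pct)

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            percentile_rank(1.0, [])


class TestU1DuplexEnergy:
    PERFECT = "CAGGUAAGU"

    def test_perfect_complement_minimal_by_brute_force(self):
        """The full complement of ACUUACCUG beats all 4^9 donor 9-mers."""
        e_perfect = u1_duplex_energy(self.PERFECT)
        best = min(
            u1_duplex_energy("".join(t))
            for t in itertools.product("ACGU", repeat=9)
        )
        assert e_perfect == best
        assert e_perfect < 0

    def test_every_single_mismatch_strictly_weaker(self):
        e_perfect = u1_duplex_energy(self.PERFECT)
        for i in range(9):
            for b in "ACGU":
                if b == self.PERFECT[i]:
                    continue
                mut = self.PERFECT[:i] + b + self.PERFECT[i + 1 :]
                assert u1_duplex_energy(mut) > e_perfect

    def test_no_pairable_positions_is_zero(self):
        # complement of perfect at every position pairs nowhere (A<->C style swaps)
        seq = "".join({"C": "A", "A": "C", "G": "A", "U": "C"}[b] for b in self.PERFECT)
        assert u1_duplex_energy(seq) == 0.0

    def test_t_u_spelling_invariance(self):
        assert u1_duplex_energy("CAGGTAAGT") == u1_duplex_energy("CAGGUAAGU")

    def test_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            u1_duplex_energy("CAGGUAAG")  # too short
        with pytest.raises(ValueError):
            u1_duplex_energy("CAGGUAAGX")


def _install_windows(seq: str, genome_seq: str, intron: tuple[int, int]) -> str:
    """Helper: place GT..AG at intron boundaries of a synthetic chromosome."""
    s = list(genome_seq)
    s[intron[0] : intron[0] + 2] = "GT"
    s[intron[1] - 2 : intron[1]] = "AG"
    return "".join(s)


class TestExtractSpliceWindows:
    def test_plus_strand_windows_match_hand_read_substrings(self):
        rng = np.random.default_rng(0)
        raw = "".join(rng.choice(list("ACGT"), size=300))
        raw = _install_windows("", raw, (100, 200))
        genome = GenomeSequence({"c": raw})
        gene = GeneModel("g", "c", "+", exons=[(50, 100), (200, 260)])
        recs, skipped = extract_splice_windows([gene], genome)
        assert not skipped
        (r,) = recs
        assert r["fivess_window"] == raw[97:106]
        assert r["threess_window"] == raw[178:202]
        assert r["fivess_window"][3:5] == "GT"
        assert r["threess_window"][20:22] == "AG"
        assert len(r["fivess_window"]) == FIVE_SS_WINDOW.length
        assert len(r["threess_window"]) == THREE_SS_WINDOW.length

    def test_minus_strand_mirror_gives_identical_windows(self):
        rng = np.random.default_rng(1)
        raw = "".join(rng.choice(list("ACGT"), size=300))
        raw = _install_windows("", raw, (100, 200))
        genome = GenomeSequence({"c": raw})
        plus = GeneModel("g", "c", "+", exons=[(50, 100), (200, 260)])
        rc = GenomeSequence({"c": reverse_complement(raw)})
        L = len(raw)
        minus = GeneModel(
            "g", "c", "-", exons=[(L - 100, L - 50), (L - 260, L - 200)]
        )
        rec_p, _ = extract_splice_windows([plus], genome)
        rec_m, _ = extract_splice_windows([minus], rc)
        assert rec_p[0]["fivess_window"] == rec_m[0]["fivess_window"]
        assert rec_p[0]["threess_window"] == rec_m[0]["threess_window"]

    def test_short_and_noncanonical_introns_skipped_with_reason(self):
        rng = np.random.default_rng(2)
        raw = "".join(rng.choice(list("ACGT"), size=300))
        genome = GenomeSequence({"c": raw.replace("G", "A")})  # no GT boundaries
        gene = GeneModel("g", "c", "+", exons=[(50, 100), (200, 260)])
        recs, skipped = extract_splice_windows([gene], genome)
        assert not recs and "non-GT..AG" in skipped[0]

        short = GeneModel("g2", "c", "+", exons=[(50, 100), (110, 160)])
        recs, skipped = extract_splice_windows([short], genome, gt_ag_only=False)
        assert not recs and "length" in skipped[0]
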