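"""PFM parsing, PWM construction and relative-score scanning."""

import math

import numpy as np
import pytest

from permdeg import (
    parse_jaspar,
    pfm_to_pwm,
    rank_predicted_tfs,
    scan_sequence,
    simulate_promoters,
)
from permdeg.errors import FormatError, ParameterError
from permdeg.motifs import (
    MotifHit,
    PositionFrequencyMatrix,
    format_jaspar,
    parse_jaspar_all,
    reverse_complement,
)

BRACKETED = """>MA0001.1 TOY1
A [ 3 10 1 0 ]
C [ 2 0 1 12 ]
G [ 6 1 1 0 ]
T [ 1 1 9 0 ]
"""

PLAIN = """>MA0001.1 TOY1
A 3 10 1 0
C 2 0 1 12
G 6 1 1 0
T 1 1 9 0
"""

UNLABELED = """>MA0001.1 TOY1
3 10 1 0
2 0 1 12
6 1 1 0
1 1 9 0
"""


@pytest.fixture(scope="module")
def pfm():
    return parse_jaspar(BRACKETED)  # consensus GATC


@pytest.fixture(scope="module")
def pwm(pfm):
    return pfm_to_pwm(pfm)


class TestParser:
    def test_basic_shape(self, pfm):
        assert pfm.motif_id == "MA0001.1"
        assert pfm.name == "TOY1"
        assert pfm.length == 4
        assert pfm.counts[0, 1] == 10

    @pytest.mark.parametrize("dialect", [PLAIN, UNLABELED])
    def test_dialect_equivalence(self, pfm, dialect):
        np.testing.assert_array_equal(parse_jaspar(dialect).counts, pfm.counts)

    def test_ragged_rows_rejected(self):
        text = BRACKETED.replace("G [ 6 1 1 0 ]", "G [ 6 1 1 ]")
        with pytest.raises(FormatError, match="ragged"):
            parse_jaspar(text)

    def test_missing_row_rejected(self):
        text = "\n".join(BRACKETED.splitlines()[:4]) + "\n"
        with pytest.raises(FormatError, match="base rows"):
            parse_jaspar(text)

    def test_counts_before_header_rejected(self):
        with pytest.raises(FormatError, match="header"):
            parse_jaspar("A [ 1 2 3 ]\n")

    def test_multi_motif_and_roundtrip(self, pfm):
        text = format_jaspar(pfm) + format_jaspar(
            PositionFrequencyMatrix("M2", "other", pfm.counts[:, :2])
        )
        motifs = parse_jaspar_all(text)
        assert [m.motif_id for m in motifs] == ["MA0001.1", "M2"]
        np.testing.assert_array_equal(motifs[0].counts, pfm.counts)

    def test_consensus_tie_breaks_acgt_order(self):
        counts = np.array([[2, 0], [2, 3], [1, 3], [0, 0]], dtype=float)
        assert PositionFrequencyMatrix("M", "M", counts).consensus() == "AC"


class TestPwm:
    def test_hand_log_odds_without_pseudocount(self):
        counts = np.array(
            [[2, 8], [1, 1], [1, 1], [4, 6]], dtype=float
        )
        pwm = pfm_to_pwm(
            PositionFrequencyMatrix("M", "M", counts), pseudocount=0.0
        )
        # column 0 probabilities (0.25, 0.125, 0.125, 0.5) over uniform bg
        np.testing.assert_allclose(pwm.log_odds[:, 0], [0.0, -1.0, -1.0, 1.0])

    def test_zero_count_with_zero_pseudocount_rejected(self):
        counts = np.array([[10, 1], [0, 1], [0, 1], [0, 1]], dtype=float)
        with pytest.raises(ParameterError):
            pfm_to_pwm(PositionFrequencyMatrix("M", "M", counts), pseudocount=0.0)

    def test_count_scaling_invariance(self):
        counts = np.array([[2, 8], [1, 1], [1, 1], [4, 6]], dtype=float)
        a = pfm_to_pwm(PositionFrequencyMatrix("M", "M", counts), 0.0)
        b = pfm_to_pwm(PositionFrequencyMatrix("M", "M", 2 * counts), 0.0)
        np.testing.assert_allclose(a.log_odds, b.log_odds)

    def test_uninformative_motif_rejected(self):
        counts = np.full((4, 3), 5.0)
        with pytest.raises(ParameterError, match="uninformative"):
            pfm_to_pwm(PositionFrequencyMatrix("M", "M", counts), 0.0)

    def test_score_bounds_recorded(self, pwm):
        assert pwm.s_min == pytest.approx(pwm.log_odds.min(axis=0).sum())
        assert pwm.s_max == pytest.approx(pwm.log_odds.max(axis=0).sum())
        assert pwm.s_max > pwm.s_min

    def test_matches_biopython_pssm(self, pfm):
        Bio_motifs = pytest.importorskip("Bio.motifs")
        from Bio.motifs.matrix import FrequencyPositionMatrix

        counts = {b: list(pfm.counts[i]) for i, b in enumerate("ACGT")}
        motif = Bio_motifs.Motif(counts=FrequencyPositionMatrix("ACGT", counts))
        motif.pseudocounts = {b: 0.8 * 0.25 for b in "ACGT"}
        pssm = motif.pssm
        ours = pfm_to_pwm(pfm, 0.8)
        for i, b in enumerate("ACGT"):
            np.testing.assert_allclose(ours.log_odds[i], pssm[b], atol=1e-9)


class TestScan:
    def test_consensus_scores_one_and_is_hit(self, pfm, pwm):
        seq = "TT" + pfm.consensus() + "TT"
        hits = scan_sequence(seq, pwm, threshold=0.9, both_strands=False)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand) == (2, 6, "+")
        assert h.relative_score == pytest.approx(1.0)

    def test_anti_consensus_scores_zero(self, pfm, pwm):
        anti = "".join("ACGT"[i] for i in pwm.log_odds.argmin(axis=0))
        hits = scan_sequence(anti, pwm, threshold=0.0, both_strands=False)
        assert hits == []  # relative 0.0 is not > 0.0
        score = pwm.log_odds[
            [("ACGT".index(c)) for c in anti], np.arange(4)
        ].sum()
        assert pwm.relative(score) == pytest.approx(0.0)

    def test_minus_strand_hit_in_plus_coordinates(self, pfm, pwm):
        planted = reverse_complement(pfm.consensus())
        seq = "AAAAA" + planted + "AAAAA"
        hits = scan_sequence(seq, pwm, threshold=0.9)
        minus = [h for h in hits if h.strand == "-"]
        assert len(minus) == 1
        assert (minus[0].start, minus[0].end) == (5, 9)
        assert minus[0].relative_score == pytest.approx(1.0)

    def test_windows_with_n_skipped(self, pfm, pwm):
        seq = "TTACG" + "N" + "GATCTT"
        hits = scan_sequence(seq, pwm, threshold=0.0)
        assert hits  # valid windows do exist on both sides of the N
        assert all("N" not in seq[h.start : h.end] for h in hits)

    def test_short_sequence_empty(self, pwm):
        assert scan_sequence("AC", pwm) == []

    def test_invalid_threshold_rejected(self, pwm):
        with pytest.raises(ParameterError):
            scan_sequence("ACGTACGT", pwm, threshold=1.5)

    def test_relative_scores_bounded(self, pwm):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        hits = scan_sequence(seq, pwm, threshold=0.0)
        assert all(0.0 <= h.relative_score <= 1.0 for h in hits)

    def test_strand_symmetry_on_random_sequences(self, pwm):
        rng = np.random.default_rng(1)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=80))
            fwd = scan_sequence(seq, pwm, threshold=0.5)
            rev = scan_sequence(reverse_complement(seq), pwm, threshold=0.5)
            n = len(seq)
            mapped = sorted(
                (n - h.end, n - h.start, "-" if h.strand == "+" else "+",
                 round(h.raw_score, 9))
                for h in rev
            )
            original = sorted(
                (h.start, h.end, h.strand, round(h.raw_score, 9)) for h in fwd
            )
            assert mapped == original

    def test_planted_sites_recovered(self, pfm, pwm):
        plants = [(0, 5, "+"), (0, 30, "-"), (1, 12, "+")]
        seqs, truth = simulate_promoters(pfm, 2, 60, plants, seed=3)
        for seq_id, pos, strand in truth:
            hits = scan_sequence(seqs[seq_id], pwm, 0.9, sequence_id=seq_id)
            assert any(
                h.start == pos and h.strand == strand for h in hits
            ), (seq_id, pos, strand)


class TestRanking:
    def test_empty(self):
        assert len(rank_predicted_tfs({})) == 0
        assert len(rank_predicted_tfs({"M": []})) == 0

    def test_ordering_and_ties(self):
        mk = lambda rel: MotifHit("s", 0, 4, "+", 1.0, rel)  # noqa: E731
        table = rank_predicted_tfs(
            {"B": [mk(0.92)], "A": [mk(0.95), mk(0.91)], "C": [mk(0.95)]}
        )
        assert list(table["motif_id"]) == ["A", "C", "B"]
        assert table["n_hits"].tolist() == [2, 1, 1]
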