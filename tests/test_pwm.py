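"""PWM construction, information content, scoring and consensus."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdzscan import (
    AMINO_ACIDS,
    PWM,
    PeptideAlignment,
    build_pwm,
    consensus,
    position_information_content,
    score_all,
    score_cterm,
)
from pdzscan.pwm import MAX_BITS, read_peptides, read_pwms_json, write_pwms_json

IDX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
LOG20 = math.log2(20)


class TestBuildPWM:
    def test_hand_counted_frequencies(self, toy_pwm):
        # {ETWV, ESWV, ETWI, QTWV}: offset 0 -> V 3/4, I 1/4; offset 2 -> T 3/4, S 1/4
        assert toy_pwm.probs[0, IDX["V"]] == pytest.approx(0.75)
        assert toy_pwm.probs[0, IDX["I"]] == pytest.approx(0.25)
        assert toy_pwm.probs[2, IDX["T"]] == pytest.approx(0.75)
        assert toy_pwm.probs[2, IDX["S"]] == pytest.approx(0.25)
        other = [i for i in range(20) if AMINO_ACIDS[i] not in "VI"]
        assert toy_pwm.probs[0, other].sum() == 0.0
        assert toy_pwm.probs[1, IDX["W"]] == pytest.approx(1.0)

    def test_single_peptide_columns_are_one_hot(self):
        pwm = build_pwm(PeptideAlignment("x", ["AAAAAAA"] * 5), 0.0)
        assert np.allclose(pwm.probs[:, IDX["A"]], 1.0)
        assert np.allclose(pwm.ic, LOG20)

    def test_offsets_beyond_longest_peptide_are_uniform(self, toy_pwm):
        # peptides are 4-mers: offsets 4..6 undefined -> uniform rows, IC 0
        assert np.allclose(toy_pwm.probs[4:], 0.05)
        assert np.allclose(toy_pwm.ic[4:], 0.0)

    def test_uniform_column_has_zero_information(self):
        pwm = build_pwm(PeptideAlignment("u", list(AMINO_ACIDS)), 0.0)
        assert np.allclose(pwm.probs[0], 0.05)
        assert pwm.ic[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("mode", ["proportional", "inverse", "flat"])
    @pytest.mark.parametrize("kappa", [0.0, 0.5, 1.0, 10.0])
    def test_rows_stochastic_for_all_modes(self, toy_alignment, kappa, mode):
        pwm = build_pwm(toy_alignment, kappa, mode)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-9)
        assert (pwm.probs >= 0).all()

    def test_pseudocount_fills_zeros(self, toy_alignment):
        pwm = build_pwm(toy_alignment, 1.0, "proportional")
        assert (pwm.probs[0] > 0).all()

    def test_empty_alignment_rejected(self):
        with pytest.raises(ValueError, match="empty alignment"):
            PeptideAlignment("bad", [])

    def test_invalid_residue_names_offending_peptide(self):
        with pytest.raises(ValueError, match="ETXV"):
            PeptideAlignment("bad", ["ETWV", "ETXV"])

    def test_negative_kappa_rejected(self, toy_alignment):
        with pytest.raises(ValueError):
            build_pwm(toy_alignment, -1.0)


class TestInformationContent:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ([1.0] + [0.0] * 19, LOG20),
            ([0.05] * 20, 0.0),
            # H(0.75, 0.25) = 0.8113 bits
            ([0.75, 0.25] + [0.0] * 18, LOG20 - 0.811278),
        ],
    )
    def test_reference_values(self, freqs, expected):
        assert position_information_content(freqs) == pytest.approx(expected, abs=1e-5)

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            position_information_content([-0.1, 1.1] + [0.0] * 18)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            position_information_content([0.5] * 20)


def _uniform_pwm():
    return PWM("u", np.full((7, 20), 0.05), np.zeros(7))


class TestScoring:
    def test_uniform_model_background_score(self):
        assert score_cterm(_uniform_pwm(), "GETWVAA") == pytest.approx(
            7 * math.log10(0.05)
        )

    def test_perfect_consensus_scores_zero(self):
        pwm = build_pwm(PeptideAlignment("x", ["GETWVAA"] * 3), 0.0)
        assert score_cterm(pwm, "GETWVAA") == 0.0

    def test_toy_pwm_recomputed_score(self, toy_pwm):
        # log10(.75) at offsets 0, 2, 3 plus log10(1) at offset 1
        assert score_cterm(toy_pwm, "ETWV") == pytest.approx(3 * math.log10(0.75))

    def test_short_sequence_uses_available_offsets(self, toy_pwm):
        assert score_cterm(toy_pwm, "WV") == pytest.approx(math.log10(0.75))

    def test_zero_probability_gives_minus_inf_only_without_pseudocount(
        self, toy_alignment
    ):
        raw = build_pwm(toy_alignment, 0.0)
        smoothed = build_pwm(toy_alignment, 1.0)
        assert score_cterm(raw, "ETWA") == float("-inf")
        assert np.isfinite(score_cterm(smoothed, "ETWA"))

    def test_invalid_and_empty_sequences_rejected(self, toy_pwm):
        with pytest.raises(ValueError):
            score_cterm(toy_pwm, "ETX")
        with pytest.raises(ValueError, match="empty"):
            score_cterm(toy_pwm, "")

    def test_score_never_positive(self, toy_alignment):
        for kappa in (0.0, 1.0):
            pwm = build_pwm(toy_alignment, kappa)
            for seq in ("ETWV", "QSWI", "AAAAAAA", "V"):
                assert score_cterm(pwm, seq) <= 0.0

    def test_monotone_in_residue_probability(self, toy_pwm):
        # offset 0: p(V)=0.75 > p(I)=0.25 -> swapping I for V raises the score
        assert score_cterm(toy_pwm, "ETWV") > score_cterm(toy_pwm, "ETWI")


class TestScoreAll:
    def test_singleton_matrix_equals_score_cterm(self, toy_pwm):
        m = score_all([toy_pwm], ["ETWV"])
        assert m.shape == (1, 1)
        assert m.iloc[0, 0] == score_cterm(toy_pwm, "ETWV")

    def test_cartesian_shape_and_labels(self, designed_pwms):
        seqs = ["AAAAAAA", "CCCCCCC", "DEFGHIK", "WYWYWYW"]
        m = score_all(designed_pwms, seqs)
        assert m.shape == (3, 4)
        assert list(m.index) == [p.domain_id for p in designed_pwms]
        assert list(m.columns) == seqs

    def test_column_order_follows_input_order(self, designed_pwms):
        seqs = ["AAAAAAA", "CCCCCCC", "DEFGHIK"]
        fwd = score_all(designed_pwms, seqs)
        rev = score_all(designed_pwms, seqs[::-1])
        assert np.allclose(fwd.values, rev.values[:, ::-1])

    def test_empty_inputs_rejected(self, toy_pwm):
        with pytest.raises(ValueError):
            score_all([], ["AAAA"])
        with pytest.raises(ValueError):
            score_all([toy_pwm], [])


class TestConsensus:
    def test_one_hot_pwm_recovers_peptide(self):
        pwm = build_pwm(PeptideAlignment("x", ["GETWVAA"] * 2), 0.0)
        assert consensus(pwm) == "GETWVAA"

    def test_uniform_pwm_breaks_ties_alphabetically(self):
        assert consensus(_uniform_pwm()) == "AAAAAAA"

    def test_toy_pwm_consensus_tail(self, toy_pwm):
        assert consensus(toy_pwm).endswith("ETWV")

    def test_consensus_beats_every_sequence_exhaustively(self):
        # two-residue toy alphabet: consensus optimality over all 2^7 7-mers
        pwm = build_pwm(
            PeptideAlignment(
                "x", ["TTTTTTT", "TTTTTTS", "TSTTTST", "STTTSTT", "TTSTTTT"]
            ),
            0.0,
        )
        best_score = score_cterm(pwm, consensus(pwm))
        for bits in range(2**7):
            seq = "".join("TS"[(bits >> i) & 1] for i in range(7))
            assert best_score >= score_cterm(pwm, seq) - 1e-12


# hypothesis: random alignments keep rows stochastic and scores bounded
@st.composite
def alignments(draw):
    n = draw(st.integers(1, 8))
    peps = [
        "".join(
            draw(st.sampled_from(AMINO_ACIDS))
            for _ in range(draw(st.integers(1, 7)))
        )
        for _ in range(n)
    ]
    return PeptideAlignment("h", peps)


@given(
    aln=alignments(),
    kappa=st.floats(0.0, 20.0, allow_nan=False),
    mode=st.sampled_from(["proportional", "inverse", "flat"]),
)
@settings(max_examples=60, deadline=None, derandomize=True)
def test_random_alignments_build_valid_models(aln, kappa, mode):
    pwm = build_pwm(aln, kappa, mode)
    assert np.allclose(pwm.probs.sum(axis=1), 1.0, atol=1e-9)
    assert (pwm.ic >= -1e-9).all() and (pwm.ic <= LOG20 + 1e-9).all()
    assert score_cterm(pwm, aln.peptides[0]) <= 1e-12
    # consensus optimality, compared over the same number of visited offsets
    best = consensus(pwm)
    window = best[len(best) - len(aln.peptides[0]):]
    assert score_cterm(pwm, window) >= score_cterm(pwm, aln.peptides[0]) - 1e-9


class TestIO:
    def test_json_roundtrip(self, toy_pwm, tmp_path):
        path = tmp_path / "pwms.json"
        write_pwms_json([toy_pwm], path)
        (reread,) = read_pwms_json(path)
        assert reread.domain_id == toy_pwm.domain_id
        assert np.allclose(reread.probs, toy_pwm.probs)
        assert np.allclose(reread.ic, toy_pwm.ic)

    def test_read_peptides_plain_and_fasta(self, tmp_path):
        plain = tmp_path / "DLG1#2.txt"
        plain.write_text("ETWV\nESWV\n")
        aln = read_peptides(plain)
        assert aln.domain_id == "DLG1#2"
        assert aln.peptides == ("ETWV", "ESWV")

        fasta = tmp_path / "MPDZ#1.fa"
        fasta.write_text(">p1\nETWV\n>p2\nQSWI\n")
        aln2 = read_peptides(fasta)
        assert aln2.peptides == ("ETWV", "QSWI")
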