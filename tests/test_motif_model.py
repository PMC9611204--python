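"""Unit and property tests for PSSM scoring and exact p-values."""

import io
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhizotrn.motif_model import (
    PSSM,
    FormatError,
    exact_pvalue,
    log_odds,
    parse_matrix_id,
    read_transfac,
    reverse_complement,
    score_distribution,
    score_sequence,
    significance,
    write_transfac,
)

from conftest import random_pssm


class TestMatrixId:
    @pytest.mark.parametrize(
        "mid,expected",
        [("RHE_RS13345_m5", ("RHE_RS13345", 5)), ("G001_m1", ("G001", 1))],
    )
    def test_parse(self, mid, expected):
        assert parse_matrix_id(mid) == expected

    @pytest.mark.parametrize("bad", ["G001_q1", "G001", "_m1x", "G001_m"])
    def test_malformed(self, bad):
        with pytest.raises(FormatError):
            parse_matrix_id(bad)


class TestLogOdds:
    def test_background_column_is_zero(self):
        # counts proportional to the background give zero log-odds
        p = PSSM("X_m1", np.array([[1.0], [1.0], [1.0], [1.0]]))
        assert np.allclose(log_odds(p), 0.0)

    def test_hand_arithmetic(self):
        p = PSSM("X_m1", np.array([[4.0], [0.0], [0.0], [0.0]]), pseudocount=1.0)
        assert log_odds(p)[0, 0] == pytest.approx(math.log2((4 + 0.25) / 5 / 0.25))

    def test_zero_background_rejected(self):
        p = PSSM("X_m1", np.ones((4, 2)), background=np.array([0.5, 0.5, 0.0, 0.0]))
        with pytest.raises(ValueError):
            log_odds(p)

    def test_count_scaling_behaviour(self):
        # the regularised ratio is homogeneous: scaling counts and pseudocount
        # together cancels exactly; scaling counts alone shifts the mix
        counts = np.array([[4.0, 1.0], [0.0, 2.0], [1.0, 0.0], [0.0, 2.0]])
        a = PSSM("X_m1", counts, pseudocount=1.0)
        b = PSSM("X_m1", counts * 10, pseudocount=10.0)
        c = PSSM("X_m1", counts * 10, pseudocount=1.0)
        assert np.allclose(log_odds(a), log_odds(b))
        assert not np.allclose(log_odds(a), log_odds(c))

    def test_probability_columns_sum_to_one(self, rng):
        p = random_pssm(rng, 7)
        assert np.allclose(p.probabilities().sum(axis=0), 1.0, atol=1e-12)


class TestScoreSequence:
    def test_zero_matrix_scores_zero(self):
        p = PSSM("X_m1", np.ones((4, 3)))
        assert score_sequence(p, "ACG") == pytest.approx(0.0)

    def test_reverse_strand_equals_revcomp_direct(self, rng):
        p = random_pssm(rng, 5)
        seq = "ACGTT"
        assert score_sequence(p, seq, "R") == pytest.approx(
            score_sequence(p, reverse_complement(seq), "D")
        )

    def test_matches_per_position_sum(self, rng):
        p = random_pssm(rng, 3)
        lod = log_odds(p)
        expected = lod[0, 0] + lod[1, 1] + lod[2, 2]  # A, C, G
        assert score_sequence(p, "ACG") == pytest.approx(expected)

    def test_rejects_length_mismatch_and_alphabet(self, rng):
        p = random_pssm(rng, 4)
        with pytest.raises(ValueError):
            score_sequence(p, "ACG")
        with pytest.raises(ValueError):
            score_sequence(p, "ACGN")


def brute_force_tail(pssm, threshold):
    """Exhaustive p-value over all 4^w sequences (the independent oracle)."""
    lod = log_odds(pssm)
    total = 0.0
    for seq in itertools.product(range(4), repeat=pssm.width):
        s = sum(lod[b, j] for j, b in enumerate(seq))
        if s >= threshold:
            total += np.prod([pssm.background[b] for b in seq])
    return total


class TestExactPvalue:
    def test_minus_inf_is_one(self, rng):
        p = random_pssm(rng, 4)
        assert exact_pvalue(p, float("-inf")) == 1.0

    def test_width_one_forced(self):
        p = PSSM("X_m1", np.array([[10.0], [0.0], [0.0], [0.0]]))
        best = log_odds(p)[0, 0]
        assert exact_pvalue(p, best) == pytest.approx(0.25)

    @pytest.mark.parametrize("width", [1, 2, 3, 4, 5, 6])
    def test_matches_enumeration_within_discretisation(self, width, rng):
        g = 0.01
        for trial in range(3):
            p = random_pssm(rng, width, name=f"G{trial}_m1")
            dist = score_distribution(p, g)
            lod = log_odds(p)
            scores = [
                sum(lod[b, j] for j, b in enumerate(seq))
                for seq in itertools.product(range(4), repeat=width)
            ]
            delta = (width + 1) * g / 2
            for t in np.percentile(scores, [5, 35, 65, 95]):
                pd = dist.pvalue(t)
                lo = brute_force_tail(p, t + delta)
                hi = brute_force_tail(p, t - delta)
                assert lo - 1e-12 <= pd <= hi + 1e-12

    def test_monotone_in_threshold(self, rng):
        p = random_pssm(rng, 5)
        dist = score_distribution(p)
        ts = np.linspace(dist.grid[0] - 1, dist.grid[-1] + 1, 60)
        ps = [dist.pvalue(t) for t in ts]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
        assert ps[0] == 1.0 and ps[-1] == 0.0

    def test_tail_invariants(self, rng):
        dist = score_distribution(random_pssm(rng, 4))
        assert np.all(np.diff(dist.tail_prob) <= 1e-15)
        assert dist.tail_prob[0] == pytest.approx(1.0)

    def test_halving_granularity_converges(self, rng):
        p = random_pssm(rng, 4)
        for t in (2.0, 4.0):
            g = 0.02
            p_coarse = score_distribution(p, g).pvalue(t)
            p_fine = score_distribution(p, g / 2).pvalue(t)
            delta = (p.width + 1) * g / 2
            bound = brute_force_tail(p, t - delta) - brute_force_tail(p, t + delta)
            assert abs(p_coarse - p_fine) <= bound + 1e-12


class TestSignificance:
    @pytest.mark.parametrize(
        "p,expected", [(1.0, 0.0), (1e-6, 6.0), (5e-5, 4.3010299956639813)]
    )
    def test_values(self, p, expected):
        assert significance(p) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [0.0, -1.0, 1.5])
    def test_domain(self, bad):
        with pytest.raises(ValueError):
            significance(bad)


class TestTransfac:
    def test_round_trip_identity_on_counts(self, rng):
        pssms = [random_pssm(rng, w, name=f"G{i:03d}_m{i % 5 + 1}") for i, w in
                 enumerate([3, 6, 10])]
        buf = io.StringIO()
        write_transfac(pssms, buf)
        buf.seek(0)
        back = read_transfac(buf)
        assert [b.matrix_id for b in back] == [p.matrix_id for p in pssms]
        for b, p in zip(back, pssms):
            assert np.array_equal(b.counts, p.counts)

    def test_real_counts_tolerated(self):
        text = "ID  G001_m2\nP0      A      C      G      T\n01   1.5   0.5   1     1\nXX\n//\n"
        (p,) = read_transfac(io.StringIO(text))
        assert p.counts[0, 0] == pytest.approx(1.5)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.floats(min_value=1e-30, max_value=1.0, exclude_min=True))
def test_significance_inverts_pvalue(p):
    assert 10 ** (-significance(p)) == pytest.approx(p, rel=1e-9)
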