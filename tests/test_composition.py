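"""Composition encoders: single-sequence formulas and alignment pooling.

The pseudo-composition is checked against an independent step-by-step
re-implementation of the defining formulas (the oracle shares no code
with the package path it verifies).
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from transub.composition import (
    PAAC_NAMES,
    aac,
    encode_alignment,
    encode_sequence,
    feature_table,
    paac,
    pseaac,
    theta_factors,
)
from transub.properties import (
    HOPP_WOODS_HYDROPHILICITY,
    SIDE_CHAIN_MASS,
    TANFORD_HYDROPHOBICITY,
    PropertyTables,
    default_tables,
    standardize_table,
)
from transub.seqio import AMINO_ACIDS, Alignment

seq_strategy = st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=80)


# ---------------------------------------------------------------- oracles

def oracle_pseaac(seq, lam, omega):
    """Independent evaluation of the pseudo-composition formulas."""

    def standardize(table):
        vals = [table[a] for a in AMINO_ACIDS]
        mean = sum(vals) / 20
        sd = (sum((v - mean) ** 2 for v in vals) / 20) ** 0.5
        return {a: (table[a] - mean) / sd for a in AMINO_ACIDS}

    h1 = standardize(TANFORD_HYDROPHOBICITY)
    h2 = standardize(HOPP_WOODS_HYDROPHILICITY)
    m = standardize(SIDE_CHAIN_MASS)

    def corr(a, b):
        return (
            (h1[b] - h1[a]) ** 2 + (h2[b] - h2[a]) ** 2 + (m[b] - m[a]) ** 2
        ) / 3.0

    L = len(seq)
    thetas = [
        sum(corr(seq[i], seq[i + k]) for i in range(L - k)) / (L - k)
        for k in range(1, lam + 1)
    ]
    f = [seq.count(a) / L for a in AMINO_ACIDS]
    denom = sum(f) + omega * sum(thetas)
    return [fi / denom for fi in f] + [omega * t / denom for t in thetas]


# ----------------------------------------------------------- single seq

class TestAac:
    def test_homopolymer(self):
        v = aac("AAAA")
        assert v.values[0] == 1.0 and v.values[1:].sum() == 0.0

    def test_uniform(self):
        v = aac("ACDE")
        np.testing.assert_allclose(v.values[:4], 0.25)

    def test_matches_independent_tally(self, random_sequence):
        s = random_sequence(200)
        v = aac(s)
        for i, a in enumerate(AMINO_ACIDS):
            assert v.values[i] == pytest.approx(s.count(a) / 200)

    def test_empty_error(self):
        with pytest.raises(ValueError, match="no countable"):
            aac("XXX")


class TestPaac:
    def test_homopolymer_pair(self):
        v = paac("AAA")
        assert v.values[0] == 1.0  # d_AA = 2 pairs / (3-1)

    def test_alternating(self):
        v = paac("ACAC")
        d = dict(zip(PAAC_NAMES, v.values))
        assert d["AC"] == pytest.approx(2 / 3)
        assert d["CA"] == pytest.approx(1 / 3)

    def test_length_is_400(self, random_sequence):
        assert len(paac(random_sequence(60))) == 400

    def test_too_short_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            paac("A")

    def test_row_sums_approximate_letter_frequencies(self, random_sequence):
        # pair matrix marginals reconstruct per-letter composition to O(1/L)
        s = random_sequence(500)
        pair = paac(s).values.reshape(20, 20)
        single = aac(s).values
        np.testing.assert_allclose(pair.sum(axis=1), single, atol=2 / 500)


class TestStandardize:
    def test_mean_zero_population_sd_one(self):
        for raw in (
            TANFORD_HYDROPHOBICITY,
            HOPP_WOODS_HYDROPHILICITY,
            SIDE_CHAIN_MASS,
        ):
            std = standardize_table(raw)
            vals = np.array([std[a] for a in AMINO_ACIDS])
            assert abs(vals.mean()) < 1e-9
            assert vals.std() == pytest.approx(1.0, abs=1e-9)

    def test_constant_table_errors(self):
        with pytest.raises(ValueError, match="zero denominator"):
            standardize_table({a: 1.0 for a in AMINO_ACIDS})

    def test_missing_residue_errors(self):
        broken = dict(TANFORD_HYDROPHOBICITY)
        del broken["W"]
        with pytest.raises(ValueError, match="missing"):
            standardize_table(broken)


class TestTheta:
    def test_homopolymer_thetas_vanish(self):
        np.testing.assert_allclose(theta_factors("A" * 30, 5), 0.0)

    def test_non_negative(self, random_sequence):
        assert (theta_factors(random_sequence(50), 8) >= 0).all()

    def test_alternating_pair(self):
        # "RKRK": at lag 2 every pair is identical, at lag 1 it is (R,K)
        t = theta_factors("RKRK", 2)
        tables = default_tables()
        expected = (
            (tables.h1["K"] - tables.h1["R"]) ** 2
            + (tables.h2["K"] - tables.h2["R"]) ** 2
            + (tables.m_norm["K"] - tables.m_norm["R"]) ** 2
        ) / 3.0
        assert t[1] == 0.0
        assert t[0] == pytest.approx(expected)

    def test_lambda_too_large(self):
        with pytest.raises(ValueError, match="lambda \\(4\\).*length \\(3\\)"):
            theta_factors("ACD", 4)


class TestPseaac:
    def test_lambda_zero_equals_aac(self, random_sequence):
        s = random_sequence(80)
        np.testing.assert_allclose(pseaac(s, lam=0).values, aac(s).values)

    def test_matches_step_by_step_oracle(self):
        s = "ACDEFGHIK"
        got = pseaac(s, lam=3, omega=0.05).values
        np.testing.assert_allclose(got, oracle_pseaac(s, 3, 0.05), rtol=1e-12)

    def test_oracle_agreement_random(self, random_sequence):
        for lam, omega in [(1, 0.05), (5, 0.3), (10, 0.7)]:
            s = random_sequence(60)
            np.testing.assert_allclose(
                pseaac(s, lam=lam, omega=omega).values,
                oracle_pseaac(s, lam, omega),
                rtol=1e-12,
            )

    def test_omega_warning_outside_range(self):
        with pytest.warns(UserWarning, match="omega"):
            pseaac("ACDEFGHIK", lam=2, omega=0.9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seq=seq_strategy, lam=st.integers(0, 6), omega=st.floats(0.05, 0.7))
    def test_sum_to_one_property(self, seq, lam, omega):
        if lam >= len(seq):
            return
        assert pseaac(seq, lam=lam, omega=omega).values.sum() == pytest.approx(1.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seq=seq_strategy)
def test_probability_vector_property(seq):
    for scheme in ("AAC", "PAAC"):
        v = encode_sequence(seq, scheme)
        assert (v.values >= 0).all()
        assert v.values.sum() == pytest.approx(1.0)


# ------------------------------------------------------------- alignment

class TestEncodeAlignment:
    def test_identical_rows_equal_single_sequence(self, random_sequence):
        s = random_sequence(60)
        aln = Alignment(ids=[f"r{i}" for i in range(5)], seqs=[s] * 5)
        for scheme in ("AAC", "PAAC", "PseAAC"):
            np.testing.assert_allclose(
                encode_alignment(aln, scheme, lam=4).values,
                encode_sequence(s, scheme, lam=4).values,
                atol=1e-12,
            )

    def test_gaps_ignored_aac(self):
        aln = Alignment(ids=["r1", "r2"], seqs=["AC-", "A-C"])
        v = encode_alignment(aln, "AAC")
        assert v.values[0] == pytest.approx(0.5)  # A
        assert v.values[1] == pytest.approx(0.5)  # C

    def test_pair_pooling_manual_tally(self):
        # rows ACD and AC-: pairs {AC, CD} + {AC}
        aln = Alignment(ids=["r1", "r2"], seqs=["ACD", "AC-"])
        v = encode_alignment(aln, "PAAC")
        d = dict(zip(PAAC_NAMES, v.values))
        assert d["AC"] == pytest.approx(2 / 3)
        assert d["CD"] == pytest.approx(1 / 3)

    def test_pairs_bridge_gap_columns(self):
        # residues separated only by gaps are adjacent after compaction
        aln = Alignment(ids=["r1"], seqs=["A--C"])
        v = encode_alignment(aln, "PAAC")
        assert dict(zip(PAAC_NAMES, v.values))["AC"] == 1.0

    def test_one_row_equals_sequence_encoder_exactly(self, random_sequence):
        s = random_sequence(40)
        aln = Alignment(ids=["only"], seqs=[s])
        for scheme in ("AAC", "PAAC"):
            assert (
                encode_alignment(aln, scheme).values
                == encode_sequence(s, scheme).values
            ).all()

    def test_row_permutation_invariance(self, rng, random_sequence):
        seqs = [random_sequence(50) for _ in range(6)]
        ids = [f"r{i}" for i in range(6)]
        aln = Alignment(ids=ids, seqs=seqs)
        perm = rng.permutation(6)
        aln_p = Alignment(ids=[ids[i] for i in perm], seqs=[seqs[i] for i in perm])
        for scheme in ("AAC", "PAAC", "PseAAC"):
            np.testing.assert_allclose(
                encode_alignment(aln, scheme, lam=5).values,
                encode_alignment(aln_p, scheme, lam=5).values,
            )

    def test_nothing_countable_error(self):
        aln = Alignment(ids=["r1"], seqs=["---"])
        with pytest.raises(ValueError, match="nothing countable"):
            encode_alignment(aln, "AAC")

    def test_pseaac_short_rows_skipped_with_warning(self, caplog, random_sequence):
        long_row = random_sequence(30)
        aln = Alignment(
            ids=["long", "short"], seqs=[long_row, "AC" + "-" * 28]
        )
        with caplog.at_level("WARNING"):
            v = encode_alignment(aln, "PseAAC", lam=10)
        assert "skipped" in caplog.text
        assert v.values.sum() == pytest.approx(1.0)


def test_feature_table_layout(random_sequence):
    vecs = {f"s{i}": paac(random_sequence(50)) for i in range(3)}
    tab = feature_table(vecs)
    assert tab.shape == (3, 400)
    assert list(tab.columns[:2]) == ["AA", "AC"]
    assert tab.index.name == "seq_id"
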