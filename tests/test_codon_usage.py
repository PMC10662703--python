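import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitosel import (
    codon_usage_summary,
    composition_and_skew,
    count_codons,
    enc,
    enc_expected,
    get_code,
    neutrality_regression,
    positional_gc_and_pr2,
    rscu,
)
from mitosel.codon_usage import CodonCounts

from oracles import brute_enc

CODE = get_code(5)


class TestComposition:
    @pytest.mark.parametrize(
        "seq,at_skew,gc_skew",
        [("AATT", 0.0, math.nan), ("AAAT", 0.5, math.nan), ("GGGC", math.nan, 0.5)],
    )
    def test_skew_formulas(self, seq, at_skew, gc_skew):
        c = composition_and_skew(seq)
        for got, want in ((c.at_skew, at_skew), (c.gc_skew, gc_skew)):
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want)

    @settings(derandomize=True, max_examples=50)
    @given(st.text(alphabet="ACGTN-", min_size=4, max_size=60))
    def test_fractions_sum_to_one_and_skews_bounded(self, seq):
        if not any(ch in "ACGT" for ch in seq):
            return
        c = composition_and_skew(seq)
        assert c.a + c.t + c.c + c.g == pytest.approx(1.0)
        assert c.at_content == pytest.approx(c.a + c.t)
        for skew in (c.at_skew, c.gc_skew):
            assert math.isnan(skew) or -1.0 <= skew <= 1.0


class TestCountCodons:
    def test_simple_tally(self):
        cc = count_codons("ATGATG", CODE)
        assert cc.counts == {"ATG": 2} and cc.n_codons == 2

    def test_gapped_codon_skipped(self):
        cc = count_codons("AT-GTG", CODE)
        assert cc.counts == {"GTG": 1} and cc.n_skipped == 1

    def test_stop_tallied_separately(self):
        cc = count_codons("TAA", CODE)
        assert cc.n_stop == 1 and cc.n_codons == 0

    def test_frame_violation(self):
        with pytest.raises(ValueError):
            count_codons("ATGA", CODE)


class TestRSCU:
    def test_uniform_fourfold_family(self):
        cc = count_codons("GGA" * 5 + "GGT" * 5 + "GGC" * 5 + "GGG" * 5, CODE)
        t = rscu(cc)
        assert all(t.rscu[c] == pytest.approx(1.0) for c in CODE.family["G"])

    def test_twofold_all_one_codon(self):
        cc = count_codons("AAA" * 10, CODE)  # Lys family AAA/AAG
        t = rscu(cc)
        assert t.rscu["AAA"] == pytest.approx(2.0) and t.rscu["AAG"] == 0.0

    def test_sixfold_maximal_bias(self):
        cc = count_codons("TTA" * 12, CODE)  # Leu, 6 synonyms in code 5
        assert rscu(cc).rscu["TTA"] == pytest.approx(6.0)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_family_sums_equal_family_sizes(self, seed):
        rng = np.random.default_rng(seed)
        counts = {c: int(rng.integers(0, 30)) for c in CODE.sense_codons}
        cc = CodonCounts(counts, CODE, sum(counts.values()))
        t = rscu(cc)
        for aa, codons in CODE.family.items():
            if aa in t.absent_families:
                continue
            assert sum(t.rscu[c] for c in codons) == pytest.approx(
                len(codons), abs=1e-9
            )


class TestENC:
    def test_even_usage_reaches_code_capacity(self):
        cc = count_codons("".join(c * 50 for c in CODE.sense_codons), CODE)
        assert enc(cc) == pytest.approx(62.0)

    def test_one_codon_per_amino_acid_is_minimum(self):
        seq = "".join(codons[0] * 10 for codons in CODE.family.values())
        assert enc(count_codons(seq, CODE)) == pytest.approx(20.0)

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_independent_wright_oracle(self, seed):
        rng = np.random.default_rng(seed)
        counts = {c: int(rng.integers(0, 40)) for c in CODE.sense_codons}
        cc = CodonCounts(counts, CODE, sum(counts.values()))
        got = enc(cc)
        want = brute_enc(counts, CODE)
        if math.isnan(want):
            assert math.isnan(got)
        else:
            assert got == pytest.approx(want, abs=1e-9)

    def test_invariant_under_proportional_scaling_at_large_n(self):
        # the finite-sample correction in F decays like 1/n, so scaling all
        # counts by 10 moves ENC by O(1/n): negligible at large counts
        rng = np.random.default_rng(7)
        counts = {c: int(rng.integers(5, 40)) * 10**7 for c in CODE.sense_codons}
        scaled = {c: v * 10 for c, v in counts.items()}
        e1 = enc(CodonCounts(counts, CODE, sum(counts.values())))
        e2 = enc(CodonCounts(scaled, CODE, sum(scaled.values())))
        assert e1 == pytest.approx(e2, abs=1e-6)

    def test_absent_class_undefined(self):
        # only Lys observed: 4/6/8-fold classes empty
        assert math.isnan(enc(count_codons("AAAAAG", CODE)))


class TestExpectedENC:
    @pytest.mark.parametrize("s,expected", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_closed_form(self, s, expected):
        assert enc_expected(s) == pytest.approx(expected)

    def test_domain_checked(self):
        with pytest.raises(ValueError):
            enc_expected(1.5)


class TestPositionalGCAndPR2:
    def test_parity_center(self):
        # Gly codons with equal third-base usage
        summary = positional_gc_and_pr2("GGA" + "GGT" + "GGG" + "GGC", CODE)
        assert summary.pr2_x == pytest.approx(0.5)
        assert summary.pr2_y == pytest.approx(0.5)

    def test_all_t_third_positions(self):
        summary = positional_gc_and_pr2("GGTGTTCCT", CODE)
        assert summary.pr2_y == 0.0

    def test_gc12_of_gc_rich_codons(self):
        assert positional_gc_and_pr2("GCCGGC", CODE).gc12 == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bounds_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(CODE.sense_codons), size=40))
        s = codon_usage_summary(seq, CODE)
        assert 0.0 <= s.gc3s <= 1.0 and 0.0 <= s.gc12 <= 1.0
        for coord in (s.pr2_x, s.pr2_y):
            assert math.isnan(coord) or 0.0 <= coord <= 1.0
        assert math.isnan(s.enc) or 20.0 <= s.enc <= 62.0


class TestNeutralityRegression:
    def test_identity_line(self):
        pts = [(0.1, 0.1), (0.2, 0.2), (0.3, 0.3), (0.4, 0.4)]
        fit = neutrality_regression(pts)
        assert fit.slope == pytest.approx(1.0) and fit.r_squared == pytest.approx(1.0)

    def test_flat_line(self):
        fit = neutrality_regression([(0.1, 0.4), (0.2, 0.4), (0.3, 0.4)])
        assert fit.slope == pytest.approx(0.0)

    def test_matches_least_squares_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.3, 0.05, size=50)
        y = 0.4 * x + rng.normal(0, 0.01, size=50)
        fit = neutrality_regression(list(zip(x, y)))
        slope, intercept = np.polyfit(x, y, 1)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            neutrality_regression([(0.2, 0.1), (0.2, 0.5), (0.2, 0.9)])
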