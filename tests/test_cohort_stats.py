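"""Spectrum, CNV abundance, gene frequencies and group tests."""

import math

import numpy as np
import pytest

from vafshape.cohort_stats import (
    SPECTRUM_CLASSES,
    adjust_bh,
    cnv_abundance,
    compare_categorical,
    compare_continuous,
    mutation_spectrum,
    per_gene_mf_frequency,
)
from vafshape.io_formats import CNVSegment, MutationRecord


def _mut(ref, alt, sample="S1", gene="G1", polyphen="probably_damaging", pos=1):
    return MutationRecord(sample, "1", pos, ref, alt, 30, 20, polyphen, gene)


class TestSpectrum:
    @pytest.mark.parametrize(
        "ref,alt,klass",
        [
            ("G", "A", "C>T"), ("G", "T", "C>A"), ("G", "C", "C>G"),
            ("A", "G", "T>C"), ("A", "C", "T>G"), ("A", "T", "T>A"),
            ("C", "T", "C>T"), ("T", "G", "T>G"),
        ],
    )
    def test_strand_collapse(self, ref, alt, klass):
        spectrum = mutation_spectrum([_mut(ref, alt)])
        assert spectrum.counts[klass] == 1 and spectrum.total == 1

    def test_twelve_record_fixture_fractions(self):
        muts = (
            [_mut("C", "T")] * 4 + [_mut("G", "A")] * 2  # 6x C>T
            + [_mut("C", "A")] * 3                        # 3x C>A
            + [_mut("A", "G")] * 2                        # 2x T>C
            + [_mut("T", "A")]                            # 1x T>A
        )
        spectrum = mutation_spectrum(muts)
        assert spectrum.fractions["C>T"] == pytest.approx(0.5)
        assert spectrum.fractions["C>A"] == pytest.approx(0.25)
        assert spectrum.fractions["T>C"] == pytest.approx(2 / 12)
        assert spectrum.fractions["T>A"] == pytest.approx(1 / 12)
        assert sum(spectrum.fractions.values()) == pytest.approx(1.0)

    def test_collapse_covers_all_twelve_substitutions_exactly_once(self):
        """The 12 ordered base pairs partition onto the 6 classes, two each."""
        from vafshape.cohort_stats import _COLLAPSE

        assert len(_COLLAPSE) == 12
        targets = list(_COLLAPSE.values())
        assert set(targets) == set(SPECTRUM_CLASSES)
        for klass in SPECTRUM_CLASSES:
            assert targets.count(klass) == 2


class TestCNVAbundance:
    def test_all_neutral_is_zero(self):
        segs = [CNVSegment("S", "1", 1, 100, 20, 0.0),
                CNVSegment("S", "1", 101, 200, 20, 0.1)]
        assert cnv_abundance(segs) == 0.0

    def test_equal_halves(self):
        segs = [CNVSegment("S", "1", 1, 100, 20, 0.0),
                CNVSegment("S", "1", 101, 200, 20, 1.0)]
        assert cnv_abundance(segs) == pytest.approx(0.5)

    def test_boundary_mean_not_counted_as_altered(self):
        segs = [CNVSegment("S", "1", 1, 100, 20, 0.2)]
        assert cnv_abundance(segs) == 0.0

    def test_no_segments_is_missing(self):
        assert math.isnan(cnv_abundance([]))


class TestGeneFrequency:
    LABELS = {"S1": 1, "S2": 1, "S3": 1, "S4": 1}

    def test_one_of_four_samples(self):
        table = per_gene_mf_frequency([_mut("C", "T", sample="S1")], self.LABELS)
        assert table.loc["G1", 1] == pytest.approx(0.25)

    def test_multiple_hits_in_one_sample_count_once(self):
        muts = [_mut("C", "T", sample="S1", pos=p) for p in (1, 2, 3)]
        table = per_gene_mf_frequency(muts, self.LABELS)
        assert table.loc["G1", 1] == pytest.approx(0.25)

    def test_seventy_one_of_two_hundred(self):
        labels = {f"S{i}": 1 for i in range(200)}
        muts = [_mut("C", "T", sample=f"S{i}", gene="PIK3CA") for i in range(71)]
        table = per_gene_mf_frequency(muts, labels)
        assert table.loc["PIK3CA", 1] == pytest.approx(0.355)

    def test_non_mf_mutations_ignored(self):
        muts = [_mut("C", "T", sample="S1", polyphen="benign")]
        assert per_gene_mf_frequency(muts, self.LABELS).empty


def fisher_2x2_oracle(table):
    """Two-sided Fisher p by hypergeometric enumeration."""
    a, b = table[0]
    c, d = table[1]
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(col1, x) * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    p_obs = prob(a)
    return sum(
        prob(x)
        for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1)
        if prob(x) <= p_obs + 1e-12
    )


class TestCategorical:
    def test_perfectly_balanced_table_chi_square_p_one(self):
        result = compare_categorical([[20, 20], [20, 20]])
        assert result.test_used == "chi_square"
        assert result.raw_p == pytest.approx(1.0)

    def test_low_expected_frequency_switches_to_fisher(self):
        result = compare_categorical([[2, 3], [4, 1]])
        assert result.test_used == "fisher_exact"

    def test_large_expected_frequencies_use_chi_square(self):
        result = compare_categorical([[30, 50], [45, 40]])
        assert result.test_used == "chi_square"

    def test_fisher_matches_hypergeometric_brute_force(self):
        table = [[10, 0], [0, 10]]
        result = compare_categorical(table)
        assert result.test_used == "fisher_exact"
        assert result.raw_p == pytest.approx(fisher_2x2_oracle(table), rel=1e-9)
        assert result.raw_p == pytest.approx(2 / 184_756, rel=1e-6)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            compare_categorical([[0, 0], [5, 3]])

    def test_monte_carlo_fisher_close_to_exact_on_small_rxc(self):
        """On a 2x3 table small enough to enumerate, the Monte-Carlo Fisher
        p agrees with full enumeration within sampling error."""
        table = np.array([[3, 1, 1], [1, 3, 2]])
        result = compare_categorical(table, seed=11)
        assert result.test_used == "fisher_exact"

        from vafshape.cohort_stats import _log_table_prob

        row, col = table.sum(1), table.sum(0)
        p_obs = _log_table_prob(table)
        total = 0.0
        hit = 0.0
        for a in range(min(row[0], col[0]) + 1):
            for b in range(min(row[0] - a, col[1]) + 1):
                c = row[0] - a - b
                if c < 0 or c > col[2]:
                    continue
                t = np.array([[a, b, c], [col[0] - a, col[1] - b, col[2] - c]])
                if (t < 0).any():
                    continue
                lp = _log_table_prob(t)
                total += math.exp(lp)
                if lp <= p_obs + 1e-9:
                    hit += math.exp(lp)
        exact_p = hit / total
        assert result.raw_p == pytest.approx(exact_p, abs=0.02)

    def test_chi_square_and_fisher_agree_on_large_balanced_tables(self):
        table = [[600, 400], [550, 450]]
        chi = compare_categorical(table)
        assert chi.test_used == "chi_square"
        from scipy.stats import fisher_exact

        _, fisher_p = fisher_exact(table)
        assert chi.raw_p == pytest.approx(fisher_p, abs=0.02)


class TestContinuous:
    def test_null_rarely_significant(self):
        rng = np.random.default_rng(77)
        rejections = 0
        for _ in range(100):
            groups = {g: rng.normal(10, 2, size=15) for g in "abc"}
            result, _ = compare_continuous(groups, with_tukey=False)
            rejections += result.raw_p < 0.05
        assert rejections <= 10

    def test_large_shift_detected_by_tukey(self, rng):
        groups = {
            "a": rng.normal(0, 1, size=30),
            "b": rng.normal(5, 1, size=30),  # 5 SD shift
        }
        result, tukey = compare_continuous(groups)
        assert result.raw_p < 1e-6
        assert bool(tukey.iloc[0]["reject"])

    def test_identical_groups_give_f_zero_p_one(self):
        values = [1.0, 2.0, 3.0, 4.0]
        result, _ = compare_continuous({"a": values, "b": list(values)})
        assert result.raw_p == pytest.approx(1.0)
        assert result.effect.startswith("F=0")

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_continuous({"a": [1.0, 2.0]})


class TestBenjaminiHochberg:
    def test_hand_computed_three_values(self):
        assert adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert adjust_bh([0.5]) == pytest.approx([0.5])

    def test_order_preserved(self):
        p = [0.04, 0.001, 0.7, 0.02]
        adjusted = adjust_bh(p)
        # the smallest raw p stays the smallest adjusted p, in place
        assert int(np.argmin(adjusted)) == int(np.argmin(p))
        assert len(adjusted) == len(p)

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.uniform(0, 1, size=50)
        adjusted = adjust_bh(p)
        assert (adjusted >= p - 1e-12).all() and (adjusted <= 1.0).all()

    def test_idempotent_on_tied_adjusted_output(self):
        """When step-up adjustment flattens the vector (as in the
        three-value hand example), re-adjusting reproduces it.  (General
        BH is not idempotent: q_i = min_{j>=i} p_j m / j rescales by m/j
        again on a second pass.)"""
        once = adjust_bh([0.01, 0.02, 0.03])
        assert adjust_bh(once) == pytest.approx(once)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])
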