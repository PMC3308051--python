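"""Site taxonomy, filters, calibration, flank rescue and the error model."""

import math

import numpy as np
import pytest

from polycap.pileup_store import BASE_ORDER, CoverageSummary, Pileup
from polycap.variant_classifier import (
    ClassifierConfig,
    LABEL_FILTERED,
    LABEL_GSS,
    LABEL_SNP,
    REASON_LOW_MONO,
    REASON_RATIO,
    REASON_TRIALLELIC,
    TheoryParams,
    VariableSite,
    calibrate_ratio_thresholds,
    call_variable_sites,
    classify_site,
    expected_missed_variant_sites,
    flank_rescue,
    log2_variant_ratio,
    mdc_target_filter,
    simulate_ivs_ratio_mixture,
    validation_confusion,
)


def _pileup(columns, ref=None, accs=("Ld", "Td")):
    """Build a single-target pileup from {pos: {acc: {base: n}}}."""
    L = max(columns) + 1
    ref = ref or "A" * L
    pile = Pileup({"t": ref}, list(accs))
    for pos, per_acc in columns.items():
        for acc, counts in per_acc.items():
            for base, n in counts.items():
                pile.counts["t"][acc][pos, BASE_ORDER.index(base)] = n
    return pile


def _site(ld, td, ref_base="A", alleles=None, target="t", position=0):
    counts = {"Ld": ld, "Td": td}
    pooled = {}
    for c in counts.values():
        for b, n in c.items():
            pooled[b] = pooled.get(b, 0) + n
    ranked = sorted(pooled, key=lambda b: (-pooled[b], b))
    alleles = alleles or tuple(ranked[:2])
    n_alleles = sum(1 for b in pooled.values() if b >= 2)
    is_ivs = {acc: counts[acc].get(alleles[0], 0) >= 1
              and counts[acc].get(alleles[1], 0) >= 1 for acc in counts}
    return VariableSite(target, position, ref_base, counts, alleles,
                        n_alleles, is_ivs)


LOOSE = ClassifierConfig(log2_upper={"Ld": 10.0, "Td": 10.0})


class TestCallVariableSites:
    def test_two_allele_site_with_per_accession_support(self):
        pile = _pileup({3: {"Ld": {"A": 5, "G": 6}, "Td": {"G": 9}}})
        (site,) = call_variable_sites(pile)
        assert set(site.alleles) == {"A", "G"}
        assert site.is_ivs == {"Ld": True, "Td": False}

    def test_single_read_second_allele_not_variable(self):
        pile = _pileup({3: {"Ld": {"A": 1, "G": 6}, "Td": {"G": 6}}})
        assert call_variable_sites(pile) == []

    def test_monomorphic_site_not_variable(self):
        pile = _pileup({3: {"Ld": {"G": 10}, "Td": {"G": 10}}})
        assert call_variable_sites(pile) == []

    def test_one_stray_read_per_accession_not_variable(self):
        # pooled support 2 but never 2 within one line: stray mismatches
        pile = _pileup({3: {"Ld": {"G": 20, "T": 1}, "Td": {"G": 18, "T": 1}}})
        assert call_variable_sites(pile) == []

    def test_low_frequency_doublet_not_variable(self):
        # 2 reads under a deep column fail the frequency gate
        pile = _pileup({3: {"Ld": {"G": 40, "T": 2}, "Td": {"G": 30}}})
        assert call_variable_sites(pile) == []

    def test_reciprocal_pattern_enters(self):
        pile = _pileup({3: {"Ld": {"A": 10}, "Td": {"G": 12}}})
        (site,) = call_variable_sites(pile)
        assert site.is_ivs == {"Ld": False, "Td": False}

    def test_excluded_target_skipped(self):
        pile = _pileup({3: {"Ld": {"A": 5, "G": 6}, "Td": {"G": 9}}})
        assert call_variable_sites(pile, exclude_targets={"t"}) == []


def _summaries(mdcs):
    return {f"g{i}": CoverageSummary(f"g{i}", {"Ld": m, "Td": m}, m, 1.0, 1.0)
            for i, m in enumerate(mdcs)}


class TestMdcTargetFilter:
    def test_percentile_cutoff_matches_oracle(self):
        summaries = _summaries(range(1, 101))
        cutoff, excluded = mdc_target_filter(summaries, list(summaries))
        assert cutoff == pytest.approx(np.percentile(np.arange(1, 101), 99))
        assert excluded == {"g99"}  # only MDC 100 >= 99.01

    def test_override_is_inclusive_at_the_boundary(self):
        summaries = _summaries([10, 61, 80])
        cfg = ClassifierConfig(mdc_cutoff_override=61)
        cutoff, excluded = mdc_target_filter(summaries, list(summaries), cfg)
        assert cutoff == 61 and excluded == {"g1", "g2"}

    def test_no_target_above_cutoff(self):
        summaries = _summaries([5, 6, 7])
        cfg = ClassifierConfig(mdc_cutoff_override=100)
        _, excluded = mdc_target_filter(summaries, list(summaries), cfg)
        assert excluded == set()

    def test_empty_single_copy_set_rejected(self):
        with pytest.raises(ValueError):
            mdc_target_filter(_summaries([5]), [])


class TestLog2Ratio:
    @pytest.mark.parametrize("ref_n,alt_n,expected", [
        (8, 2, 2.0), (5, 5, 0.0), (2, 8, -2.0),
    ])
    def test_reference_over_alternative(self, ref_n, alt_n, expected):
        site = _site({"A": ref_n, "G": alt_n}, {"A": 1, "G": 1}, ref_base="A")
        assert log2_variant_ratio(site, "Ld") == pytest.approx(expected)

    def test_zero_count_guarded(self):
        site = _site({"A": 8}, {"A": 4, "G": 4}, ref_base="A", alleles=("A", "G"))
        with pytest.raises(ValueError):
            log2_variant_ratio(site, "Ld")


class TestCalibration:
    def test_separated_samples_give_largest_true_value(self):
        u = calibrate_ratio_thresholds([0.2, 0.5, 1.0], [4.0, 4.5, 5.0])
        assert u == 1.0  # largest candidate below the false cluster

    def test_empty_false_set_returns_max_true(self):
        assert calibrate_ratio_thresholds([0.1, 0.9, 2.2], []) == 2.2

    def test_interleaved_vectors_match_exhaustive_scan(self):
        true_r = [0.1, 0.3, 0.5, 0.9, 1.1, 1.3, 1.8, 2.2, 2.6, 3.0]
        false_r = [0.8, 1.6, 2.4, 3.1, 3.5, 3.9, 4.2, 4.6, 5.0, 5.4]

        def oracle(target_rate):
            best = None
            for u in sorted(set(true_r + false_r)):
                nt = sum(1 for v in true_r if v <= u)
                nf = sum(1 for v in false_r if v <= u)
                if nt + nf and nf / (nt + nf) <= target_rate:
                    best = u
            return best

        for rate in (0.05, 0.10, 0.25, 0.5):
            assert calibrate_ratio_thresholds(true_r, false_r, rate) == oracle(rate)

    def test_unattainable_rate_warns_and_returns_minimum(self):
        with pytest.warns(UserWarning):
            u = calibrate_ratio_thresholds([2.0, 3.0], [1.0, 1.5], 0.01)
        assert u == 1.0

    def test_mixture_calibration_controls_false_rate_on_fresh_draw(self):
        rng_train = np.random.default_rng(100)
        rng_test = np.random.default_rng(200)
        t_tr, f_tr = simulate_ivs_ratio_mixture(2000, 500, rng=rng_train)
        u = calibrate_ratio_thresholds(t_tr, f_tr, 0.05)
        t_te, f_te = simulate_ivs_ratio_mixture(2000, 500, rng=rng_test)
        n_t = (t_te <= u).sum()
        n_f = (f_te <= u).sum()
        assert n_f / (n_t + n_f) <= 0.05


class TestClassifySite:
    def test_snp_orientation_shared_allele_is_ancestral(self):
        site = _site({"A": 6, "G": 7}, {"G": 15}, ref_base="G")
        call = classify_site(site, LOOSE)
        assert call.label == LABEL_SNP
        assert (call.lineage, call.derived, call.ancestral) == ("Ld", "A", "G")

    def test_gss_when_both_lines_are_ivs(self):
        site = _site({"C": 5, "T": 6}, {"C": 7, "T": 4}, ref_base="C")
        assert classify_site(site, LOOSE).label == LABEL_GSS

    def test_low_monomorphic_coverage_filtered(self):
        site = _site({"A": 6, "G": 7}, {"G": 6}, ref_base="G")
        call = classify_site(site, LOOSE)
        assert (call.label, call.filter_reason) == (LABEL_FILTERED, REASON_LOW_MONO)

    def test_triallelic_filtered(self):
        site = _site({"A": 6, "G": 7}, {"T": 9, "G": 2}, ref_base="G")
        call = classify_site(site, LOOSE)
        assert call.filter_reason == REASON_TRIALLELIC

    def test_skewed_ratio_filtered(self):
        cfg = ClassifierConfig(log2_upper={"Ld": 1.6, "Td": 1.0})
        site = _site({"G": 24, "A": 2}, {"G": 15}, ref_base="G")  # ratio 3.58
        call = classify_site(site, cfg)
        assert call.filter_reason == REASON_RATIO

    def test_accession_swap_symmetry(self, rng):
        cfg = ClassifierConfig(log2_upper={"Ld": 3.0, "Td": 3.0})
        for _ in range(50):
            d1 = {b: int(n) for b, n in
                  zip("AG", rng.integers(0, 12, 2)) if n > 0}
            d2 = {b: int(n) for b, n in
                  zip("AG", rng.integers(0, 12, 2)) if n > 0}
            pooled = {}
            for c in (d1, d2):
                for b, n in c.items():
                    pooled[b] = pooled.get(b, 0) + n
            if len([b for b, n in pooled.items() if n >= 2]) < 2:
                continue
            fwd = classify_site(_site(d1, d2, ref_base="G"), cfg)
            swp = classify_site(_site(d2, d1, ref_base="G"), cfg)
            assert fwd.label == swp.label
            if fwd.label == LABEL_SNP:
                assert {fwd.lineage, swp.lineage} == {"Ld", "Td"}
                assert fwd.derived == swp.derived


class TestFlankRescue:
    REF = {"t": "ACGTTGCAGCAATCGGATTACCAGTGGCTAATCGATCGGCTATATCGGACGTTCAATGCC"}

    def _snp_call(self, pos=30, derived="T"):
        ref_base = self.REF["t"][pos]
        site = _site({ref_base: 6, derived: 7}, {ref_base: 15},
                     ref_base=ref_base, position=pos,
                     alleles=(ref_base, derived))
        return classify_site(site, LOOSE)

    def test_hidden_variant_in_diverged_reads_is_found(self):
        call = self._snp_call(pos=30, derived="T")
        ref = self.REF["t"]
        window = ref[10:50]
        carrier = list(window)
        carrier[20] = "T"  # the missing second variant at the site
        for off in (2, 11, 35):  # three extra mismatches: still <= cap
            carrier[off] = {"A": "C", "C": "G", "G": "T", "T": "A"}[carrier[off]]
        cfg = ClassifierConfig(log2_upper={"Ld": 9, "Td": 9},
                               flank_max_mismatches=3)
        assert flank_rescue(call, ["".join(carrier)], self.REF, cfg)

    def test_true_snp_with_no_second_variant_not_rescued(self):
        call = self._snp_call(pos=30, derived="T")
        reads = [self.REF["t"][i:i + 40] for i in (0, 10, 20)]
        assert not flank_rescue(call, reads, self.REF, LOOSE)

    def test_empty_read_pool_not_rescued(self):
        call = self._snp_call()
        assert not flank_rescue(call, [], self.REF, LOOSE)

    def test_reverse_strand_carrier_found(self):
        from polycap.synthetic_tetraploid import revcomp

        call = self._snp_call(pos=30, derived="T")
        window = list(self.REF["t"][12:52])
        window[18] = "T"
        assert flank_rescue(call, [revcomp("".join(window))], self.REF, LOOSE)


class TestTheory:
    def test_reproduces_printed_point_estimate(self):
        t = TheoryParams(lambda_cov=13.0, divergence_d=0.02,
                         target_length_L=3_500_000)
        assert expected_missed_variant_sites(t) == pytest.approx(0.3167, abs=5e-4)
        assert round(expected_missed_variant_sites(t), 1) == 0.3

    def test_vanishes_at_high_coverage(self):
        t = TheoryParams(1000.0, 0.02, 3_500_000)
        assert expected_missed_variant_sites(t) == pytest.approx(0.0, abs=1e-12)

    def test_probability_capped_at_one(self):
        t = TheoryParams(math.log(2), 0.02, 5000)  # 2 exp(-lambda) = 1
        assert expected_missed_variant_sites(t) == pytest.approx(100.0)

    def test_nonpositive_lambda_rejected(self):
        with pytest.raises(ValueError):
            expected_missed_variant_sites(TheoryParams(0.0, 0.02, 100))

    def test_strictly_decreasing_in_lambda(self):
        values = [expected_missed_variant_sites(TheoryParams(l, 0.02, 3.5e6))
                  for l in np.linspace(0.5, 20, 40)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestValidationConfusion:
    def test_gss_sanger_counts(self):
        called = {("g", i) for i in range(97)}
        truth = {("g", i) for i in range(96)} | {("x", i) for i in range(187)}
        out = validation_confusion(called, truth)
        assert out["shared"] == 96
        assert out["false_positive_rate"] == pytest.approx(1 / 97)
        assert out["false_negative_rate"] == pytest.approx(187 / 283)
        assert round(100 * out["false_negative_rate"]) == 66

    def test_perfect_agreement(self):
        s = {("g", 1), ("g", 2)}
        out = validation_confusion(s, s)
        assert out["false_positive_rate"] == 0.0
        assert out["false_negative_rate"] == 0.0

    def test_snp_sanger_counts(self):
        called = {("g", i) for i in range(43)}
        truth = {("g", i) for i in range(30)} | {("y", i) for i in range(28)}
        out = validation_confusion(called, truth)
        assert out["false_positive_rate"] == pytest.approx(13 / 43)

    def test_empty_called_set_undefined_fpr(self):
        out = validation_confusion(set(), {("g", 1)})
        assert out["false_positive_rate"] is None
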