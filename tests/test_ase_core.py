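"""Bias estimation, the exact two-sided binomial test, and the QC cascade."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from tissue_ase import (Assay, BiasModel, FilterFlag, FilterParams,
                        binom_pvalues_two_sided, binomial_ase_test, call_ase,
                        estimate_reference_bias)
from conftest import make_record


def brute_force_two_sided(k, n, p):
    """Oracle: enumerate all outcomes, sum those no more likely than k."""
    pmf = [math.comb(n, j) * p**j * (1 - p)**(n - j) for j in range(n + 1)]
    cutoff = pmf[k] * (1 + 1e-7)
    return min(1.0, sum(x for x in pmf if x <= cutoff))


class TestBiasEstimation:
    def test_symmetric_counts_give_half(self):
        recs = [make_record(site_id=f"s{i}", ref=50, alt=50) for i in range(2)]
        model = estimate_reference_bias(recs, scope="global")
        assert model.p_ref[("*", "*")] == pytest.approx(0.5)

    def test_pooled_ratio(self):
        recs = [make_record(site_id="a", ref=60, alt=40),
                make_record(site_id="b", ref=54, alt=46)]
        model = estimate_reference_bias(recs, scope="global")
        assert model.p_ref[("*", "*")] == pytest.approx(0.57)

    def test_monte_carlo_recovery(self):
        """10,000 null sites at depth 100, true ref probability 0.55."""
        rng = np.random.default_rng(42)
        refs = rng.binomial(100, 0.55, size=10_000)
        recs = [make_record(site_id=f"s{i}", ref=int(r), alt=int(100 - r))
                for i, r in enumerate(refs)]
        model = estimate_reference_bias(recs, scope="global")
        assert model.p_ref[("*", "*")] == pytest.approx(0.55, abs=0.005)

    def test_depth_failing_records_excluded(self):
        # the shallow record would drag the estimate to 0.75 if included
        recs = [make_record(site_id="deep", ref=50, alt=50),
                make_record(site_id="shallow", ref=10, alt=0)]
        model = estimate_reference_bias(recs, scope="global")
        assert model.p_ref[("*", "*")] == pytest.approx(0.5)

    def test_no_passing_records_errors(self):
        with pytest.raises(ValueError, match="insufficient data"):
            estimate_reference_bias([make_record(ref=2, alt=1)])

    def test_sample_scope_separates_tissues(self):
        recs = [make_record(site_id=f"a{i}", tissue="liver", ref=60, alt=40)
                for i in range(3)]
        recs += [make_record(site_id=f"b{i}", tissue="heart", ref=50, alt=50)
                 for i in range(3)]
        model = estimate_reference_bias(recs, scope="sample")
        assert model.p_ref[("liver", "mmpcr")] == pytest.approx(0.6)
        assert model.p_ref[("heart", "mmpcr")] == pytest.approx(0.5)


class TestBinomialTest:
    @pytest.mark.parametrize("ref,alt,p,expected", [
        (10, 10, 0.5, 1.0),
        (20, 0, 0.5, 2 * 0.5**20),
        (15, 5, 0.5, 0.04138946533203125),
    ])
    def test_frozen_examples(self, ref, alt, p, expected):
        assert binomial_ase_test(ref, alt, p) == pytest.approx(expected, rel=1e-9)

    def test_matches_brute_force_over_all_small_totals(self):
        """Exhaustive oracle equivalence: every (k, n<=50, p)."""
        for p in (0.3, 0.5, 0.55, 0.7):
            for n in range(1, 51):
                ks = np.arange(n + 1)
                got = binom_pvalues_two_sided(ks, np.full(n + 1, n), p)
                want = [brute_force_two_sided(int(k), n, p) for k in ks]
                np.testing.assert_allclose(got, want, rtol=1e-9, atol=1e-300)

    def test_matches_scipy_binomtest(self):
        """Independent library cross-check on assorted cases."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(1, 400))
            k = int(rng.integers(0, n + 1))
            p = float(rng.uniform(0.2, 0.8))
            ours = binomial_ase_test(k, n - k, p)
            ref = stats.binomtest(k, n, p).pvalue
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)

    @given(st.integers(0, 60), st.integers(0, 60), st.integers(1, 63))
    @settings(max_examples=120, deadline=None)
    def test_symmetry(self, a, b, sixtyfourths):
        """test(a, b, p) == test(b, a, 1-p) exactly (allele relabeling).

        p is drawn on a dyadic grid so 1 - p is exactly representable;
        the identity is then bitwise, not approximate.
        """
        if a + b == 0:
            return
        p = sixtyfourths / 64
        assert binomial_ase_test(a, b, p) == binomial_ase_test(b, a, 1 - p)

    def test_invalid_p_rejected(self):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                binomial_ase_test(5, 5, bad)

    def test_type_one_error_near_nominal(self):
        """Null counts at depth 200 with known p: rejection rate ~ alpha.

        The discrete test is conservative, so the rate sits at or below
        the nominal 0.05 but should not be far below it.
        """
        rng = np.random.default_rng(2024)
        p_ref = 0.55
        refs = rng.binomial(200, p_ref, size=10_000)
        pv = binom_pvalues_two_sided(refs, np.full(10_000, 200), p_ref)
        rate = float((pv < 0.05).mean())
        assert 0.035 <= rate <= 0.065


def global_bias(p=0.5):
    return BiasModel(scope="global", p_ref={("*", "*"): p})


class TestCallASE:
    def test_allele_depth_flag(self, site_map):
        (call,) = call_ase([make_record(ref=4, alt=30)], site_map, global_bias())
        assert FilterFlag.ALLELE_DEPTH in call.filter_flags
        assert not call.qc_pass

    def test_total_depth_flag(self, site_map):
        (call,) = call_ase([make_record(ref=12, alt=6)], site_map, global_bias())
        assert FilterFlag.TOTAL_DEPTH in call.filter_flags
        assert FilterFlag.ALLELE_DEPTH not in call.filter_flags

    def test_biallelic_flag(self, site_map):
        (call,) = call_ase([make_record(ref=100, alt=100, other=30)],
                           site_map, global_bias())
        assert FilterFlag.BIALLELIC in call.filter_flags  # 30/230 > 0.05

    def test_intragenic_flag(self, site_map):
        (call,) = call_ase([make_record(site_id="s3", ref=100, alt=100)],
                           site_map, global_bias())
        assert FilterFlag.INTRAGENIC in call.filter_flags
        relaxed = FilterParams(require_intragenic=False)
        (call2,) = call_ase([make_record(site_id="s3", ref=100, alt=100)],
                            site_map, global_bias(), relaxed)
        assert call2.qc_pass

    def test_strong_ase_called(self, site_map):
        (call,) = call_ase([make_record(ref=180, alt=20)], site_map, global_bias())
        assert call.qc_pass and call.is_ase
        assert call.p_value < 1e-30
        assert call.allelic_ratio == pytest.approx(0.1)

    def test_mmpcr_alpha_stricter_than_rna(self, site_map):
        # pick counts with p-value between 0.01 and 0.05
        rec_rna = make_record(ref=63, alt=40, assay=Assay.RNA_SEQ)
        rec_mm = make_record(ref=63, alt=40, assay=Assay.MMPCR)
        (c_rna,) = call_ase([rec_rna], site_map, global_bias())
        (c_mm,) = call_ase([rec_mm], site_map, global_bias())
        assert 0.01 < c_rna.p_value < 0.05
        assert c_rna.is_ase and not c_mm.is_ase

    def test_unknown_site_errors(self, site_map):
        with pytest.raises(KeyError, match="unknown sites"):
            call_ase([make_record(site_id="nope")], site_map, global_bias())

    def test_filter_monotonicity(self, site_map, default_dataset):
        """Tightening any threshold can only shrink the qc-pass set."""
        records = default_dataset.records_for(Assay.MMPCR)[:500]
        sites = default_dataset.sites
        bias = estimate_reference_bias(records)
        loose = FilterParams()
        passing = {c.site_id + c.tissue_id + c.replicate_id
                   for c in call_ase(records, sites, bias, loose) if c.qc_pass}
        for tight in (FilterParams(min_allele_depth=50),
                      FilterParams(min_total_depth=2000),
                      FilterParams(max_other_fraction=0.0001)):
            tighter = {c.site_id + c.tissue_id + c.replicate_id
                       for c in call_ase(records, sites, bias, tight) if c.qc_pass}
            assert tighter <= passing

    def test_table_s3_style_depth_variant_configurable(self, site_map):
        """The alternative single 10-read total-depth rule is reachable."""
        params = FilterParams(min_allele_depth=0, min_total_depth=10)
        (call,) = call_ase([make_record(ref=11, alt=1)], site_map,
                           global_bias(), params)
        assert call.qc_pass
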