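"""Cohort contrasts: DNA-bias filter, frequency strata, t-tests, Fisher."""

import math

import numpy as np
import pytest

from tissue_ase import (ASEClass, Assay, HetSite, VariantClass, compare_groups,
                        dna_bias_filter, fisher_enrichment, fisher_exact_2x2,
                        stratify_by_frequency)
from tissue_ase.ase_core import ASECall
from test_cross_tissue import make_call, make_profile


def brute_force_fisher(table):
    """Oracle: enumerate all 2x2 tables with the observed margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def hyper(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)) / math.comb(n, c1)

    obs = hyper(a) * (1 + 1e-7)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(hyper(x) for x in range(lo, hi + 1) if hyper(x) <= obs)


def nonsense_site(i, maf=None, private=False):
    return HetSite(site_id=f"n{i}", chrom="1", pos=i + 1, ref_base="A",
                   alt_base="T", variant_class=VariantClass.NONSENSE,
                   maf=maf, is_private=private)


def dna_call(site_id, ratio, tissue="frontal_lobe"):
    n = 100
    alt = int(round(ratio * n))
    return ASECall(site_id=site_id, tissue_id=tissue, replicate_id="rep1",
                   assay=Assay.EXOME_DNA, ref_count=n - alt, alt_count=alt,
                   other_count=0, allelic_ratio=ratio, p_value=0.5,
                   qc_pass=True)


class TestDnaBiasFilter:
    def test_low_in_all_samples_removed(self):
        site = nonsense_site(0)
        calls = [dna_call("n0", 0.15, "frontal_lobe"), dna_call("n0", 0.18, "small_intestine")]
        assert dna_bias_filter([site], calls) == []

    def test_one_sample_above_threshold_retained(self):
        site = nonsense_site(0)
        calls = [dna_call("n0", 0.15, "frontal_lobe"), dna_call("n0", 0.45, "small_intestine")]
        assert dna_bias_filter([site], calls) == [site]

    def test_balanced_dna_retained(self):
        site = nonsense_site(0)
        calls = [dna_call("n0", 0.5, "frontal_lobe"), dna_call("n0", 0.5, "small_intestine")]
        assert dna_bias_filter([site], calls) == [site]

    def test_non_nonsense_passes_through(self):
        site = HetSite(site_id="c0", chrom="1", pos=5, ref_base="A", alt_base="G")
        calls = [dna_call("c0", 0.05)]
        assert dna_bias_filter([site], calls) == [site]

    def test_missing_dna_call_retained_with_warning(self):
        site = nonsense_site(0)
        with pytest.warns(UserWarning, match="no usable DNA call"):
            assert dna_bias_filter([site], []) == [site]

    def test_removal_set_shrinks_as_threshold_decreases(self):
        sites = [nonsense_site(i) for i in range(20)]
        rng = np.random.default_rng(8)
        calls = [dna_call(s.site_id, float(r), t)
                 for s in sites
                 for t, r in zip(("frontal_lobe", "small_intestine"),
                                 rng.uniform(0, 0.6, 2))]
        kept_strict = {s.site_id for s in dna_bias_filter(sites, calls, 0.3)}
        kept_loose = {s.site_id for s in dna_bias_filter(sites, calls, 0.1)}
        assert kept_strict <= kept_loose


class TestStratifyByFrequency:
    def test_partition(self):
        sites = [nonsense_site(0, maf=0.12), nonsense_site(1, maf=0.01),
                 nonsense_site(2, private=True)]
        strata = stratify_by_frequency(sites)
        assert [s.site_id for s in strata["common"]] == ["n0"]
        assert [s.site_id for s in strata["rare"]] == ["n1", "n2"]

    def test_absent_maf_not_private_warns_rare(self):
        site = nonsense_site(0)
        with pytest.warns(UserWarning, match="no MAF"):
            strata = stratify_by_frequency([site])
        assert strata["rare"] == [site]

    def test_cutoff_boundary_is_rare(self):
        strata = stratify_by_frequency([nonsense_site(0, maf=0.05)])
        assert len(strata["rare"]) == 1  # common requires maf strictly > 0.05


class TestCompareGroups:
    def control(self, i):
        return HetSite(site_id=f"c{i}", chrom="1", pos=100 + i, ref_base="A",
                       alt_base="G")

    def test_identical_groups_t_zero_p_one(self):
        sites = [self.control(0), nonsense_site(0, maf=0.2)]
        calls = [make_call(site="c0", tissue=t, ratio=r) for t, r in
                 zip("ab", (0.4, 0.6))]
        calls += [make_call(site="n0", tissue=t, ratio=r) for t, r in
                  zip("ab", (0.4, 0.6))]
        res = compare_groups(calls, sites, per_tissue=False)
        (cmp,) = [r for r in res if {r.group_a, r.group_b} == {"control", "nonsense"}]
        assert cmp.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp.p_value == pytest.approx(1.0)

    def test_separated_groups_strongly_significant(self):
        rng = np.random.default_rng(77)
        sites, calls = [], []
        for i in range(30):
            sites.append(self.control(i))
            calls.append(make_call(site=f"c{i}", tissue="liver",
                                   ratio=float(np.clip(rng.normal(0.50, 0.05), 0, 1))))
        for i in range(30):
            sites.append(nonsense_site(i, private=True))
            calls.append(make_call(site=f"n{i}", tissue="liver",
                                   ratio=float(np.clip(rng.normal(0.25, 0.05), 0, 1))))
        res = compare_groups(calls, sites, pairs=[("control", "nonsense")])
        assert res[0].p_value < 1e-10
        assert res[0].mean_ratio_a > res[0].mean_ratio_b

    def test_insufficient_group_reported_without_p(self):
        sites = [self.control(0), nonsense_site(0, maf=0.2)]
        calls = [make_call(site="c0", tissue="a", ratio=0.5),
                 make_call(site="c0", tissue="b", ratio=0.5),
                 make_call(site="n0", tissue="a", ratio=0.2)]
        res = compare_groups(calls, sites, per_tissue=False)
        (cmp,) = [r for r in res if {r.group_a, r.group_b} == {"control", "nonsense"}]
        assert cmp.n_b == 1 and cmp.p_value is None
        assert cmp.mean_ratio_b == pytest.approx(0.2)

    def test_relabel_invariance(self):
        rng = np.random.default_rng(9)
        sites, calls = [], []
        for i in range(10):
            sites.append(self.control(i))
            calls.append(make_call(site=f"c{i}", ratio=float(rng.uniform(0.3, 0.7))))
            sites.append(nonsense_site(i, maf=0.2))
            calls.append(make_call(site=f"n{i}", ratio=float(rng.uniform(0.1, 0.5))))
        ab = compare_groups(calls, sites, pairs=[("control", "nonsense")])[0]
        ba = compare_groups(calls, sites, pairs=[("nonsense", "control")])[0]
        assert ab.p_value == pytest.approx(ba.p_value)
        assert ab.t_statistic == pytest.approx(-ba.t_statistic)

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError, match="grouping"):
            compare_groups([], [], grouping="nope")


class TestFisher:
    def test_reconstructed_study_table(self):
        """Deleterious fraction: 22/52 in shared ASE vs 43/172 in no ASE."""
        odds, p, corrected = fisher_exact_2x2([[22, 30], [43, 129]])
        assert p == pytest.approx(0.0228, abs=5e-4)
        assert not corrected and odds == pytest.approx(22 * 129 / (30 * 43))

    def test_uniform_table(self):
        odds, p, _ = fisher_exact_2x2([[10, 10], [10, 10]])
        assert odds == 1.0 and p == pytest.approx(1.0)

    def test_diagonal_table_enumeration(self):
        _, p, corrected = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252)
        assert corrected  # zero cells make ad/bc undefined

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(80):
            table = rng.integers(0, 16, size=(2, 2))
            if table.sum() == 0:
                continue
            _, p, _ = fisher_exact_2x2(table.tolist())
            assert p == pytest.approx(brute_force_fisher(table.tolist()),
                                      rel=1e-9, abs=1e-12)

    def test_enrichment_from_profiles(self):
        profiles, sites = [], []
        spec = [("shared_ase", True, 22), ("shared_ase", False, 30),
                ("no_ase", True, 43), ("no_ase", False, 129)]
        i = 0
        for label, deleterious, count in spec:
            for _ in range(count):
                sid = f"s{i}"
                prof = make_profile([0.2, 0.2, 0.2], site=sid)
                object.__setattr__(prof, "class_label", ASEClass(label))
                profiles.append(prof)
                sites.append(HetSite(
                    site_id=sid, chrom="1", pos=i + 1, ref_base="A", alt_base="G",
                    variant_class=VariantClass.DELETERIOUS_NSSNP if deleterious
                    else VariantClass.CONTROL))
                i += 1
        res = fisher_enrichment(profiles, sites, "shared_ase", "no_ase")
        assert res.table == ((22, 30), (43, 129))
        assert res.p_value == pytest.approx(0.0228, abs=5e-4)

    def test_empty_class_errors(self):
        prof = make_profile([0.5, 0.5, 0.5], site="s0")
        object.__setattr__(prof, "class_label", ASEClass.NO_ASE)
        site = HetSite(site_id="s0", chrom="1", pos=1, ref_base="A", alt_base="G")
        with pytest.raises(ValueError, match="empty"):
            fisher_enrichment([prof], [site], "shared_ase", "no_ase")
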