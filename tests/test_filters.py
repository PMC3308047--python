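"""Site-level filter rules of both calling pipelines."""

import numpy as np
import pytest

from exonpop import FilterConfig, allele_balance, bc_filter, bi_filter, hrun
from exonpop.errors import AnnotationError, ConfigError
from exonpop.filters import snp_cluster_keys


class TestBcFilter:
    def make(self, site_factory, quality, genotypes, gq):
        return site_factory(quality=quality, genotypes=genotypes, gq=gq)

    def test_confident_het_kept(self, site_factory):
        s = self.make(site_factory, 50, (0, 1, 0), (99, 20, 99))
        assert bc_filter([s]) == [s]

    def test_low_quality_removed(self, site_factory):
        s = self.make(site_factory, 39, (0, 1, 1), (99, 99, 99))
        assert bc_filter([s]) == []

    def test_requires_a_nonreference_genotype(self, site_factory):
        s = self.make(site_factory, 50, (0, 0, 0), (99, 99, 99))
        assert bc_filter([s]) == []

    def test_low_gq_carrier_not_enough(self, site_factory):
        s = self.make(site_factory, 50, (0, 1, 0), (99, 9, 99))
        assert bc_filter([s]) == []

    def test_missing_quality_is_annotation_error(self, site_factory):
        s = self.make(site_factory, None, (0, 1, 0), (99, 99, 99))
        with pytest.raises(AnnotationError):
            bc_filter([s])


class TestHrun:
    def test_scan_from_spec_example(self, site_factory):
        # ref CAAAAT, SNP C->A at the first base: run of 4 A's to the right
        s = site_factory(pos=1, ref="C", alt="A")
        assert hrun("CAAAAT", s) == 4

    def test_non_matching_run_is_zero(self, site_factory):
        s = site_factory(pos=3, ref="C", alt="G")
        assert hrun("AACAAAA", s) == 0

    def test_max_of_both_sides(self, site_factory):
        # TT [C->T] TTTTT: left run 2, right run 5
        s = site_factory(pos=3, ref="C", alt="T")
        assert hrun("TTCTTTTT", s) == 5

    def test_out_of_bounds(self, site_factory):
        with pytest.raises(IndexError):
            hrun("ACGT", site_factory(pos=10, ref="A", alt="G"))


class TestAlleleBalance:
    def test_single_het(self, site_factory):
        s = site_factory(genotypes=(0, 1, 0), ref_depths=(9, 9, 9),
                         alt_depths=(0, 1, 0))
        assert allele_balance(s) == pytest.approx(0.9)

    def test_balanced_hets(self, site_factory):
        s = site_factory(genotypes=(1, 1, 0), ref_depths=(5, 5, 9),
                         alt_depths=(5, 5, 0))
        assert allele_balance(s) == pytest.approx(0.5)

    def test_mean_over_hets(self, site_factory):
        s = site_factory(genotypes=(1, 1, 2), ref_depths=(8, 6, 0),
                         alt_depths=(2, 4, 10))
        assert allele_balance(s) == pytest.approx(0.7)

    def test_no_hets_is_undefined(self, site_factory):
        s = site_factory(genotypes=(0, 0, 2), ref_depths=(9, 9, 0),
                         alt_depths=(0, 0, 9))
        assert allele_balance(s) is None


class TestBiFilter:
    REF = "ACGTACGTACGT" * 50  # no long homopolymers anywhere

    def clean(self, site_factory, pos=100, qd=10.0):
        return site_factory(pos=pos, ref=self.REF[pos - 1],
                            alt={"A": "C", "C": "A", "G": "T", "T": "G"}[
                                self.REF[pos - 1]],
                            qd=qd, genotypes=(0, 1, 0), ref_depths=(9, 5, 9),
                            alt_depths=(0, 5, 0))

    def test_clean_site_kept(self, site_factory):
        s = self.clean(site_factory)
        assert bi_filter([s], self.REF) == [s]

    def test_low_qd_removed(self, site_factory):
        s = self.clean(site_factory, qd=4.9)
        assert bi_filter([s], self.REF) == []

    def test_high_ab_removed(self, site_factory):
        s = site_factory(pos=100, ref="T", alt="G", qd=10.0,
                         genotypes=(1, 1, 0), ref_depths=(8, 8, 9),
                         alt_depths=(2, 2, 0))  # AB = 0.8 >= 0.75
        assert bi_filter([s], self.REF) == []

    def test_no_het_site_passes_ab_rule(self, site_factory):
        s = site_factory(pos=100, ref="T", alt="G", qd=10.0,
                         genotypes=(0, 0, 2), ref_depths=(9, 9, 0),
                         alt_depths=(0, 0, 9))
        assert bi_filter([s], self.REF) == [s]

    def test_homopolymer_adjacent_removed(self, site_factory):
        ref = "C" + "G" * 200
        s = site_factory(pos=1, ref="C", alt="G", qd=10.0,
                         genotypes=(0, 1, 0), ref_depths=(9, 5, 9),
                         alt_depths=(0, 5, 0))
        assert bi_filter([s], ref) == []

    def test_cluster_of_three_within_ten_bases_removed(self, site_factory):
        sites = [self.clean(site_factory, pos=p) for p in (100, 104, 108)]
        assert bi_filter(sites, self.REF) == []

    def test_spread_sites_kept(self, site_factory):
        sites = [self.clean(site_factory, pos=p) for p in (100, 120, 140)]
        assert len(bi_filter(sites, self.REF)) == 3

    def test_rules_are_order_independent(self, site_factory):
        """The composite filter equals the intersection of single-rule
        survivor sets."""
        sites = [self.clean(site_factory, pos=p, qd=qd)
                 for p, qd in [(100, 10), (104, 4), (108, 12), (130, 9),
                               (200, 3), (300, 8)]]
        composite = {s.key for s in bi_filter(sites, self.REF)}
        cfg = FilterConfig()
        qd_ok = {s.key for s in sites if s.qd >= cfg.bi_min_qd}
        hrun_ok = {s.key for s in sites
                   if hrun(self.REF, s) <= cfg.bi_max_hrun}
        ab_ok = {s.key for s in sites
                 if (allele_balance(s) or 0.0) < cfg.bi_max_ab}
        clustered = snp_cluster_keys(sites, cfg.bi_cluster_n,
                                     cfg.bi_cluster_window)
        cluster_ok = {s.key for s in sites} - clustered
        assert composite == qd_ok & hrun_ok & ab_ok & cluster_ok


def test_filter_config_validation():
    with pytest.raises(ConfigError):
        FilterConfig(bi_max_ab=0.0).validate()
    with pytest.raises(ConfigError):
        FilterConfig(bc_min_quality=-1).validate()
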