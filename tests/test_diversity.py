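"""Heterozygosity, callability, spectra, projection, and Watterson's theta."""

import itertools
import math

import numpy as np
import pytest

from exonpop import (AFSpectrum, TargetRegions, build_afs, callable_mask,
                     fraction_in_bins, neutral_expectation, per_base_het,
                     project_afs, site_het, watterson_theta)
from exonpop.errors import (AnnotationError, DomainError,
                            UndefinedResultError)


def flat_targets(n_bases):
    return TargetRegions([("1", 0, n_bases)])


class TestCallableMask:
    def test_hundred_chromosome_rule(self):
        targets = flat_targets(2)
        depths = np.zeros((2, 60), dtype=int)
        depths[0, :] = 12           # 60 samples -> 120 chromosomes
        depths[1, :45] = 12         # 45 samples -> 90 chromosomes
        mask = callable_mask(depths, targets)
        assert mask.mask.tolist() == [True, False]
        assert mask.n_callable == 1

    def test_random_depths_match_brute_force(self):
        rng = np.random.default_rng(2)
        targets = flat_targets(300)
        depths = rng.integers(0, 30, size=(300, 70))
        mask = callable_mask(depths, targets, min_depth=10, min_chroms=100)
        for i in range(300):
            expected = 2 * sum(1 for d in depths[i] if d >= 10) >= 100
            assert mask.mask[i] == expected

    def test_shape_mismatch(self):
        with pytest.raises(DomainError):
            callable_mask(np.zeros((5, 3)), flat_targets(7))


class TestSiteHet:
    @pytest.mark.parametrize("j,n,expected", [
        (1, 2, 1.0), (0, 10, 0.0), (5, 10, 25 / 45), (10, 10, 0.0)])
    def test_worked_examples(self, j, n, expected):
        assert site_het(j, n) == pytest.approx(expected)

    def test_matches_pair_counting(self):
        for n in range(2, 16):
            for j in range(n + 1):
                alleles = [1] * j + [0] * (n - j)
                pairs = list(itertools.combinations(alleles, 2))
                frac = sum(a != b for a, b in pairs) / len(pairs)
                assert site_het(j, n) == pytest.approx(frac)

    def test_domain(self):
        with pytest.raises(DomainError):
            site_het(0, 1)
        with pytest.raises(DomainError):
            site_het(5, 4)


class TestPerBaseHet:
    def test_single_variant_over_ten_bases(self, site_factory):
        # j=1, n=4 -> het = 2*1*3/(4*3) = 0.5; over 10 bases -> 0.05
        site = site_factory(genotypes=(1, 0))
        assert per_base_het([site], 10) == pytest.approx(0.05)

    def test_no_variants_is_zero(self):
        assert per_base_het([], 10) == 0.0

    def test_zero_callable_bases(self):
        with pytest.raises(UndefinedResultError):
            per_base_het([], 0)

    def test_class_filter(self, site_factory):
        a = site_factory(genotypes=(0, 1, 0), site_class="silent")
        b = site_factory(genotypes=(0, 1, 0), site_class="missense", pos=200)
        only_a = per_base_het([a, b], 10, site_class="silent")
        assert only_a == pytest.approx(site_het(1, 6) / 10)


class TestBuildAfs:
    def test_unfolded_ancestral_ref(self, site_factory):
        s = site_factory(genotypes=(1, 1, 1), ancestral="A", ref="A")
        afs = build_afs([s], polarize=True)
        assert afs.n == 6 and afs.counts[3] == 1

    def test_unfolded_ancestral_alt_flips(self, site_factory):
        gt = (1, 1, 1, 0, 0)  # alt count 3 of n=10
        s = site_factory(genotypes=gt, ref="A", alt="G", ancestral="G")
        afs = build_afs([s], polarize=True)
        assert afs.counts[7] == 1

    def test_mismatched_ancestral_excluded(self, site_factory):
        s = site_factory(genotypes=(0, 1, 1), ref="A", alt="G", ancestral="C")
        t = site_factory(genotypes=(0, 1, 1), ref="A", alt="G", ancestral="A",
                         pos=200)
        afs = build_afs([s, t], polarize=True)
        assert afs.S == 1

    def test_folded_uses_minor_allele(self, site_factory):
        gt = (2, 2, 2, 1, 0)  # alt count 7 of 10
        s = site_factory(genotypes=gt)
        afs = build_afs([s], polarize=False)
        assert afs.counts[3] == 1 and not afs.polarized

    def test_polarize_without_ancestral_is_error(self, site_factory):
        with pytest.raises(AnnotationError):
            build_afs([site_factory(genotypes=(0, 1, 0))], polarize=True)


class TestProjection:
    def test_single_site_worked_example(self):
        counts = np.zeros(5)
        counts[2] = 1  # j=2 of n=4
        projected = project_afs(AFSpectrum(4, counts), 2)
        assert projected.counts == pytest.approx([1 / 6, 2 / 3, 1 / 6])

    def test_projection_to_self_is_identity(self):
        rng = np.random.default_rng(3)
        counts = rng.random(11)
        afs = AFSpectrum(10, counts)
        assert project_afs(afs, 10).counts == pytest.approx(counts)

    def test_mass_conservation(self):
        rng = np.random.default_rng(4)
        counts = rng.random(13)
        afs = AFSpectrum(12, counts)
        projected = project_afs(afs, 7)
        assert projected.counts.sum() == pytest.approx(counts.sum())

    def test_composition_consistency(self):
        rng = np.random.default_rng(5)
        afs = AFSpectrum(15, rng.random(16))
        direct = project_afs(afs, 6)
        via = project_afs(project_afs(afs, 10), 6)
        assert np.allclose(direct.counts, via.counts, atol=1e-12)

    def test_cannot_project_up(self):
        with pytest.raises(DomainError):
            project_afs(AFSpectrum(4, np.zeros(5)), 6)


class TestWattersonAndNeutral:
    def test_worked_examples(self):
        assert watterson_theta(10, 5) == pytest.approx(4.8)
        assert watterson_theta(0, 5) == 0.0
        assert watterson_theta(7, 2) == pytest.approx(7.0)

    def test_neutral_expectation_shape(self):
        afs = neutral_expectation(6.0, 10)
        assert afs.counts[2] == pytest.approx(3.0)
        # log-log slope of theta/i is -1 by construction
        i = np.arange(1, 10)
        slope = np.polyfit(np.log(i), np.log(afs.counts[1:10]), 1)[0]
        assert slope == pytest.approx(-1.0)

    def test_theta_inversion_identity(self):
        theta, n = 5.0, 12
        afs = neutral_expectation(theta, n)
        assert watterson_theta(afs.S, n) == pytest.approx(theta)


class TestFractionInBins:
    def test_counting_oracle(self, site_factory):
        rng = np.random.default_rng(6)
        sites = []
        for k in range(200):
            n = 50
            ac = int(rng.integers(1, n))
            gt = np.zeros(n, dtype=np.int8)
            gt[:ac // 2] = 2
            if ac % 2:
                gt[ac // 2] = 1
            sites.append(site_factory(pos=k + 1, genotypes=gt,
                                      known=bool(rng.integers(0, 2))))
        out = fraction_in_bins(sites, edges=(0.01, 0.1, 0.5))
        fracs = [v["fraction"] for v in out.values()]
        assert sum(fracs) == pytest.approx(1.0)
        low = sum(1 for s in sites if s.minor_freq() < 0.01)
        assert fracs[0] == pytest.approx(low / len(sites))

    def test_all_known_sites(self, site_factory):
        sites = [site_factory(pos=p, genotypes=(0, 1, 0), known=True)
                 for p in (1, 2, 3)]
        out = fraction_in_bins(sites)
        occupied = [v for v in out.values() if v["fraction"] > 0]
        assert all(v["known_fraction"] == pytest.approx(1.0) for v in occupied)

    def test_empty_input(self):
        with pytest.raises(UndefinedResultError):
            fraction_in_bins([])
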