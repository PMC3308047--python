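"""Minor-allele sharing: exact combinatorics, down-sampling, bootstrap."""

import numpy as np
import pytest

from exonpop import (DownsampleSpec, SamplePanel, bootstrap_ci,
                     downsampled_sharing, panmictic_expectation, site_sharing)
from exonpop.errors import ConfigError, DomainError, UndefinedResultError


@pytest.fixture
def two_continent_panel():
    s2p = {f"{p}{i}": p for p in "AB" for i in range(3)}
    s2p.update({f"C{i}": "C" for i in range(3)})
    return SamplePanel(s2p, {"A": "Africa", "B": "Africa", "C": "Europe"})


class TestSiteSharing:
    def test_all_in_one_population(self, two_continent_panel):
        assert site_sharing({"A": 2}, two_continent_panel) == (1.0, 0.0, 0.0)

    def test_pair_on_same_continent(self, two_continent_panel):
        assert site_sharing({"A": 1, "B": 1}, two_continent_panel) == (
            0.0, 1.0, 0.0)

    def test_cross_continent_example(self, two_continent_panel):
        p = site_sharing({"A": 2, "C": 1}, two_continent_panel)
        assert p == pytest.approx((1 / 3, 0.0, 2 / 3))

    def test_singleton_is_an_error(self, two_continent_panel):
        with pytest.raises(DomainError):
            site_sharing({"A": 1}, two_continent_panel)

    def test_probabilities_sum_to_one(self, two_continent_panel):
        rng = np.random.default_rng(0)
        for _ in range(200):
            counts = {p: int(c) for p, c in
                      zip("ABC", rng.integers(0, 6, 3)) if c}
            if sum(counts.values()) < 2:
                continue
            p = site_sharing(counts, two_continent_panel)
            assert sum(p) == pytest.approx(1.0, abs=1e-12)


class TestPanmicticExpectation:
    def test_two_pops_same_continent(self, two_continent_panel):
        p = panmictic_expectation({"A": 2, "B": 2}, two_continent_panel)
        assert p == pytest.approx((1 / 3, 2 / 3, 0.0))

    def test_one_population(self, two_continent_panel):
        assert panmictic_expectation({"A": 5}, two_continent_panel) == (
            1.0, 0.0, 0.0)

    def test_equal_sizes_limit_to_one_over_k(self):
        panel = SamplePanel({f"p{k}": f"P{k}" for k in range(4)},
                            {f"P{k}": "X" for k in range(4)})
        sizes = {f"P{k}": 100_000 for k in range(4)}
        p_same, _, _ = panmictic_expectation(sizes, panel)
        assert p_same == pytest.approx(0.25, abs=1e-4)


class TestDownsampledSharing:
    def hets(self, site_factory, panel, per_pop):
        """A site with the requested per-population het carrier counts."""
        gt = np.zeros(len(panel), dtype=np.int8)
        for pop, c in per_pop.items():
            idx = panel.indices_by_population()[pop][:c]
            gt[idx] = 1
        return site_factory(genotypes=gt)

    def test_degenerate_spec_equals_mean_site_sharing(
            self, site_factory, two_continent_panel):
        panel = two_continent_panel
        sites = [self.hets(site_factory, panel, {"A": 2, "B": 1}),
                 self.hets(site_factory, panel, {"A": 2, "C": 2})]
        spec = DownsampleSpec(m={p: 6 for p in panel.populations})
        est = downsampled_sharing(sites, spec, panel, edges=(0.9, 0.99),
                                  bin_labels=("all", "x", "y"))
        expected = np.mean([site_sharing({"A": 2, "B": 1}, panel),
                            site_sharing({"A": 2, "C": 2}, panel)], axis=0)
        assert est.estimates[0] == pytest.approx(expected)
        assert est.n_sites[0] == 2

    def test_single_site_weight_example(self, site_factory):
        """{A:2 of 4 chroms, m=2}: conditional sharing 1 with weight
        C(2,2)C(2,0)/C(4,2) = 1/6."""
        panel = SamplePanel({"x1": "A", "x2": "A"}, {"A": "Af"})
        site = site_factory(genotypes=(1, 1))
        extra = site_factory(genotypes=(1, 1), pos=200)
        spec = DownsampleSpec(m={"A": 2}, method="exact")
        est = downsampled_sharing([site, extra], spec, panel,
                                  edges=(0.9, 0.99),
                                  bin_labels=("all", "x", "y"))
        assert est.estimates[0] == pytest.approx((1.0, 0.0, 0.0))

    def test_singletons_dropped(self, site_factory, two_continent_panel):
        panel = two_continent_panel
        sites = [self.hets(site_factory, panel, {"A": 1})]
        spec = DownsampleSpec(m={p: 6 for p in panel.populations})
        est = downsampled_sharing(sites, spec, panel)
        assert est.n_sites.sum() == 0

    def test_oversized_spec_rejected(self, two_continent_panel):
        spec = DownsampleSpec(m={"A": 7})
        with pytest.raises(ConfigError):
            spec.validate(two_continent_panel)

    def test_estimates_sum_to_one_per_bin(self, site_factory,
                                          two_continent_panel):
        panel = two_continent_panel
        rng = np.random.default_rng(1)
        sites = []
        for k in range(30):
            per_pop = {p: int(c) for p, c in zip("ABC", rng.integers(0, 3, 3))}
            if sum(per_pop.values()) < 2:
                continue
            sites.append(self.hets(site_factory, panel, per_pop))
        spec = DownsampleSpec(m={p: 4 for p in panel.populations},
                              method="exact")
        est = downsampled_sharing(sites, spec, panel)
        for b in range(3):
            if est.n_sites[b]:
                assert est.estimates[b].sum() == pytest.approx(1.0, abs=1e-12)


class TestBootstrap:
    def test_identical_sites_give_zero_width_ci(self, site_factory):
        sites = [site_factory(genotypes=(1, 1, 0), pos=p) for p in (1, 2, 3)]
        lo, hi = bootstrap_ci(sites,
                              lambda ss: np.array([len(ss)], dtype=float),
                              B=200, seed=0)
        assert lo == pytest.approx(hi)

    def test_deterministic_under_seed(self, site_factory):
        rng = np.random.default_rng(2)
        sites = [site_factory(pos=p, genotypes=rng.integers(0, 3, 6))
                 for p in range(1, 40)]
        est = lambda ss: np.array([np.mean([s.alt_count() for s in ss])])
        assert bootstrap_ci(sites, est, B=300, seed=9) == pytest.approx(
            bootstrap_ci(sites, est, B=300, seed=9))

    def test_too_few_sites(self, site_factory):
        with pytest.raises(UndefinedResultError):
            bootstrap_ci([site_factory()], lambda ss: np.zeros(1), B=200)
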