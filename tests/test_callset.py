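"""Call-set intersection, QC summaries, and indel merging/filters."""

import math

import numpy as np
import pytest

from exonpop import (intersect_callsets, indel_site_filters, merge_indels,
                     summarize_callset)
from exonpop.errors import AnnotationError


class TestIntersectCallsets:
    def test_identical_sets(self, site_factory):
        a = [site_factory(pos=p) for p in (10, 20)]
        b = [site_factory(pos=p) for p in (10, 20)]
        both, only_a, only_b = intersect_callsets(a, b)
        assert [s.pos for s in both] == [10, 20]
        assert only_a == [] and only_b == []

    def test_same_position_different_alt_is_unique(self, site_factory):
        a = [site_factory(pos=10, alt="G")]
        b = [site_factory(pos=10, alt="T")]
        both, only_a, only_b = intersect_callsets(a, b)
        assert both == [] and len(only_a) == 1 and len(only_b) == 1

    def test_partition_matches_set_oracle(self, site_factory):
        rng = np.random.default_rng(1)
        mk = lambda keys: [site_factory(pos=int(p), alt=a)
                           for p, a in keys]
        keys_a = {(int(p), "GT"[i]) for p, i in
                  zip(rng.integers(1, 400, 500), rng.integers(0, 2, 500))}
        keys_b = {(int(p), "GT"[i]) for p, i in
                  zip(rng.integers(1, 400, 500), rng.integers(0, 2, 500))}
        both, only_a, only_b = intersect_callsets(mk(keys_a), mk(keys_b))
        assert len(both) == len(keys_a & keys_b)
        assert len(only_a) == len(keys_a - keys_b)
        assert len(only_b) == len(keys_b - keys_a)
        assert len(both) + len(only_a) == len(keys_a)


class TestSummarizeCallset:
    def test_ts_tv_worked_example(self, site_factory):
        sites = [site_factory(pos=i + 1, ref=r, alt=a) for i, (r, a) in
                 enumerate([("A", "G"), ("C", "T"), ("G", "A"), ("A", "T")])]
        assert summarize_callset(sites).ts_tv == pytest.approx(3.0)

    def test_zero_transversions_reports_infinity(self, site_factory):
        sites = [site_factory(pos=1, ref="A", alt="G")]
        assert math.isinf(summarize_callset(sites).ts_tv)

    @pytest.mark.parametrize("known_flags,expected", [
        ((False, False), 0.0), ((True, True), 100.0), ((True, False), 50.0)])
    def test_pct_known(self, site_factory, known_flags, expected):
        sites = [site_factory(pos=i + 1, known=k)
                 for i, k in enumerate(known_flags)]
        assert summarize_callset(sites).pct_known == pytest.approx(expected)

    def test_known_sites_list_overrides_flags(self, site_factory):
        sites = [site_factory(pos=1), site_factory(pos=2)]
        out = summarize_callset(sites, known_sites={("1", 2)})
        assert out.pct_known == pytest.approx(50.0)


class TestMergeIndels:
    def mk_del(self, site_factory, pos, genotypes=(0, 1, 0), length=1):
        return site_factory(pos=pos, ref="A" + "T" * length, alt="A",
                            genotypes=genotypes, alt_depths=(0, 4, 0))

    def test_nearby_same_type_merged(self, site_factory):
        merged = merge_indels([[self.mk_del(site_factory, 100)],
                               [self.mk_del(site_factory, 104)]])
        assert len(merged) == 1
        assert merged[0].pos == 100

    def test_type_mismatch_not_merged(self, site_factory):
        ins = site_factory(pos=103, ref="A", alt="ATT", genotypes=(0, 1, 0))
        merged = merge_indels([[self.mk_del(site_factory, 100)], [ins]])
        assert len(merged) == 2

    def test_transitive_closure(self, site_factory):
        sites = [self.mk_del(site_factory, p) for p in (100, 104, 108)]
        merged = merge_indels([sites])
        assert len(merged) == 1 and merged[0].pos == 100

    def test_matches_union_find_oracle(self, site_factory):
        rng = np.random.default_rng(7)
        positions = sorted(set(rng.integers(1, 2000, size=120).tolist()))
        sites = [self.mk_del(site_factory, p) for p in positions]
        merged = merge_indels([sites], window=5)
        # union-find over pairs within the window
        parent = list(range(len(positions)))
        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i
        for i in range(len(positions)):
            for j in range(i + 1, len(positions)):
                if abs(positions[i] - positions[j]) <= 5:
                    parent[find(i)] = find(j)
        n_clusters = len({find(i) for i in range(len(positions))})
        assert len(merged) == n_clusters

    def test_idempotent(self, site_factory):
        sites = [self.mk_del(site_factory, p) for p in (100, 104, 113, 400)]
        once = merge_indels([sites])
        twice = merge_indels([once])
        assert [s.key for s in twice] == [s.key for s in once]

    def test_representative_keeps_highest_ac_alleles(self, site_factory):
        a = self.mk_del(site_factory, 100, genotypes=(0, 1, 0), length=1)
        b = self.mk_del(site_factory, 103, genotypes=(1, 1, 2), length=2)
        (rep,) = merge_indels([[a, b]])
        assert rep.pos == 100  # leftmost position
        assert rep.ref == b.ref  # alleles of the higher-AC member


class TestIndelSiteFilters:
    def test_length1_singleton_removed(self, site_factory):
        s = site_factory(pos=10, ref="AT", alt="A", genotypes=(0, 1, 0),
                         alt_depths=(0, 4, 0))  # AC = 1, length 1
        assert indel_site_filters([s]) == []

    def test_length1_nonsingleton_kept(self, site_factory):
        s = site_factory(pos=10, ref="AT", alt="A", genotypes=(1, 1, 1),
                         alt_depths=(4, 4, 4))
        assert indel_site_filters([s]) == [s]

    def test_longer_singleton_kept(self, site_factory):
        s = site_factory(pos=10, ref="ATTT", alt="A", genotypes=(0, 1, 0),
                         alt_depths=(0, 2, 0))
        assert indel_site_filters([s]) == [s]

    def test_insufficient_read_support_removed(self, site_factory):
        s = site_factory(pos=10, ref="ATTT", alt="A", genotypes=(1, 1, 0),
                         alt_depths=(1, 1, 0))
        assert indel_site_filters([s]) == []

    def test_missing_read_counts_is_annotation_error(self, site_factory):
        s = site_factory(pos=10, ref="AT", alt="A", genotypes=(0, 1, 0))
        with pytest.raises(AnnotationError):
            indel_site_filters([s])
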