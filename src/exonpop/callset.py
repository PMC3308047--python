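"""Call-set intersection QC, summary statistics, and indel merging.

The intersection of two independently produced call sets, keyed by
(chrom, pos, ref, alt), is the high-confidence release set; the unique
fractions are retained for error-mode analysis. Call-set quality is
summarized by the transition/transversion ratio and the fraction of sites
present in a known-sites list, the two standard aggregate QC metrics for
coding variant sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import AnnotationError
from .filters import FilterConfig
from .sites import VariantSite, sites_by_key


@dataclass(frozen=True)
class CallsetSummary:
    """Aggregate QC of one call set (site count, %known, Ts/Tv)."""
    n_sites: int
    pct_known: float
    ts_tv: float

    def to_series(self, name: str = "callset") -> pd.Series:
        return pd.Series({"SNPs": self.n_sites, "%known": round(self.pct_known, 2),
                          "Ts/Tv": round(self.ts_tv, 2)}, name=name)


def intersect_callsets(a: Sequence[VariantSite], b: Sequence[VariantSite]
                       ) -> tuple[list[VariantSite], list[VariantSite],
                                  list[VariantSite]]:
    """Partition two call sets into (both, only_a, only_b) by allele key.

    Sites in ``both`` carry the annotations of call set ``a``. The partition
    is exact: |both| + |only_a| = |a| and symmetrically for b.
    """
    keys_a = sites_by_key(a)
    keys_b = sites_by_key(b)
    both = [s for k, s in keys_a.items() if k in keys_b]
    only_a = [s for k, s in keys_a.items() if k not in keys_b]
    only_b = [s for k, s in keys_b.items() if k not in keys_a]
    return both, only_a, only_b


def summarize_callset(sites: Sequence[VariantSite],
                      known_sites: Optional[set] = None) -> CallsetSummary:
    """Ts/Tv over SNPs and percent of sites in the known list.

    ``known_sites`` may contain (chrom, pos) pairs or full allele keys; when
    omitted, each site's ``known`` flag is used. A set with transitions but
    no transversions reports an infinite Ts/Tv rather than raising.
    """
    n = len(sites)
    if known_sites is None:
        n_known = sum(1 for s in sites if s.known)
    else:
        n_known = sum(1 for s in sites
                      if (s.chrom, s.pos) in known_sites or s.key in known_sites)
    snps = [s for s in sites if s.is_snp]
    ts = sum(1 for s in snps if s.is_transition)
    tv = len(snps) - ts
    if tv == 0:
        ts_tv = math.inf if ts > 0 else 0.0
    else:
        ts_tv = ts / tv
    pct_known = 100.0 * n_known / n if n else 0.0
    return CallsetSummary(n_sites=n, pct_known=pct_known, ts_tv=ts_tv)


def merge_indels(callsets: Iterable[Sequence[VariantSite]],
                 window: int = 5) -> list[VariantSite]:
    """Merge equivalent indel events across call sets.

    Same-type (insertion vs deletion) events within ``window`` bp of each
    other are considered equivalent; equivalence is closed transitively, and
    each cluster emits one representative: the leftmost position, carrying
    the alleles of the member with the highest alternate allele count (ties
    by position). Idempotent: merging a merged set changes nothing.
    """
    pooled: list[VariantSite] = []
    for cs in callsets:
        pooled.extend(cs)
    by_group: dict[tuple[str, str], list[VariantSite]] = {}
    for s in pooled:
        if s.vtype == "snp":
            raise AnnotationError(f"site {s.chrom}:{s.pos} is not an indel")
        by_group.setdefault((s.chrom, s.vtype), []).append(s)

    merged: list[VariantSite] = []
    for group in by_group.values():
        group.sort(key=lambda s: s.pos)
        cluster: list[VariantSite] = []
        for s in group:
            if cluster and s.pos - cluster[-1].pos <= window:
                cluster.append(s)
            else:
                if cluster:
                    merged.append(_cluster_representative(cluster))
                cluster = [s]
        if cluster:
            merged.append(_cluster_representative(cluster))
    merged.sort(key=lambda s: (s.chrom, s.pos, s.ref, s.alt))
    return merged


def _cluster_representative(cluster: list[VariantSite]) -> VariantSite:
    def ac(s: VariantSite) -> int:
        try:
            return s.alt_count()
        except Exception:
            return 0

    best = max(cluster, key=lambda s: (ac(s), -s.pos))
    leftmost = cluster[0]
    if best is leftmost:
        return leftmost
    from dataclasses import replace
    return replace(best, pos=leftmost.pos, info=dict(best.info))


def indel_site_filters(sites: Sequence[VariantSite],
                       config: FilterConfig = FilterConfig()
                       ) -> list[VariantSite]:
    """Site-level indel filters: read support and the 1-bp singleton rule.

    A site is removed if no sample shows >= ``indel_min_reads`` variant
    reads, or if it is a length-1 indel whose alternate allele count is 1
    (the class dominated by sequencing artifacts).
    """
    config.validate()
    kept = []
    for s in sites:
        if s.alt_depths is None:
            raise AnnotationError(
                f"site {s.chrom}:{s.pos} lacks per-sample variant read counts")
        if int(s.alt_depths.max(initial=0)) < config.indel_min_reads:
            continue
        if s.indel_length == 1 and s.alt_count() == 1:
            continue
        kept.append(s)
    return kept
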