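"""Site-level heuristic filters of the two SNP calling pipelines.

Two filter families are implemented as they were deployed in practice:

* the quality-based filter (``bc_filter``): site quality >= 40 PHRED and at
  least one sample carrying a non-reference genotype with genotype quality
  >= 10;
* the artifact-signature filter (``bi_filter``): keep a site only if
  QD (quality/depth) >= 5, the adjacent allele-sharing homopolymer run is
  <= 3, the mean reference-allele balance over heterozygotes is < 0.75, and
  the site is not part of a cluster of >= 3 variants spanning <= 10 bases.

Sites with no heterozygous sample have an undefined allele balance and pass
the AB rule by convention: the rule targets heterozygote artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import AnnotationError, ConfigError, DomainError
from .sites import HET, VariantSite


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of both pipelines' site filters (defaults as deployed)."""
    bc_min_quality: float = 40.0
    bc_min_genotype_quality: float = 10.0
    bi_min_qd: float = 5.0
    bi_max_hrun: int = 3
    bi_max_ab: float = 0.75
    bi_cluster_n: int = 3
    bi_cluster_window: int = 10
    indel_merge_window: int = 5
    indel_min_reads: int = 2

    def validate(self) -> None:
        for name in ("bc_min_quality", "bc_min_genotype_quality", "bi_min_qd",
                     "bi_max_hrun", "bi_cluster_n", "bi_cluster_window",
                     "indel_merge_window", "indel_min_reads"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 < self.bi_max_ab <= 1.0:
            raise ConfigError("bi_max_ab must be in (0, 1]")


def _chrom_seq(reference, chrom: str) -> str:
    if isinstance(reference, str):
        return reference
    try:
        return str(reference[chrom])
    except (KeyError, TypeError) as exc:
        raise AnnotationError(f"reference lacks chromosome {chrom!r}") from exc


def hrun(reference, site: VariantSite) -> int:
    """Length of the longest homopolymer of the alternate base adjacent to
    the site, on either side.

    ``reference`` is a chromosome sequence string or a mapping from
    chromosome name to sequence. A run that does not share the alternate
    allele's base contributes 0.
    """
    if not site.is_snp:
        raise DomainError("hrun is defined for SNPs only")
    seq = _chrom_seq(reference, site.chrom)
    i = site.pos - 1
    if not 0 <= i < len(seq):
        raise IndexError(
            f"position {site.pos} outside reference of length {len(seq)}")
    b = site.alt.upper()
    left = 0
    j = i - 1
    while j >= 0 and seq[j].upper() == b:
        left += 1
        j -= 1
    right = 0
    j = i + 1
    while j < len(seq) and seq[j].upper() == b:
        right += 1
        j += 1
    return max(left, right)


def allele_balance(site: VariantSite) -> Optional[float]:
    """Mean ref-depth fraction over heterozygous samples, or None if no hets.

    Polarized for the reference allele: values near 1 mean the alternate
    allele is barely supported by reads at heterozygous calls.
    """
    if site.genotypes is None:
        raise AnnotationError(f"site {site.chrom}:{site.pos} has no genotypes")
    if site.ref_depths is None or site.alt_depths is None:
        raise AnnotationError(
            f"site {site.chrom}:{site.pos} lacks per-sample allele depths")
    hets = site.genotypes == HET
    if not hets.any():
        return None
    r = site.ref_depths[hets].astype(float)
    a = site.alt_depths[hets].astype(float)
    total = r + a
    ok = total > 0
    if not ok.any():
        return None
    return float(np.mean(r[ok] / total[ok]))


def bc_filter(sites: Sequence[VariantSite],
              config: FilterConfig = FilterConfig()) -> list[VariantSite]:
    """Keep sites with quality >= threshold and at least one confident
    non-reference genotype."""
    config.validate()
    kept = []
    for s in sites:
        if s.quality is None:
            raise AnnotationError(f"site {s.chrom}:{s.pos} has no quality")
        if s.genotypes is None or s.genotype_quals is None:
            raise AnnotationError(
                f"site {s.chrom}:{s.pos} lacks genotypes or genotype qualities")
        if s.quality < config.bc_min_quality:
            continue
        carrier = (s.genotypes > 0) & (
            s.genotype_quals >= config.bc_min_genotype_quality)
        if carrier.any():
            kept.append(s)
    return kept


def snp_cluster_keys(sites: Sequence[VariantSite], n: int,
                     window: int) -> set[tuple]:
    """Keys of sites belonging to any run of >= n variants spanning <= window
    bases on one chromosome (distinct positions; split alleles at one
    position count once for the span)."""
    flagged: set[tuple] = set()
    by_chrom: dict[str, list[VariantSite]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, group in by_chrom.items():
        group.sort(key=lambda s: s.pos)
        pos = np.array(sorted({s.pos for s in group}))
        bad_pos: set[int] = set()
        for i in range(len(pos) - n + 1):
            if pos[i + n - 1] - pos[i] <= window:
                bad_pos.update(int(p) for p in pos[i:i + n])
        for s in group:
            if s.pos in bad_pos:
                flagged.add(s.key)
    return flagged


def bi_filter(sites: Sequence[VariantSite], reference,
              config: FilterConfig = FilterConfig()) -> list[VariantSite]:
    """Apply the artifact-signature filters; returns the surviving sites.

    The four rules are independent: the result equals the intersection of
    the single-rule survivor sets.
    """
    config.validate()
    clustered = snp_cluster_keys(sites, config.bi_cluster_n,
                                 config.bi_cluster_window)
    kept = []
    for s in sites:
        if s.qd is None:
            raise AnnotationError(f"site {s.chrom}:{s.pos} has no QD annotation")
        if s.qd < config.bi_min_qd:
            continue
        if hrun(reference, s) > config.bi_max_hrun:
            continue
        ab = allele_balance(s)
        if ab is not None and ab >= config.bi_max_ab:
            continue
        if s.key in clustered:
            continue
        kept.append(s)
    return kept
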