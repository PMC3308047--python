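"""Variant sites and per-site allele arithmetic.

Genotypes are stored as alternate-allele dosages per sample: 0 (hom-ref),
1 (het), 2 (hom-alt), -1 (missing). Missing genotypes are excluded from both
numerator and denominator of every frequency computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DomainError
from .panel import SamplePanel

HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

_BASES = frozenset("ACGT")
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

SNP = "snp"
INSERTION = "insertion"
DELETION = "deletion"


@dataclass
class VariantSite:
    """One alternate allele at one genomic position (multi-allelics are split).

    Attributes
    ----------
    chrom, pos:
        Chromosome name and 1-based position (VCF convention).
    ref, alt:
        Reference and alternate allele strings.
    quality:
        PHRED-scaled site quality, if called.
    qd:
        Site quality divided by depth of coverage, if annotated.
    genotypes:
        Alternate-allele dosage per sample (-1 = missing), or None.
    genotype_quals, ref_depths, alt_depths:
        Optional per-sample arrays aligned with ``genotypes``.
    ancestral:
        Ancestral base from an outgroup alignment, or None if unknown.
    known:
        Whether the site appears in a known-sites (dbSNP-style) list.
    site_class:
        Functional class label (e.g. silent / missense / nonsense).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    quality: Optional[float] = None
    qd: Optional[float] = None
    genotypes: Optional[np.ndarray] = None
    genotype_quals: Optional[np.ndarray] = None
    ref_depths: Optional[np.ndarray] = None
    alt_depths: Optional[np.ndarray] = None
    ancestral: Optional[str] = None
    known: bool = False
    site_class: Optional[str] = None
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.genotypes is not None:
            self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    # -- typing ----------------------------------------------------------
    @property
    def vtype(self) -> str:
        if len(self.ref) == len(self.alt):
            if len(self.ref) != 1:
                raise ValueError(f"unsupported allele pair {self.ref}>{self.alt}")
            return SNP
        return INSERTION if len(self.alt) > len(self.ref) else DELETION

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_transition(self) -> bool:
        return self.is_snp and (self.ref, self.alt) in _TRANSITIONS

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    # -- allele arithmetic ----------------------------------------------
    def _called(self) -> np.ndarray:
        if self.genotypes is None:
            raise DomainError(f"site {self.chrom}:{self.pos} carries no genotypes")
        return self.genotypes[self.genotypes >= 0]

    def alt_count(self, indices: Optional[np.ndarray] = None) -> int:
        """Alternate allele count over non-missing genotypes."""
        g = self.genotypes if indices is None else self.genotypes[indices]
        g = g[g >= 0]
        return int(g.sum())

    def chrom_count(self, indices: Optional[np.ndarray] = None) -> int:
        """Number of successfully genotyped chromosomes (2 per called sample)."""
        g = self.genotypes if indices is None else self.genotypes[indices]
        return int(2 * (g >= 0).sum())

    def alt_freq(self) -> float:
        n = self.chrom_count()
        if n == 0:
            raise DomainError(f"site {self.chrom}:{self.pos} has no called samples")
        return self.alt_count() / n

    def minor_freq(self) -> float:
        f = self.alt_freq()
        return min(f, 1.0 - f)

    def minor_allele(self) -> str:
        """'alt' if the alternate allele is the (strictly) minor one, else 'ref'.

        Ties at frequency 0.5 label the alternate allele minor.
        """
        return "alt" if self.alt_freq() <= 0.5 else "ref"

    def minor_counts_by_population(
            self, panel: SamplePanel) -> tuple[dict[str, int], dict[str, int]]:
        """Per-population minor-allele counts and called chromosome counts."""
        minor_is_alt = self.minor_allele() == "alt"
        counts: dict[str, int] = {}
        chroms: dict[str, int] = {}
        for pop, idx in panel.indices_by_population().items():
            n = self.chrom_count(idx)
            c = self.alt_count(idx)
            counts[pop] = c if minor_is_alt else n - c
            chroms[pop] = n
        return counts, chroms

    def derived_count(self) -> Optional[int]:
        """Derived allele count, or None if the site cannot be polarized.

        The ancestral base must match one of the two alleles; sites with an
        unknown ancestral base, or one matching neither allele, are excluded
        from unfolded spectra.
        """
        if self.ancestral is None or self.ancestral.upper() not in _BASES:
            return None
        anc = self.ancestral.upper()
        if anc == self.ref:
            return self.alt_count()
        if anc == self.alt:
            return self.chrom_count() - self.alt_count()
        return None


def het_indices(site: VariantSite) -> np.ndarray:
    """Indices of samples called heterozygous at the site."""
    if site.genotypes is None:
        raise DomainError(f"site {site.chrom}:{site.pos} carries no genotypes")
    return np.flatnonzero(site.genotypes == HET)


def sites_by_key(sites) -> dict[tuple, VariantSite]:
    return {s.key: s for s in sites}
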