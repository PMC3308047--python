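"""Nucleotide diversity, allele-frequency spectra, and projection.

Core quantities
---------------
Pairwise heterozygosity of a site with allele count j among n chromosomes is
2j(n-j)/(n(n-1)): the fraction of chromosome pairs differing at the site.
Per-base heterozygosity divides the summed site heterozygosity of a site
class by the number of *callable* bases of that class, where a targeted base
is callable when at least ``min_chroms`` chromosomes carry read depth >=
``min_depth``.

An allele-frequency spectrum (AFS) at chromosome count n holds the number of
sites per allele-count bin; "unfolded" bins count derived alleles (polarized
by an outgroup base), "folded" bins count minor alleles. Spectra observed at
heterogeneous per-site chromosome counts are made comparable by projecting
each site to a common size m with the hypergeometric distribution:
E[count i | j of n] = C(j,i) C(n-j, m-i) / C(n,m). Projection is linear and
composition-consistent, and keeps fractional expected counts.

Watterson's estimator theta_W = S / a_{n-1} (S segregating sites, a_{n-1}
the (n-1)-th harmonic number) and the neutral constant-size expectation
E[count i] = theta/i complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from ._utils import harmonic
from .errors import AnnotationError, DomainError, UndefinedResultError
from .regions import TargetRegions
from .sites import VariantSite


# ---------------------------------------------------------------------------
# callability
# ---------------------------------------------------------------------------

@dataclass
class CallabilityMask:
    """Per-base callability over target regions.

    ``mask[i]`` corresponds to the i-th targeted base in the global base
    indexing of ``targets`` (see :meth:`TargetRegions.base_index`).
    """
    targets: TargetRegions
    mask: np.ndarray
    min_depth: int
    min_chroms: int

    @property
    def n_callable(self) -> int:
        return int(self.mask.sum())

    def is_callable(self, chrom: str, pos0: int) -> bool:
        i = self.targets.base_index(chrom, pos0)
        return bool(i >= 0 and self.mask[i])


def callable_mask(depths: np.ndarray, targets: TargetRegions,
                  min_depth: int = 10, min_chroms: int = 100
                  ) -> CallabilityMask:
    """Mark targeted bases with >= min_depth coverage in >= min_chroms
    chromosomes (two per sample meeting the depth threshold)."""
    depths = np.asarray(depths)
    if depths.ndim != 2 or depths.shape[0] != targets.total_length:
        raise DomainError(
            f"depth matrix has {depths.shape[0] if depths.ndim == 2 else '?'} "
            f"rows for {targets.total_length} targeted bases")
    chroms = 2 * (depths >= min_depth).sum(axis=1)
    return CallabilityMask(targets, chroms >= min_chroms, min_depth, min_chroms)


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------

def site_het(j: int, n: int) -> float:
    """Pairwise heterozygosity 2j(n-j)/(n(n-1)) of one site."""
    if n < 2:
        raise DomainError(f"need >= 2 chromosomes, got {n}")
    if not 0 <= j <= n:
        raise DomainError(f"allele count {j} outside [0, {n}]")
    return 2.0 * j * (n - j) / (n * (n - 1.0))


def per_base_het(sites: Sequence[VariantSite],
                 callable_bases: int | CallabilityMask,
                 site_class: Optional[str] = None,
                 sample_indices: Optional[np.ndarray] = None) -> float:
    """Summed site heterozygosity per callable base of a site class.

    ``callable_bases`` is either the number of callable bases of the class
    (monomorphic callable bases contribute 0 to the numerator and 1 to the
    denominator) or a CallabilityMask, in which case variant sites outside
    the mask are excluded and the mask's total callable count is the
    denominator. Values are per base; multiply by 1e4 for the conventional
    x10^-4 display scale.
    """
    if isinstance(callable_bases, CallabilityMask):
        mask = callable_bases
        denom = mask.n_callable
        included = [s for s in sites if mask.is_callable(s.chrom, s.pos - 1)]
    else:
        denom = int(callable_bases)
        included = list(sites)
    if denom <= 0:
        raise UndefinedResultError("zero callable bases")
    total = 0.0
    for s in included:
        if site_class is not None and s.site_class != site_class:
            continue
        n = s.chrom_count(sample_indices)
        if n < 2:
            continue
        total += site_het(s.alt_count(sample_indices), n)
    return total / denom


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

@dataclass
class AFSpectrum:
    """Allele-frequency spectrum at a fixed chromosome count.

    ``counts[i]`` is the (possibly fractional, after projection) number of
    sites with allele count i, i = 0..n. ``polarized`` records whether bins
    count derived alleles (True) or minor alleles (False).
    """
    n: int
    counts: np.ndarray
    polarized: bool = True

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (self.n + 1,):
            raise ValueError(f"counts must have length n+1 = {self.n + 1}")
        if (self.counts < -1e-9).any():
            raise ValueError("negative spectrum counts")

    @property
    def S(self) -> float:
        """Number of segregating sites (mass in bins 1..n-1)."""
        return float(self.counts[1:self.n].sum())

    @property
    def monomorphic_mass(self) -> float:
        return float(self.counts[0] + self.counts[self.n])

    def normalized(self) -> np.ndarray:
        """Segregating bins 1..n-1 scaled to sum to 1."""
        seg = self.counts[1:self.n]
        s = seg.sum()
        if s == 0:
            raise UndefinedResultError("empty spectrum")
        return seg / s

    def fold(self) -> "AFSpectrum":
        """Collapse to minor-allele counts (bins above n/2 emptied)."""
        c = np.zeros(self.n + 1)
        for i in range(self.n + 1):
            c[min(i, self.n - i)] += self.counts[i]
        return AFSpectrum(self.n, c, polarized=False)


def build_afs(sites: Sequence[VariantSite], n: Optional[int] = None,
              polarize: bool = True,
              sample_indices: Optional[np.ndarray] = None) -> AFSpectrum:
    """Build an AFS from sites, projecting heterogeneous chromosome counts.

    Unfolded spectra use derived-allele counts; sites that cannot be
    polarized (unknown ancestral base, or one matching neither allele) are
    excluded and raise only if *no* site carries ancestral information.
    Folded spectra use minor-allele counts. Sites genotyped in fewer than
    ``n`` chromosomes contribute their hypergeometric projection onto n.
    """
    sites = list(sites)
    if polarize and sites and all(s.ancestral is None for s in sites):
        raise AnnotationError("polarization requested but no site carries an "
                              "ancestral annotation")
    per_site: list[tuple[int, int]] = []  # (count, chroms)
    for s in sites:
        ns = s.chrom_count(sample_indices)
        if ns < 2:
            continue
        ac = s.alt_count(sample_indices)
        if polarize:
            anc = s.ancestral.upper() if s.ancestral is not None else None
            if anc == s.ref:
                d = ac
            elif anc == s.alt:
                d = ns - ac
            else:
                continue  # unknown ancestral state, or matches neither allele
            per_site.append((d, ns))
        else:
            per_site.append((min(ac, ns - ac), ns))
    if n is None:
        n = max((ns for _, ns in per_site), default=2)
    counts = np.zeros(n + 1)
    for j, ns in per_site:
        if ns == n:
            counts[j] += 1.0
        elif ns > n:
            counts += _projection_row(j, ns, n)
        else:
            # fewer chromosomes than requested: the site cannot be expanded
            continue
    return AFSpectrum(n, counts, polarized=polarize)


def _projection_row(j: int, n: int, m: int) -> np.ndarray:
    i = np.arange(m + 1)
    return hypergeom.pmf(i, n, j, m)


def project_afs(afs: AFSpectrum, m: int) -> AFSpectrum:
    """Project a spectrum to m <= n chromosomes (expected hypergeometric
    subsample counts; fractional, no rounding).

    Mass landing in bins 0 and m is the projection's loss to monomorphism,
    readable from ``monomorphic_mass``.
    """
    if m > afs.n:
        raise DomainError(f"cannot project n={afs.n} up to m={m}")
    if m < 1:
        raise DomainError("m must be >= 1")
    counts = np.zeros(m + 1)
    for j in range(afs.n + 1):
        if afs.counts[j] != 0:
            counts += afs.counts[j] * _projection_row(j, afs.n, m)
    return AFSpectrum(m, counts, polarized=afs.polarized)


def watterson_theta(S: float, n: int) -> float:
    """Watterson's estimator: S / a_{n-1}."""
    if n < 2:
        raise DomainError(f"need >= 2 chromosomes, got {n}")
    if S == 0:
        return 0.0
    return S / harmonic(n - 1)


def neutral_expectation(theta: float, n: int) -> AFSpectrum:
    """Constant-size neutral expectation: E[count i] = theta / i."""
    if theta <= 0:
        raise DomainError("theta must be > 0")
    counts = np.zeros(n + 1)
    i = np.arange(1, n)
    counts[1:n] = theta / i
    return AFSpectrum(n, counts, polarized=True)


# ---------------------------------------------------------------------------
# frequency-bin summaries
# ---------------------------------------------------------------------------

def fraction_in_bins(sites: Sequence[VariantSite],
                     edges: Sequence[float] = (0.01, 0.1, 0.5),
                     freq: str = "minor") -> dict[str, dict[str, float]]:
    """Fractions of sites per allele-frequency bin, with known fractions.

    Bins are [0, e1), [e1, e2), ... [e_{k-1}, e_k]; ``freq`` selects minor
    or alternate allele frequency. Returns
    {label: {"fraction": ..., "known_fraction": ...}}; fractions sum to 1.
    """
    sites = list(sites)
    if not sites:
        raise UndefinedResultError("no sites")
    edges = list(edges)
    lows = [0.0] + edges[:-1]
    labels = [f"[{lo:g},{hi:g})" if k < len(edges) - 1 else f"[{lo:g},{hi:g}]"
              for k, (lo, hi) in enumerate(zip(lows, edges))]
    totals = np.zeros(len(edges))
    known = np.zeros(len(edges))
    for s in sites:
        f = s.minor_freq() if freq == "minor" else s.alt_freq()
        k = int(np.searchsorted(edges, f, side="right"))
        k = min(k, len(edges) - 1)
        totals[k] += 1
        known[k] += s.known
    out: dict[str, dict[str, float]] = {}
    for k, label in enumerate(labels):
        out[label] = {
            "fraction": totals[k] / len(sites),
            "known_fraction": known[k] / totals[k] if totals[k] else float("nan"),
        }
    return out
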