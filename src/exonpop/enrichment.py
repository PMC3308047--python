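"""Allele-frequency-binned functional-category contrasts.

Coding variants are binned by minor allele frequency into low (<0.01),
intermediate (0.01 to 0.1) and common (>0.1) bins — boundary values 0.01 and
0.1 fall in the intermediate bin, matching the open labels — and counted per
functional class. Per-bin false-positive rates can be corrected for by
deflating each bin's count to its expected true-positive count,
c' = c * (1 - e_b); corrected counts are fractional. Class-versus-class
contrasts use a chi-square test of homogeneity on the 2x3 class-by-bin
table, the skew toward the low bin being the quantity of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import ConfigError, DomainError, UndefinedResultError
from .sites import VariantSite

BIN_LABELS = ("low", "intermediate", "common")

#: Per-bin genotype/validation error rates estimated from assay series on a
#: deep-coverage exome call set, in (low, intermediate, common) order.
DEFAULT_BIN_ERROR_RATES = (0.062, 0.032, 0.034)


@dataclass
class BinnedCounts:
    """Site counts per functional class (rows) and AF bin (columns)."""
    classes: tuple[str, ...]
    counts: np.ndarray
    edges: tuple[float, float] = (0.01, 0.1)
    error_rates: Optional[tuple[float, float, float]] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.classes), 3):
            raise ValueError("counts must be n_classes x 3")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.error_rates is not None:
            if any(not 0.0 <= e < 1.0 for e in self.error_rates):
                raise ConfigError("error rates must be in [0, 1)")

    def row(self, cls: str) -> np.ndarray:
        return self.counts[self.classes.index(cls)]

    def fractions(self, cls: str) -> np.ndarray:
        r = self.row(cls)
        return r / r.sum()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(BIN_LABELS))


def af_bin(f: float, edges: Sequence[float] = (0.01, 0.1)) -> int:
    """Bin index of a minor AF: [0,e1) -> 0, [e1,e2] -> 1, (e2,0.5] -> 2."""
    if f < edges[0]:
        return 0
    if f <= edges[1]:
        return 1
    return 2


def bin_by_af(sites: Sequence[VariantSite],
              classes: Optional[Sequence[str]] = None,
              edges: Sequence[float] = (0.01, 0.1),
              error_rates: Optional[Sequence[float]] = None) -> BinnedCounts:
    """Count sites per (functional class, minor-AF bin).

    Classes default to those observed, in first-appearance order; sites with
    no class label are skipped.
    """
    if classes is None:
        seen: list[str] = []
        for s in sites:
            if s.site_class is not None and s.site_class not in seen:
                seen.append(s.site_class)
        classes = seen
    classes = tuple(classes)
    counts = np.zeros((len(classes), 3))
    index = {c: i for i, c in enumerate(classes)}
    for s in sites:
        if s.site_class not in index:
            continue
        counts[index[s.site_class], af_bin(s.minor_freq(), edges)] += 1
    return BinnedCounts(classes, counts, tuple(edges),
                        tuple(error_rates) if error_rates is not None else None)


def correct_counts(binned: BinnedCounts) -> BinnedCounts:
    """Deflate each bin's counts to expected true positives: c * (1 - e_b)."""
    if binned.error_rates is None:
        raise ConfigError("error_rates must be set to correct counts")
    e = np.asarray(binned.error_rates)
    return replace(binned, counts=binned.counts * (1.0 - e)[None, :])


@dataclass(frozen=True)
class ContrastResult:
    """Chi-square homogeneity contrast between two functional classes."""
    class_a: str
    class_b: str
    statistic: float
    pvalue: float
    df: int
    low_fraction_a: float
    low_fraction_b: float
    corrected: bool


def class_contrast(binned: BinnedCounts, class_a: str, class_b: str,
                   corrected: bool = False) -> ContrastResult:
    """Chi-square test of homogeneity on the 2x3 class-by-bin table.

    With ``corrected=True`` the error-deflated (fractional) counts are used;
    the statistic is then a score on expected true-positive counts rather
    than a count-based test. All-zero bins are dropped from the table;
    identical distributions give statistic 0 and p = 1.
    """
    source = correct_counts(binned) if corrected else binned
    table = np.vstack([source.row(class_a), source.row(class_b)])
    if table[0].sum() == 0 or table[1].sum() == 0:
        raise DomainError("both classes need at least one site")
    keep = table.sum(axis=0) > 0
    table = table[:, keep]
    if table.shape[1] < 2:
        raise UndefinedResultError("contrast table is degenerate "
                                   "(all mass in one bin)")
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    df = table.shape[1] - 1
    pvalue = float(chi2.sf(stat, df))
    return ContrastResult(class_a, class_b, stat, pvalue, df,
                          float(source.fractions(class_a)[0]),
                          float(source.fractions(class_b)[0]),
                          corrected)


def enrichment_table(binned: BinnedCounts,
                     corrected: Optional[BinnedCounts] = None) -> pd.DataFrame:
    """Long-format table (class, bin, count, corrected count, fraction)."""
    rows = []
    for ci, cls in enumerate(binned.classes):
        fr = binned.fractions(cls)
        for bi, label in enumerate(BIN_LABELS):
            rows.append({
                "class": cls, "bin": label,
                "count": binned.counts[ci, bi],
                "corrected_count": (corrected.counts[ci, bi]
                                    if corrected is not None else np.nan),
                "fraction": fr[bi],
            })
    return pd.DataFrame(rows)
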