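"""Validation-series planning and contingency arithmetic.

Implements the bookkeeping of an experimental validation campaign: stratified
sampling of sites into assay series, validation rates over conclusive assays,
and genotype-accuracy summaries from a 3x3 called-vs-assayed table. Assays
with no conclusive outcome are excluded from every rate denominator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import STREAM_PLAN, substream
from .errors import UndefinedResultError

#: Row/column order of genotype contingency tables.
GENOTYPE_LABELS = ("hom_ref", "het", "hom_alt")


@dataclass
class AssayTable:
    """Validation outcomes for one assay series.

    ``confirmed`` / ``non_variant`` / ``inconclusive`` count site-level assay
    outcomes; ``genotype_counts`` is an optional 3x3 matrix with rows =
    called genotype class and columns = assayed (true) genotype class, in
    (hom-ref, het, hom-alt) order.
    """
    confirmed: int = 0
    non_variant: int = 0
    inconclusive: int = 0
    genotype_counts: Optional[np.ndarray] = None

    def __post_init__(self):
        for name in ("confirmed", "non_variant", "inconclusive"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.genotype_counts is not None:
            self.genotype_counts = np.asarray(self.genotype_counts)
            if self.genotype_counts.shape != (3, 3):
                raise ValueError("genotype_counts must be 3x3")
            if (self.genotype_counts < 0).any():
                raise ValueError("genotype_counts must be >= 0")

    @property
    def conclusive(self) -> int:
        return self.confirmed + self.non_variant

    def __add__(self, other: "AssayTable") -> "AssayTable":
        gc = None
        if self.genotype_counts is not None or other.genotype_counts is not None:
            a = self.genotype_counts if self.genotype_counts is not None else 0
            b = other.genotype_counts if other.genotype_counts is not None else 0
            gc = np.asarray(a) + np.asarray(b)
        return AssayTable(self.confirmed + other.confirmed,
                          self.non_variant + other.non_variant,
                          self.inconclusive + other.inconclusive, gc)


def validation_rate(confirmed: int, non_variant: int) -> float:
    """Percent of conclusive assays that confirmed a variant.

    Returned at full precision; display layers round to one decimal.
    """
    conclusive = confirmed + non_variant
    if conclusive < 1:
        raise UndefinedResultError("no conclusive assays")
    return 100.0 * confirmed / conclusive


@dataclass
class GenotypeAccuracy:
    """Accuracy summary of a 3x3 called-vs-assayed genotype table."""
    per_class: dict[str, float]
    overall: float
    variant_fdr: float
    missed_variant_rate: float
    n_compared: int


def genotype_accuracy(table: AssayTable) -> GenotypeAccuracy:
    """Per-class and overall genotype accuracy plus variant-call error rates.

    Per-class accuracy is diagonal/row-total (among genotypes *called* in a
    class, the fraction the assay confirmed); overall accuracy is
    trace/total. The variant-genotype false discovery rate is the miscalled
    fraction among called het + hom-alt genotypes; the missed-variant rate is
    the fraction of assayed variant genotypes that were called hom-ref.
    """
    if table.genotype_counts is None:
        raise UndefinedResultError("assay table has no genotype comparison")
    m = np.asarray(table.genotype_counts, dtype=float)
    total = m.sum()
    if total <= 0:
        raise UndefinedResultError("empty genotype table")
    per_class: dict[str, float] = {}
    for i, label in enumerate(GENOTYPE_LABELS):
        row = m[i].sum()
        per_class[label] = 100.0 * m[i, i] / row if row > 0 else float("nan")
    overall = 100.0 * np.trace(m) / total
    called_variant = m[1:].sum()
    fdr = ((called_variant - m[1, 1] - m[2, 2]) / called_variant
           if called_variant > 0 else float("nan"))
    assayed_variant = m[:, 1:].sum()
    missed = (m[0, 1:].sum() / assayed_variant
              if assayed_variant > 0 else float("nan"))
    return GenotypeAccuracy(per_class, float(overall), float(fdr),
                            float(missed), int(round(total)))


@dataclass(frozen=True)
class SeriesRequest:
    """One stratified sampling request: a stratum predicate and a size."""
    name: str
    selector: Callable
    n: int


def plan_series(sites: Sequence, requests: Sequence[SeriesRequest],
                seed: int = 0) -> dict[str, list]:
    """Random stratified site samples without replacement, per series.

    If a stratum is smaller than requested, all its sites are returned and a
    shortfall warning is emitted. Deterministic under ``seed``.
    """
    rng = substream(seed, STREAM_PLAN)
    out: dict[str, list] = {}
    for req in requests:
        stratum = [s for s in sites if req.selector(s)]
        if len(stratum) < req.n:
            warnings.warn(
                f"series {req.name!r}: stratum has {len(stratum)} sites, "
                f"{req.n} requested; returning all", stacklevel=2)
            chosen = list(range(len(stratum)))
        else:
            chosen = sorted(rng.choice(len(stratum), size=req.n,
                                       replace=False).tolist())
        out[req.name] = [stratum[i] for i in chosen]
    return out


def validation_report(series: Mapping[str, AssayTable]) -> pd.DataFrame:
    """Assemble a series-by-outcome table with per-series validation rates.

    Columns are the series (plus a Totals column); rows are confirmed
    variants, non-variants, and the validation rate in percent (one decimal).
    """
    totals = AssayTable()
    data: dict[str, list] = {}
    for name, t in series.items():
        data[name] = [t.confirmed, t.non_variant,
                      round(validation_rate(t.confirmed, t.non_variant), 1)]
        totals = totals + t
    data["Totals"] = [totals.confirmed, totals.non_variant,
                      round(validation_rate(totals.confirmed,
                                            totals.non_variant), 1)]
    return pd.DataFrame(data, index=["Variant", "Non-variants",
                                     "Validation rate (%)"])
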