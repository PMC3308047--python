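"""Functional annotation of coding positions and variants.

Three classifiers:

* codon degeneracy of a reference position (non-/two-/three-/four-fold),
  counting how many of the three alternative bases leave the translation
  unchanged under the standard nuclear genetic code;
* amino-acid effect of a SNP (silent / missense / nonsense), with stop-loss
  folded into missense since the three-way scheme has no such category;
* combination of SIFT and PolyPhen-2 predictions into a single class, by
  either the three-class concordance rule used for disease-mutation
  overlaps (``hgmd3``) or by taking the more severe prediction
  (``severest``).

Positions covered by several transcripts (differing reading frames) are
classified once per transcript context.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from Bio.Data import CodonTable

from .errors import (AnnotationError, NoPredictionError,
                     UnsupportedVariantError)
from .genemodel import GeneModel, models_at
from .sites import VariantSite

_STANDARD = CodonTable.standard_dna_table
#: codon -> single-letter amino acid, with '*' for stops (64 entries)
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TO_AA.update({c: "*" for c in _STANDARD.stop_codons})

DEGENERACY_CLASSES = ("non-degenerate", "two-fold", "three-fold", "four-fold")
EFFECT_CLASSES = ("silent", "missense", "nonsense")

SIFT_LEVELS = {"tolerated": 0, "damaging-low-confidence": 1, "damaging": 2}
POLYPHEN_LEVELS = {"benign": 0, "possibly-damaging": 1, "probably-damaging": 2}
COMBINED_CLASSES = ("benign", "possibly-damaging", "damaging")

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _translate(codon: str) -> str:
    try:
        return CODON_TO_AA[codon]
    except KeyError:
        raise AnnotationError(f"ambiguous or invalid codon {codon!r}") from None


def degeneracy_of_codon_position(codon: str, offset: int) -> str:
    """Degeneracy class of one position within a codon (offset 0..2)."""
    aa = _translate(codon)
    n_syn = 0
    for b in "ACGT":
        if b == codon[offset]:
            continue
        alt = codon[:offset] + b + codon[offset + 1:]
        if _translate(alt) == aa:
            n_syn += 1
    return DEGENERACY_CLASSES[n_syn]


def degeneracy(position: int, gene_models: Sequence[GeneModel] | GeneModel,
               reference, chrom: Optional[str] = None) -> dict[str, str]:
    """Degeneracy class per transcript context at a 1-based position.

    Returns {transcript_id: class} for every model whose CDS covers the
    position; raises AnnotationError if none does.
    """
    if isinstance(gene_models, GeneModel):
        gene_models = [gene_models]
    pos0 = position - 1
    out: dict[str, str] = {}
    for model in gene_models:
        if chrom is not None and model.chrom != chrom:
            continue
        if not model.contains(pos0):
            continue
        codon, offset = model.codon_context(reference, pos0)
        out[model.transcript_id] = degeneracy_of_codon_position(codon, offset)
    if not out:
        raise AnnotationError(f"position {position} not in any CDS")
    return out


def effect(site: VariantSite, gene_model: GeneModel, reference) -> str:
    """Amino-acid effect of a SNP under one gene model.

    silent: translation unchanged; nonsense: the alternate codon is a stop
    and the reference codon is not; everything else (including stop-loss) is
    missense.
    """
    if not site.is_snp:
        raise UnsupportedVariantError(
            f"effect classification supports SNPs only, got {site.vtype}")
    pos0 = site.pos - 1
    codon, offset = gene_model.codon_context(reference, pos0)
    alt_base = site.alt.upper()
    if gene_model.strand == "-":
        alt_base = _COMPLEMENT[alt_base]
    ref_aa = _translate(codon)
    alt_codon = codon[:offset] + alt_base + codon[offset + 1:]
    alt_aa = _translate(alt_codon)
    if alt_aa == ref_aa:
        return "silent"
    if alt_aa == "*" and ref_aa != "*":
        return "nonsense"
    return "missense"


def annotate_effects(sites: Sequence[VariantSite],
                     gene_models: Sequence[GeneModel], reference,
                     skip_noncoding: bool = True) -> None:
    """Set each SNP's ``site_class`` to its most severe effect across
    transcripts (all per-transcript classes kept in ``info['EFFECT_ALL']``)."""
    severity = {c: i for i, c in enumerate(EFFECT_CLASSES)}
    for site in sites:
        if not site.is_snp:
            continue
        models = models_at(gene_models, site.chrom, site.pos - 1)
        if not models:
            if skip_noncoding:
                continue
            raise AnnotationError(
                f"site {site.chrom}:{site.pos} not in any CDS")
        classes = {m.transcript_id: effect(site, m, reference) for m in models}
        site.info["EFFECT_ALL"] = classes
        site.site_class = max(classes.values(), key=severity.__getitem__)


@dataclass(frozen=True)
class PredictionPair:
    """SIFT and PolyPhen-2 category labels for one variant (either may be None)."""
    sift: Optional[str] = None
    polyphen: Optional[str] = None

    def __post_init__(self):
        if self.sift is not None and self.sift not in SIFT_LEVELS:
            raise ValueError(f"unknown SIFT category {self.sift!r}")
        if self.polyphen is not None and self.polyphen not in POLYPHEN_LEVELS:
            raise ValueError(f"unknown PolyPhen-2 category {self.polyphen!r}")


def combine_predictions(pair: PredictionPair, rule: str = "hgmd3") -> str:
    """Combine the two predictors into benign / possibly-damaging / damaging.

    ``hgmd3``: concordant severities map to their shared class, a single
    available prediction maps to its own class, and any conflict between the
    two programs is classified possibly-damaging. ``severest``: the ordinal
    maximum of the two severities.
    """
    s = SIFT_LEVELS.get(pair.sift) if pair.sift is not None else None
    p = POLYPHEN_LEVELS.get(pair.polyphen) if pair.polyphen is not None else None
    if s is None and p is None:
        raise NoPredictionError("neither program produced a prediction")
    if rule == "severest":
        level = max(v for v in (s, p) if v is not None)
        return COMBINED_CLASSES[level]
    if rule == "hgmd3":
        if s is None or p is None:
            return COMBINED_CLASSES[s if s is not None else p]
        return COMBINED_CLASSES[s] if s == p else "possibly-damaging"
    raise ValueError(f"unknown combination rule {rule!r}")
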