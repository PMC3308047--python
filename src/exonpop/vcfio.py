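"""VCF input/output via pysam, plus known-sites lists.

Multi-allelic records are split into one :class:`VariantSite` per alternate
allele, because every downstream statistic is defined per alternate allele.
Genotype dosages are conserved by the split: a sample's dosage for allele k
counts how many of its two called alleles equal k.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

from .errors import PanelError, ParseError
from .panel import SamplePanel
from .sites import VariantSite

_INFO_FIELDS = [
    ("QD", "1", "Float", "Variant confidence divided by depth of coverage"),
    ("AA", "1", "String", "Ancestral allele"),
    ("EFFECT", "1", "String", "Amino-acid effect class (silent/missense/nonsense)"),
    ("DEGEN", "1", "String", "Codon degeneracy class at the site"),
    ("FCLASS", "1", "String", "Combined SIFT/PolyPhen-2 functional class"),
    ("KNOWN", "0", "Flag", "Present in the known-sites list"),
]


def read_vcf(path, panel: Optional[SamplePanel] = None) -> list[VariantSite]:
    """Read a VCF into split per-alternate-allele sites.

    If a panel is given, every VCF sample must belong to it and per-sample
    arrays are ordered by the panel's sample order; otherwise VCF order is
    used.
    """
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    vcf_samples = list(vcf.header.samples)
    if panel is not None:
        missing = [s for s in vcf_samples if s not in panel]
        if missing:
            raise PanelError(f"VCF samples absent from panel: {missing}")
        order = panel.samples
        col = {s: vcf_samples.index(s) for s in order if s in vcf_samples}
        if len(col) != len(order):
            raise PanelError("panel samples missing from VCF: "
                             f"{[s for s in order if s not in vcf_samples]}")
    else:
        order = vcf_samples

    sites: list[VariantSite] = []
    n_rec = 0
    try:
        for rec in vcf:
            n_rec += 1
            alts = rec.alts or ()
            for k, alt in enumerate(alts):
                gts = np.full(len(order), -1, dtype=np.int8)
                gqs = np.full(len(order), -1, dtype=np.int32)
                rds = np.full(len(order), -1, dtype=np.int32)
                ads = np.full(len(order), -1, dtype=np.int32)
                for j, name in enumerate(order):
                    smp = rec.samples[name]
                    gt = smp.get("GT")
                    if gt is not None and any(a is not None for a in gt):
                        gts[j] = sum(1 for a in gt if a == k + 1)
                    gq = smp.get("GQ")
                    if gq is not None:
                        gqs[j] = gq
                    ad = smp.get("AD")
                    if ad is not None and ad[0] is not None:
                        rds[j] = ad[0]
                        if len(ad) > k + 1 and ad[k + 1] is not None:
                            ads[j] = ad[k + 1]
                info = dict(rec.info)
                known = bool(info.pop("KNOWN", False)) or rec.id is not None
                qd = info.pop("QD", None)
                aa = info.pop("AA", None)
                effect = info.pop("EFFECT", None)
                sites.append(VariantSite(
                    chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                    quality=rec.qual,
                    qd=float(qd) if qd is not None else None,
                    genotypes=gts,
                    genotype_quals=gqs if (gqs >= 0).any() else None,
                    ref_depths=rds if (rds >= 0).any() else None,
                    alt_depths=ads if (ads >= 0).any() else None,
                    ancestral=str(aa) if aa is not None else None,
                    known=known,
                    site_class=str(effect) if effect is not None else None,
                    info=info,
                ))
    except ValueError as exc:
        raise ParseError(f"{path}: malformed record #{n_rec + 1}: {exc}") from exc
    return sites


def _default_contigs(sites: Sequence[VariantSite]) -> dict[str, int]:
    contigs: dict[str, int] = {}
    for s in sites:
        contigs[s.chrom] = max(contigs.get(s.chrom, 0), s.pos + len(s.ref) + 1000)
    return contigs


def write_vcf(sites: Sequence[VariantSite], samples: Sequence[str], path,
              contigs: Optional[dict[str, int]] = None,
              depths: Optional[np.ndarray] = None) -> None:
    """Write sites as VCF 4.2 with GT (and DP/GQ/AD where available).

    ``depths`` is an optional (n_sites, n_samples) read-depth matrix written
    to the DP field.
    """
    header = pysam.VariantHeader()
    for name, length in (contigs or _default_contigs(sites)).items():
        header.contigs.add(name, length=int(length))
    for name, num, typ, desc in _INFO_FIELDS:
        header.info.add(name, num, typ, desc)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allele depths (ref, alt)")
    for s in samples:
        header.add_sample(s)

    order = sorted(range(len(sites)), key=lambda i: (sites[i].chrom, sites[i].pos))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in order:
            site = sites[i]
            rec = out.new_record(contig=site.chrom, start=site.pos - 1,
                                 alleles=(site.ref, site.alt))
            if site.quality is not None:
                rec.qual = float(site.quality)
            if site.qd is not None:
                rec.info["QD"] = float(site.qd)
            if site.ancestral is not None:
                rec.info["AA"] = site.ancestral
            if site.site_class is not None:
                rec.info["EFFECT"] = site.site_class
            if site.known:
                rec.info["KNOWN"] = True
            for tag in ("DEGEN", "FCLASS"):
                if tag in site.info:
                    rec.info[tag] = str(site.info[tag])
            for j, name in enumerate(samples):
                smp = rec.samples[name]
                g = int(site.genotypes[j]) if site.genotypes is not None else -1
                smp["GT"] = {0: (0, 0), 1: (0, 1), 2: (1, 1)}.get(g, (None, None))
                if site.genotype_quals is not None and site.genotype_quals[j] >= 0:
                    smp["GQ"] = int(site.genotype_quals[j])
                if depths is not None:
                    smp["DP"] = int(depths[i, j])
                if (site.ref_depths is not None and site.alt_depths is not None
                        and site.ref_depths[j] >= 0 and site.alt_depths[j] >= 0):
                    smp["AD"] = (int(site.ref_depths[j]), int(site.alt_depths[j]))
            out.write(rec)


def read_known_sites(path) -> set[tuple[str, int]]:
    """Read a known-sites list: a VCF or a two-column chrom/pos text file."""
    path = Path(path)
    if path.suffix in {".vcf", ".bcf"} or str(path).endswith(".vcf.gz"):
        return {(s.chrom, s.pos) for s in read_vcf(path)}
    out: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 'chrom pos'")
            out.add((fields[0], int(fields[1])))
    return out


def mark_known(sites: Iterable[VariantSite],
               known: set[tuple[str, int]]) -> None:
    """Set each site's ``known`` flag by (chrom, pos) membership, in place."""
    for s in sites:
        s.known = (s.chrom, s.pos) in known
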