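"""Gene models: ordered CDS intervals with strand and frame.

A gene model is the minimal structure needed for codon arithmetic: the
transcript's CDS intervals (0-based half-open genomic coordinates), the
strand, and the phase of the first coding base. Models are read from a
5-column tabular format (transcript, chrom, start, end, strand[, frame]) or
from GFF3 CDS features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AnnotationError, ParseError

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def _chrom_seq(reference, chrom: str) -> str:
    if isinstance(reference, str):
        return reference
    try:
        return str(reference[chrom])
    except (KeyError, TypeError) as exc:
        raise AnnotationError(f"reference lacks chromosome {chrom!r}") from exc


@dataclass
class GeneModel:
    """CDS structure of one transcript.

    ``intervals`` are genomic 0-based half-open, non-overlapping, stored
    sorted by genomic start; transcription order is start-to-end on '+' and
    end-to-start on '-'. ``frame_offset`` is the number of leading bases of
    the spliced CDS (in transcription order) to skip before the first
    complete codon.
    """
    transcript_id: str
    chrom: str
    strand: str
    intervals: list[tuple[int, int]]
    frame_offset: int = 0
    _starts: np.ndarray = field(init=False, repr=False)
    _ends: np.ndarray = field(init=False, repr=False)
    _cum: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ivs = sorted((int(a), int(b)) for a, b in self.intervals)
        for (a, b), (c, _) in zip(ivs, ivs[1:]):
            if b > c:
                raise ValueError(f"{self.transcript_id}: overlapping CDS intervals")
        if any(a >= b for a, b in ivs):
            raise ValueError(f"{self.transcript_id}: empty CDS interval")
        self.intervals = ivs
        self._starts = np.array([a for a, _ in ivs], dtype=np.int64)
        self._ends = np.array([b for _, b in ivs], dtype=np.int64)
        lengths = self._ends - self._starts
        self._cum = np.concatenate(([0], np.cumsum(lengths)))
        if (self.total_length - self.frame_offset) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {self.total_length} minus "
                f"frame offset {self.frame_offset} is not divisible by 3")

    @property
    def total_length(self) -> int:
        return int(self._cum[-1])

    def contains(self, pos0: int) -> bool:
        i = int(np.searchsorted(self._starts, pos0, side="right")) - 1
        return i >= 0 and pos0 < self._ends[i]

    def spliced_index(self, pos0: int) -> int:
        """Index of a genomic base within the spliced CDS, transcription order.

        Raises AnnotationError if the position is not coding in this model.
        """
        i = int(np.searchsorted(self._starts, pos0, side="right")) - 1
        if i < 0 or pos0 >= self._ends[i]:
            raise AnnotationError(
                f"position {pos0 + 1} not in CDS of {self.transcript_id}")
        plus_index = int(self._cum[i] + (pos0 - self._starts[i]))
        if self.strand == "+":
            return plus_index
        return self.total_length - 1 - plus_index

    def genomic_position(self, spliced_idx: int) -> int:
        """Inverse of :meth:`spliced_index`."""
        if not 0 <= spliced_idx < self.total_length:
            raise AnnotationError(
                f"spliced index {spliced_idx} outside CDS of {self.transcript_id}")
        plus_index = (spliced_idx if self.strand == "+"
                      else self.total_length - 1 - spliced_idx)
        i = int(np.searchsorted(self._cum, plus_index, side="right")) - 1
        return int(self._starts[i] + (plus_index - self._cum[i]))

    def codon_context(self, reference, pos0: int) -> tuple[str, int]:
        """The (codon, offset-within-codon) containing a genomic position.

        The codon is returned in coding (transcription) orientation: bases
        on the '-' strand are complemented. Positions inside an incomplete
        leading codon (frame offset) raise AnnotationError.
        """
        k = self.spliced_index(pos0) - self.frame_offset
        if k < 0:
            raise AnnotationError(
                f"position {pos0 + 1} in incomplete leading codon of "
                f"{self.transcript_id}")
        codon_idx, offset = divmod(k, 3)
        seq = _chrom_seq(reference, self.chrom)
        bases = []
        for j in range(3):
            g = self.genomic_position(self.frame_offset + 3 * codon_idx + j)
            base = seq[g].upper()
            if self.strand == "-":
                base = _COMPLEMENT.get(base, "N")
            bases.append(base)
        return "".join(bases), offset


def read_gene_models_tab(path) -> list[GeneModel]:
    """Read the tabular CDS format: transcript, chrom, start, end, strand
    [, frame], one row per CDS interval, frame taken from the first interval
    in transcription order."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["transcript", "chrom", "start", "end", "strand",
                            "frame"],
                     dtype={"transcript": str, "chrom": str})
    if df["strand"].isna().any():
        raise ParseError(f"{path}: rows need >= 5 columns")
    models = []
    for tid, group in df.groupby("transcript", sort=False):
        strand = group["strand"].iloc[0]
        ivs = list(zip(group["start"].astype(int), group["end"].astype(int)))
        first = (group.loc[group["start"].idxmin()] if strand == "+"
                 else group.loc[group["end"].idxmax()])
        frame = first.get("frame")
        frame = 0 if pd.isna(frame) else int(frame)
        models.append(GeneModel(str(tid), str(group["chrom"].iloc[0]),
                                str(strand), ivs, frame))
    return models


def read_gene_models_gff3(path) -> list[GeneModel]:
    """Read CDS features from GFF3, grouped by their Parent attribute."""
    import gffutils
    try:
        db = gffutils.create_db(str(path), ":memory:", force=True,
                                keep_order=True, merge_strategy="create_unique")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    groups: dict[str, dict] = {}
    for f in db.features_of_type("CDS"):
        parents = f.attributes.get("Parent", [f.id])
        phase = 0 if f.frame in (None, ".", "") else int(f.frame)
        for parent in parents:
            g = groups.setdefault(parent, {"chrom": f.seqid,
                                           "strand": f.strand, "rows": []})
            g["rows"].append((f.start - 1, f.end, phase))  # GFF3 is 1-based
    models = []
    for tid, g in groups.items():
        rows = sorted(g["rows"])
        frame = rows[0][2] if g["strand"] == "+" else max(
            rows, key=lambda r: r[1])[2]
        models.append(GeneModel(tid, g["chrom"], g["strand"],
                                [(a, b) for a, b, _ in rows], frame))
    return models


def read_gene_models(path) -> list[GeneModel]:
    """Dispatch on extension: .gff/.gff3 vs tabular."""
    p = str(path)
    if p.endswith((".gff", ".gff3")):
        return read_gene_models_gff3(path)
    return read_gene_models_tab(path)


def models_at(models: Sequence[GeneModel], chrom: str, pos0: int
              ) -> list[GeneModel]:
    return [m for m in models if m.chrom == chrom and m.contains(pos0)]
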