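"""Domain model: genes, transcripts, reads, intervals, statistical results.

Coordinates are 0-based half-open throughout; GTF's 1-based closed
convention is converted at the parser boundary.  Transcript sequences are
stored 5'->3' sense, DNA alphabet (U mapped to T at load).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

# Ensembl gene biotypes classed as mRNA.
MRNA_BIOTYPES = frozenset({"protein_coding", "translated_processed_pseudogene"})

# Ensembl gene biotypes classed as lncRNA (17 biotypes).
LNCRNA_BIOTYPES = frozenset({
    "lincRNA",
    "antisense_RNA",
    "bidirectional_promoter_lncRNA",
    "macro_lncRNA",
    "non_coding",
    "processed_transcript",
    "sense_intronic",
    "sense_overlapping",
    "3prime_overlapping_ncRNA",
    "polymorphic_pseudogene",
    "processed_pseudogene",
    "pseudogene",
    "transcribed_processed_pseudogene",
    "transcribed_unitary_pseudogene",
    "transcribed_unprocessed_pseudogene",
    "unitary_pseudogene",
    "unprocessed_pseudogene",
})

_LNC_SUBTYPE_MAP = {
    "lincRNA": "lincRNA",
    "antisense_RNA": "antisense",
    "sense_intronic": "sense_intronic",
    "sense_overlapping": "sense_overlapping",
}


def classify_biotype(raw_biotype: str) -> str:
    """Map an Ensembl gene biotype to one of {mRNA, lncRNA, rRNA, other}."""
    if raw_biotype in MRNA_BIOTYPES:
        return "mRNA"
    if raw_biotype in LNCRNA_BIOTYPES:
        return "lncRNA"
    if raw_biotype in ("rRNA", "Mt_rRNA"):
        return "rRNA"
    return "other"


def lnc_subtype(raw_biotype: str) -> Optional[str]:
    """Subtype label for lncRNA-classed biotypes, else None."""
    if raw_biotype not in LNCRNA_BIOTYPES:
        return None
    if raw_biotype in _LNC_SUBTYPE_MAP:
        return _LNC_SUBTYPE_MAP[raw_biotype]
    if "pseudogene" in raw_biotype:
        return "pseudogene"
    return "other"


@dataclass
class TranscriptModel:
    """A spliced transcript.

    ``exons`` are genomic (start, end) intervals ordered 5'->3' along the
    transcript (descending genomic coordinate on the minus strand).
    ``cds`` is an optional (start, end) interval in *transcript* coordinates.
    """

    transcript_id: str
    gene_id: str
    exons: list[tuple[int, int]]
    sequence: str
    strand: str = "+"
    cds: Optional[tuple[int, int]] = None
    is_primary: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    def tx_to_genomic(self, pos: int) -> int:
        """Map a transcript coordinate to a genomic coordinate."""
        if not 0 <= pos < self.length:
            raise ValueError(f"transcript position {pos} outside [0, {self.length})")
        off = pos
        for s, e in self.exons:
            w = e - s
            if off < w:
                return s + off if self.strand == "+" else e - 1 - off
            off -= w
        raise AssertionError("unreachable: exon lengths inconsistent with sequence")

    def validate(self) -> None:
        exon_len = sum(e - s for s, e in self.exons)
        if exon_len != self.length:
            raise ValueError(
                f"{self.transcript_id}: exon span {exon_len} != sequence length {self.length}"
            )
        if self.cds is not None:
            cs, ce = self.cds
            if not (0 <= cs < ce <= self.length):
                raise ValueError(f"{self.transcript_id}: CDS {self.cds} outside transcript")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    span: tuple[int, int]
    raw_biotype: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def biotype_class(self) -> str:
        return classify_biotype(self.raw_biotype)

    @property
    def lnc_subtype(self) -> Optional[str]:
        return lnc_subtype(self.raw_biotype)

    @property
    def primary_transcript(self) -> TranscriptModel:
        """Longest transcript; ties broken by lexicographically smallest id."""
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: no transcripts")
        return min(self.transcripts, key=lambda t: (-t.length, t.transcript_id))


@dataclass
class Read:
    read_id: str
    umi: str
    sequence: str
    quality: Optional[str] = None
    sample_id: str = ""


@dataclass(frozen=True)
class Interval:
    """A genomic interval (0-based half-open), e.g. a CLIP peak."""

    chrom: str
    start: int
    end: int
    name: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"interval start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class StatResult:
    statistic: float
    p_value: float
    df: Optional[float] = None
    estimate: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
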