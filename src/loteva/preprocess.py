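"""Read-level pipeline stages.

Fixed stage order: trim -> low-complexity filter -> rRNA screen ->
transcriptome pseudo-alignment -> UMI/positional duplicate removal.

The aligner is a seed-and-diagonal k-mer pseudo-aligner over the spliced
transcriptome: a read is compatible with every transcript sharing at least
``min_hits`` seed k-mers on one diagonal.  Duplicate removal groups reads
by (sample, transcript, UMI) and greedily clusters 5' offsets within a
half-read-length window (38 bp for 75-nt reads), keeping one read per
cluster.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np

from .io import revcomp
from .models import GeneModel, Read

logger = logging.getLogger("loteva")


@dataclass
class AlignmentSet:
    read_id: str
    umi: str
    sample_id: str
    compatible_transcripts: frozenset = frozenset()
    primary_transcript: Optional[str] = None
    offset: int = 0
    aligned_length: int = 0

    @property
    def mapped(self) -> bool:
        return self.primary_transcript is not None


def trim_reads(reads: Iterable[Read], n_trim: int = 5,
               min_length: int = 20) -> Iterator[Read]:
    """Remove the first ``n_trim`` bases (adapter) from each read.

    Reads left shorter than ``min_length`` are discarded; the count is
    logged.
    """
    if n_trim < 0:
        raise ValueError("n_trim must be >= 0")
    n_discarded = 0
    for r in reads:
        if len(r.sequence) < n_trim + min_length:
            n_discarded += 1
            continue
        yield Read(read_id=r.read_id, umi=r.umi,
                   sequence=r.sequence[n_trim:],
                   quality=r.quality[n_trim:] if r.quality else None,
                   sample_id=r.sample_id)
    if n_discarded:
        logger.info("trim_reads: discarded %d short reads", n_discarded)


def complexity_score(seq: str) -> float:
    """Shannon entropy of overlapping trinucleotide frequencies on [0, 100].

    H is computed in nats over the 3-mer distribution and rescaled by
    log(min(64, L - 2)), the maximum achievable entropy for the read.
    Reads shorter than 3 nt score 0.
    """
    n = len(seq) - 2
    if n < 1:
        return 0.0
    counts: dict[str, int] = defaultdict(int)
    for i in range(n):
        counts[seq[i:i + 3]] += 1
    freqs = np.array(list(counts.values()), dtype=float) / n
    h = -np.sum(freqs * np.log(freqs))
    denom = math.log(min(64, n))
    if denom == 0.0:
        return 0.0
    return float(100.0 * h / denom)


def filter_low_complexity(reads: Iterable[Read],
                          threshold: float = 70.0) -> Iterator[Read]:
    """Drop reads whose trinucleotide-entropy score falls below ``threshold``."""
    if not 0.0 <= threshold <= 100.0:
        raise ValueError("threshold must lie in [0, 100]")
    n_removed = 0
    n_total = 0
    for r in reads:
        n_total += 1
        if complexity_score(r.sequence) < threshold:
            n_removed += 1
            continue
        yield r
    logger.info("filter_low_complexity: removed %d / %d reads", n_removed, n_total)


def build_rrna_kmers(rrna_seqs: dict[str, str], k: int = 25) -> set[str]:
    """Exact k-mer set over both strands of the rRNA reference."""
    kmers: set[str] = set()
    for seq in rrna_seqs.values():
        seq = seq.upper()
        for s in (seq, revcomp(seq)):
            for i in range(len(s) - k + 1):
                kmers.add(s[i:i + k])
    return kmers


def screen_rrna(reads: Iterable[Read], rrna_kmers: set[str],
                k: int = 25) -> tuple[list[Read], int]:
    """Exclude reads sharing any exact k-mer with the rRNA reference.

    Returns (kept reads, number flagged as rRNA).  An empty reference keeps
    everything with a warning.
    """
    if not rrna_kmers:
        logger.warning("screen_rrna: empty rRNA reference, keeping all reads")
        reads = list(reads)
        return reads, 0
    kept: list[Read] = []
    n_rrna = 0
    for r in reads:
        if len(r.sequence) < k:
            raise ValueError(
                f"read {r.read_id}: length {len(r.sequence)} < k={k}"
            )
        hit = any(r.sequence[i:i + k] in rrna_kmers
                  for i in range(len(r.sequence) - k + 1))
        if hit:
            n_rrna += 1
        else:
            kept.append(r)
    logger.info("screen_rrna: flagged %d reads as rRNA", n_rrna)
    return kept, n_rrna


class TranscriptomeIndex:
    """Exact k-mer index over transcript sequences (sense strand)."""

    def __init__(self, genes: Iterable[GeneModel], k: int = 21):
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        self.lengths: dict[str, int] = {}
        self.tx_gene: dict[str, str] = {}
        for g in genes:
            for t in g.transcripts:
                seq = t.sequence.upper()
                self.lengths[t.transcript_id] = len(seq)
                self.tx_gene[t.transcript_id] = g.gene_id
                for i in range(len(seq) - k + 1):
                    self.index[seq[i:i + k]].append((t.transcript_id, i))
        self.index = dict(self.index)


def pseudoalign(reads: Iterable[Read], index: TranscriptomeIndex,
                min_hits: int = 2, stride: int = 4) -> Iterator[AlignmentSet]:
    """Assign each read its compatible transcript set and primary position.

    Seed k-mers are taken every ``stride`` bases; a transcript is compatible
    when at least ``min_hits`` seeds agree on one diagonal (offset = k-mer
    transcript position minus read position).  The primary position is the
    transcript with the most consistent seeds, ties broken by the smaller
    inferred 5' offset then transcript id.  Unmapped reads are emitted with
    ``mapped == False``.
    """
    k = index.k
    for r in reads:
        seq = r.sequence.upper()
        diag_hits: dict[tuple[str, int], int] = defaultdict(int)
        positions = range(0, max(1, len(seq) - k + 1), stride)
        for off in positions:
            for tid, pos in index.index.get(seq[off:off + k], ()):
                diag_hits[(tid, pos - off)] += 1
        best: dict[str, tuple[int, int]] = {}
        for (tid, diag), cnt in diag_hits.items():
            if cnt >= min_hits:
                cur = best.get(tid)
                if cur is None or (-cnt, diag) < (-cur[0], cur[1]):
                    best[tid] = (cnt, diag)
        if not best:
            yield AlignmentSet(read_id=r.read_id, umi=r.umi,
                               sample_id=r.sample_id)
            continue
        primary = min(best, key=lambda t: (-best[t][0], best[t][1], t))
        offset = max(0, best[primary][1])
        yield AlignmentSet(
            read_id=r.read_id, umi=r.umi, sample_id=r.sample_id,
            compatible_transcripts=frozenset(best),
            primary_transcript=primary, offset=offset,
            aligned_length=len(seq),
        )


def dedup_umi(alignments: Iterable[AlignmentSet],
              read_length: int = 75) -> tuple[list[AlignmentSet], int]:
    """Remove UMI/positional PCR duplicates.

    Reads sharing (sample, primary transcript, UMI) are sorted by 5' offset
    and clustered greedily: a read joins the open cluster iff its offset
    lies within ``ceil(read_length / 2)`` (38 for 75-nt reads) of the
    cluster's first read.  One read per cluster is kept: the cluster anchor
    (first by offset, ties broken by smallest read_id), which makes the
    operation idempotent.  Unmapped reads pass through untouched.  Returns
    (retained alignments, number removed).
    """
    window = math.ceil(read_length / 2)
    groups: dict[tuple, list[AlignmentSet]] = defaultdict(list)
    passthrough: list[AlignmentSet] = []
    for a in alignments:
        if not a.mapped:
            passthrough.append(a)
        else:
            groups[(a.sample_id, a.primary_transcript, a.umi)].append(a)
    kept: list[AlignmentSet] = []
    n_removed = 0
    for members in groups.values():
        members.sort(key=lambda a: (a.offset, a.read_id))
        cluster: list[AlignmentSet] = []
        anchor = None
        for a in members:
            if anchor is not None and a.offset - anchor <= window:
                cluster.append(a)
            else:
                if cluster:
                    kept.append(cluster[0])
                    n_removed += len(cluster) - 1
                cluster = [a]
                anchor = a.offset
        if cluster:
            kept.append(cluster[0])
            n_removed += len(cluster) - 1
    logger.info("dedup_umi: removed %d duplicate reads", n_removed)
    return kept + passthrough, n_removed


def preprocess_sample(reads: Iterable[Read], index: TranscriptomeIndex,
                      rrna_kmers: set[str], n_trim: int = 5,
                      complexity_threshold: float = 70.0,
                      rrna_k: int = 25, min_hits: int = 2,
                      read_length: int = 75) -> tuple[list[AlignmentSet], dict]:
    """Run the full fixed-order read pipeline for one sample.

    Returns deduplicated alignments plus a counter dict for logging.
    """
    trimmed = trim_reads(reads, n_trim=n_trim)
    complex_ok = filter_low_complexity(trimmed, threshold=complexity_threshold)
    kept, n_rrna = screen_rrna(complex_ok, rrna_kmers, k=rrna_k)
    aligned = list(pseudoalign(iter(kept), index, min_hits=min_hits))
    deduped, n_dup = dedup_umi(aligned, read_length=read_length)
    stats = {
        "n_after_rrna": len(kept),
        "n_rrna": n_rrna,
        "n_mapped": sum(a.mapped for a in aligned),
        "n_duplicates_removed": n_dup,
        "n_final": sum(a.mapped for a in deduped),
    }
    return deduped, stats
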