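"""Readers and writers for the standard formats the pipeline touches.

GTF (Ensembl-dialect attributes), FASTA, FASTQ with UMIs either in a
header comment tag ``UMI:<seq>`` or as a read prefix, BED3+, and the
round-trip writers used by the synthetic-data generator.
"""

from __future__ import annotations

import logging
import os
import re
import textwrap
from typing import Iterable, Iterator, Optional

import gffutils
import pyfaidx
from Bio import SeqIO

from .models import GeneModel, Interval, Read, TranscriptModel

logger = logging.getLogger("loteva")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _genomic_to_tx(pos: int, exons: list[tuple[int, int]], strand: str) -> int:
    """Map a genomic coordinate to a transcript coordinate.

    ``exons`` must be in 5'->3' transcript order.
    """
    off = 0
    for s, e in exons:
        if s <= pos < e:
            return off + (pos - s) if strand == "+" else off + (e - 1 - pos)
        off += e - s
    raise ValueError(f"genomic position {pos} not exonic")


def parse_annotation(gtf_path, fasta_path) -> list[GeneModel]:
    """Parse a GTF + genome FASTA into GeneModel objects.

    Transcript sequences are the spliced exon sequences, reverse-complemented
    for minus-strand genes.  Transcripts with overlapping exons are rejected
    with a logged diagnostic; a missing chromosome raises naming it.
    """
    with open(gtf_path) as fh:
        has_records = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_records:
        return []

    db = gffutils.create_db(
        str(gtf_path), ":memory:",
        disable_infer_genes=True, disable_infer_transcripts=True,
        keep_order=True,
    )
    genome = pyfaidx.Fasta(str(fasta_path))

    genes: list[GeneModel] = []
    n_rejected = 0
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        if g.seqid not in genome:
            raise ValueError(f"chromosome {g.seqid!r} absent from FASTA")
        biotype = g.attributes.get("gene_biotype", ["unknown"])[0]
        gene = GeneModel(
            gene_id=g.attributes["gene_id"][0],
            chrom=g.seqid, strand=g.strand,
            span=(g.start - 1, g.end),
            raw_biotype=biotype,
        )
        for t in db.children(g, featuretype="transcript", order_by="start"):
            tid = t.attributes["transcript_id"][0]
            exons = sorted(
                (ex.start - 1, ex.end)
                for ex in db.children(t, featuretype="exon")
            )
            if any(exons[i][1] > exons[i + 1][0] for i in range(len(exons) - 1)):
                logger.warning("rejecting transcript %s: overlapping exons", tid)
                n_rejected += 1
                continue
            parts = [str(genome[g.seqid][s:e]) for s, e in exons]
            seq = "".join(parts).upper()
            if t.strand == "-":
                seq = revcomp(seq)
                exons = exons[::-1]
            cds_ivs = sorted(
                (c.start - 1, c.end) for c in db.children(t, featuretype="CDS")
            )
            cds = None
            if cds_ivs:
                gmin = cds_ivs[0][0]
                gmax = cds_ivs[-1][1] - 1
                a = _genomic_to_tx(gmin, exons, t.strand)
                b = _genomic_to_tx(gmax, exons, t.strand)
                cds = (min(a, b), max(a, b) + 1)
            tx = TranscriptModel(
                transcript_id=tid, gene_id=gene.gene_id,
                exons=exons, sequence=seq, strand=t.strand, cds=cds,
            )
            tx.validate()
            gene.transcripts.append(tx)
        if gene.transcripts:
            prim = gene.primary_transcript
            for tx in gene.transcripts:
                tx.is_primary = tx is prim
            genes.append(gene)
    if n_rejected:
        logger.warning("rejected %d transcripts with overlapping exons", n_rejected)
    logger.info("parsed %d genes", len(genes))
    return genes


_UMI_RE = re.compile(r"UMI:([ACGTNacgtn]+)")


def parse_fastq_umi(fastq_path, umi_scheme: Optional[dict] = None,
                    sample_id: str = "") -> Iterator[Read]:
    """Stream UMI-tagged reads from FASTQ.

    ``umi_scheme`` is ``{"type": "header"}`` (tag ``UMI:<seq>`` in the read
    comment; default) or ``{"type": "prefix", "length": k}`` (UMI = first k
    bases, removed from the sequence).
    """
    scheme = umi_scheme or {"type": "header"}
    kind = scheme.get("type", "header")
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        seq = str(rec.seq)
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        if kind == "header":
            m = _UMI_RE.search(rec.description)
            if not m:
                raise ValueError(f"read {rec.id}: no UMI:<seq> tag in header")
            umi = m.group(1).upper()
        elif kind == "prefix":
            k = int(scheme["length"])
            if len(seq) < k:
                raise ValueError(f"read {rec.id}: shorter than UMI length {k}")
            umi, seq, qual = seq[:k].upper(), seq[k:], qual[k:]
        else:
            raise ValueError(f"unknown umi scheme {kind!r}")
        yield Read(read_id=rec.id, umi=umi, sequence=seq, quality=qual,
                   sample_id=sample_id)


def parse_bed(bed_path) -> list[Interval]:
    """Parse a BED3+ file (0-based half-open, kept as-is).

    A line with start >= end is rejected with its line number.
    """
    out: list[Interval] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"BED line {lineno}: fewer than 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"BED line {lineno}: start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 else "."
            out.append(Interval(chrom=chrom, start=start, end=end, name=name))
    return out


# ---------------------------------------------------------------- writers

def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            fh.write(textwrap.fill(seq, width) + "\n")


def _gtf_attrs(**kv) -> str:
    return " ".join(f'{k} "{v}";' for k, v in kv.items())


def write_gtf(genes: Iterable[GeneModel], path) -> None:
    """Write genes as Ensembl-dialect GTF (1-based closed on disk)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write("\t".join([
                g.chrom, "loteva", "gene", str(g.span[0] + 1), str(g.span[1]),
                ".", g.strand, ".",
                _gtf_attrs(gene_id=g.gene_id, gene_biotype=g.raw_biotype),
            ]) + "\n")
            for t in g.transcripts:
                lo = min(s for s, _ in t.exons)
                hi = max(e for _, e in t.exons)
                attrs = _gtf_attrs(gene_id=g.gene_id, transcript_id=t.transcript_id,
                                   gene_biotype=g.raw_biotype)
                fh.write("\t".join([
                    g.chrom, "loteva", "transcript", str(lo + 1), str(hi),
                    ".", t.strand, ".", attrs,
                ]) + "\n")
                for s, e in sorted(t.exons):
                    fh.write("\t".join([
                        g.chrom, "loteva", "exon", str(s + 1), str(e),
                        ".", t.strand, ".", attrs,
                    ]) + "\n")
                if t.cds is not None:
                    # emit CDS as genomic intervals, split across exons
                    for s, e in _tx_interval_to_genomic(t):
                        fh.write("\t".join([
                            g.chrom, "loteva", "CDS", str(s + 1), str(e),
                            ".", t.strand, ".", attrs,
                        ]) + "\n")


def _tx_interval_to_genomic(t: TranscriptModel) -> list[tuple[int, int]]:
    """Genomic intervals covered by the transcript's CDS."""
    cs, ce = t.cds
    out = []
    off = 0
    for s, e in t.exons:  # 5'->3' order
        w = e - s
        lo = max(cs, off)
        hi = min(ce, off + w)
        if lo < hi:
            if t.strand == "+":
                out.append((s + (lo - off), s + (hi - off)))
            else:
                out.append((e - (hi - off), e - (lo - off)))
        off += w
    return sorted(out)


def write_fastq(reads: Iterable[Read], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.quality or "I" * len(r.sequence)
            fh.write(f"@{r.read_id} UMI:{r.umi}\n{r.sequence}\n+\n{qual}\n")


def write_bed(intervals: Iterable[Interval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def ensure_dir(path) -> None:
    os.makedirs(path, exist_ok=True)
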