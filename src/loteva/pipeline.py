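"""End-to-end convenience wiring: raw reads -> gene count matrix.

Runs the fixed stage order (trim, low-complexity filter, rRNA screen,
pseudo-alignment, UMI dedup) per sample, then equivalence-class EM and
gene aggregation, producing the matrices the differential stages consume.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import pandas as pd

from .models import GeneModel, Read
from .preprocess import (TranscriptomeIndex, build_rrna_kmers,
                         preprocess_sample)
from .quantify import aggregate_genes, counts_matrix, quantify_sample


def run_sample_pipeline(reads_by_sample: dict[str, Iterable[Read]],
                        genes: Sequence[GeneModel],
                        rrna_seqs: Optional[dict[str, str]] = None,
                        n_trim: int = 5, read_length: int = 75,
                        frag_len_mean: float = 200.0,
                        align_k: int = 21, rrna_k: int = 25,
                        detection_groups: Optional[dict[str, list[str]]] = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Process every sample and return (gene table, counts matrix, alignments).

    The gene table is the long (gene_id, sample, est_counts, tpm) frame from
    :func:`loteva.quantify.aggregate_genes`; the counts matrix is its
    est_counts pivot; alignments maps sample -> deduplicated AlignmentSets
    (for coverage analysis).
    """
    index = TranscriptomeIndex(genes, k=align_k)
    rrna_kmers = build_rrna_kmers(rrna_seqs or {}, k=rrna_k)
    tx_lengths = {t.transcript_id: t.length
                  for g in genes for t in g.transcripts}
    tx_tables = {}
    alignments = {}
    for sample, reads in reads_by_sample.items():
        deduped, _stats = preprocess_sample(
            iter(reads), index, rrna_kmers, n_trim=n_trim,
            rrna_k=rrna_k, read_length=read_length)
        alignments[sample] = deduped
        tx_tables[sample] = quantify_sample(
            (a for a in deduped if a.mapped), tx_lengths,
            frag_len_mean=frag_len_mean)
    gene_table = aggregate_genes(tx_tables, genes,
                                 detection_groups=detection_groups)
    return gene_table, counts_matrix(gene_table), alignments
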