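"""Transcript feature extraction, group comparisons, half-life estimation,
CLIP-peak target enrichment and lncRNA pairing analyses.

All per-gene features are computed on the primary transcript (the longest
one).  AU-rich-element density counts possibly overlapping AUUUA (ATTTA in
DNA) pentamers per kilobase of the region; the canonical pentamer is the
minimal ARE definition and the motif is configurable.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import GeneModel, Interval, StatResult
from .stats import fisher_exact, pearson, welch_t

logger = logging.getLogger("loteva")

ARE_MOTIF = "ATTTA"


def count_overlapping(seq: str, motif: str) -> int:
    """Number of (possibly overlapping) motif occurrences in seq."""
    n = 0
    start = seq.find(motif)
    while start != -1:
        n += 1
        start = seq.find(motif, start + 1)
    return n


def _density_per_kb(seq: str, motif: str = ARE_MOTIF) -> float:
    if len(seq) < len(motif):
        return 0.0
    return count_overlapping(seq, motif) / (len(seq) / 1000.0)


def extract_features(genes: Sequence[GeneModel],
                     halflife: Optional[pd.Series] = None,
                     are_motif: str = ARE_MOTIF) -> pd.DataFrame:
    """Per-gene feature table from primary transcripts.

    Columns: biotype_class, length, utr5_len/cds_len/utr3_len (mRNA with
    annotated CDS only), exons_per_kb, gc_pct, are_per_kb_5utr,
    are_per_kb_3utr, halflife_h (when a table is supplied).
    """
    rows = []
    for g in genes:
        t = g.primary_transcript
        seq = t.sequence.upper()
        L = t.length
        gc = 100.0 * sum(seq.count(b) for b in "GC") / L if L else 0.0
        row = {
            "gene_id": g.gene_id,
            "biotype_class": g.biotype_class,
            "length": L,
            "exons_per_kb": t.exon_count / (L / 1000.0),
            "gc_pct": gc,
            "utr5_len": np.nan, "cds_len": np.nan, "utr3_len": np.nan,
            "are_per_kb_5utr": np.nan, "are_per_kb_3utr": np.nan,
        }
        if g.biotype_class == "mRNA":
            if t.cds is None:
                logger.warning("mRNA gene %s lacks CDS annotation", g.gene_id)
            else:
                cs, ce = t.cds
                row.update({
                    "utr5_len": cs, "cds_len": ce - cs, "utr3_len": L - ce,
                    "are_per_kb_5utr": _density_per_kb(seq[:cs], are_motif),
                    "are_per_kb_3utr": _density_per_kb(seq[ce:], are_motif),
                })
        rows.append(row)
    df = pd.DataFrame(rows).set_index("gene_id")
    if halflife is not None:
        df["halflife_h"] = halflife.reindex(df.index)
    return df


def compare_groups(features: pd.DataFrame, enriched: Iterable[str],
                   depleted: Iterable[str],
                   fields: Sequence[str]) -> pd.DataFrame:
    """Per-field medians and Welch p between EV-enriched and EV-depleted genes.

    Also reports the all-genes median as the reference line.  Fields with
    fewer than 2 finite values in either group, or degenerate variance, are
    skipped with a warning.
    """
    enriched = [g for g in enriched if g in features.index]
    depleted = [g for g in depleted if g in features.index]
    if not enriched or not depleted:
        raise ValueError("both gene sets must be nonempty")
    rows = []
    for f in fields:
        a = features.loc[enriched, f].dropna().to_numpy(dtype=float)
        b = features.loc[depleted, f].dropna().to_numpy(dtype=float)
        if len(a) < 2 or len(b) < 2:
            logger.warning("compare_groups: %s has < 2 finite values, skipped", f)
            continue
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            logger.warning("compare_groups: %s is constant, skipped", f)
            continue
        try:
            res = welch_t(a, b)
        except ValueError as err:
            logger.warning("compare_groups: %s skipped (%s)", f, err)
            continue
        rows.append({
            "field": f,
            "median_enriched": float(np.median(a)),
            "median_depleted": float(np.median(b)),
            "median_all": float(features[f].dropna().median()),
            "t": res.statistic, "p": res.p_value,
            "n_enriched": len(a), "n_depleted": len(b),
        })
    if not rows:
        return pd.DataFrame(columns=["median_enriched", "median_depleted",
                                     "median_all", "t", "p"])
    return pd.DataFrame(rows).set_index("field")


def estimate_half_life(timecourse: pd.DataFrame, times: Sequence[float],
                       ) -> pd.Series:
    """Per-gene half-life (hours) from a transcription-shutoff timecourse.

    Least-squares fit of ln(abundance) against time; halflife = ln2 / -slope
    for decaying genes.  Genes with fewer than 3 positive observations, or
    with non-negative slope (stable), get NaN.
    """
    times = np.asarray(times, dtype=float)
    if timecourse.shape[1] != times.size:
        raise ValueError("timecourse columns must match times")
    if times.size < 3:
        raise ValueError("need at least 3 timepoints")
    vals = timecourse.to_numpy(dtype=float)
    out = np.full(vals.shape[0], np.nan)
    for i in range(vals.shape[0]):
        mask = vals[i] > 0
        if mask.sum() < 3:
            continue
        slope = np.polyfit(times[mask], np.log(vals[i, mask]), 1)[0]
        if slope < 0:
            out[i] = np.log(2) / -slope
    return pd.Series(out, index=timecourse.index, name="halflife_h")


def genes_bound_by_peaks(peaks: Sequence[Interval],
                         genes: Sequence[GeneModel],
                         exonic_only: bool = False) -> pd.Series:
    """Flag genes overlapped by at least one peak (half-open intervals).

    Default uses the genomic gene span; ``exonic_only`` restricts to exons.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for p in peaks:
        by_chrom[p.chrom].append((p.start, p.end))
    arrs = {c: (np.array([s for s, _ in ivs]), np.array([e for _, e in ivs]))
            for c, ivs in by_chrom.items()}
    flags = {}
    for g in genes:
        ivs = ([(s, e) for t in g.transcripts for s, e in t.exons]
               if exonic_only else [g.span])
        bound = False
        if g.chrom in arrs:
            starts, ends = arrs[g.chrom]
            for s, e in ivs:
                if bool(np.any((starts < e) & (ends > s))):
                    bound = True
                    break
        flags[g.gene_id] = bound
    return pd.Series(flags, name="clip_bound")


def clip_target_enrichment(peaks: Sequence[Interval],
                           genes: Sequence[GeneModel],
                           enriched: Iterable[str], expressed: Iterable[str],
                           exonic_only: bool = False,
                           ) -> tuple[pd.Series, StatResult]:
    """Fisher test: CLIP-bound fraction of EV-enriched vs other expressed genes."""
    bound = genes_bound_by_peaks(peaks, genes, exonic_only=exonic_only)
    enriched = set(enriched)
    rest = set(expressed) - enriched
    if not peaks:
        logger.warning("clip_target_enrichment: no peaks supplied")
        return bound, StatResult(statistic=1.0, p_value=1.0)
    b_e = int(bound.reindex(sorted(enriched)).fillna(False).sum())
    b_r = int(bound.reindex(sorted(rest)).fillna(False).sum())
    table = [[b_e, len(enriched) - b_e], [b_r, len(rest) - b_r]]
    res = fisher_exact(table, alternative="greater")
    res.extra.update({
        "bound_fraction_enriched": b_e / max(1, len(enriched)),
        "bound_fraction_rest": b_r / max(1, len(rest)),
    })
    return bound, res


@dataclass
class PairReport:
    result: StatResult
    table: pd.DataFrame


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    if _overlap(a, b) > 0:
        return 0
    return max(a[0], b[0]) - min(a[1], b[1])


def pair_correlation(genes: Sequence[GeneModel], diff: pd.DataFrame,
                     mode: str) -> PairReport:
    """Correlate EV-vs-cell log2fd between paired lncRNA and protein-coding genes.

    ``mode`` 'antisense_pc' pairs each antisense lncRNA with the
    protein-coding gene it overlaps on the opposite strand (largest overlap
    wins); 'lincRNA_neighbor' pairs each lincRNA with its nearest
    protein-coding gene by genomic gap on either strand (smallest gap wins).
    Ties break to the smallest partner gene_id.  Only pairs with both genes
    in ``diff`` contribute.
    """
    pc = [g for g in genes if g.biotype_class == "mRNA"]
    pairs = []
    if mode == "antisense_pc":
        for g in genes:
            if g.lnc_subtype != "antisense":
                continue
            cands = [
                (-_overlap(g.span, h.span), h.gene_id) for h in pc
                if h.chrom == g.chrom and h.strand != g.strand
                and _overlap(g.span, h.span) > 0
            ]
            if cands:
                pairs.append((g.gene_id, min(cands)[1]))
    elif mode == "lincRNA_neighbor":
        for g in genes:
            if g.lnc_subtype != "lincRNA":
                continue
            cands = [(_gap(g.span, h.span), h.gene_id) for h in pc
                     if h.chrom == g.chrom]
            if cands:
                pairs.append((g.gene_id, min(cands)[1]))
    else:
        raise ValueError(f"unknown pairing mode {mode!r}")

    rows = [
        (lnc, pcg, diff.loc[lnc, "log2fd"], diff.loc[pcg, "log2fd"])
        for lnc, pcg in pairs if lnc in diff.index and pcg in diff.index
    ]
    table = pd.DataFrame(rows, columns=["lnc_gene", "pc_gene",
                                        "lnc_log2fd", "pc_log2fd"])
    if len(table) < 3:
        raise ValueError("fewer than 3 pairs")
    res = pearson(table["lnc_log2fd"], table["pc_log2fd"])
    return PairReport(result=res, table=table)
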