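"""Equivalence-class EM abundance estimation and coverage-extent statistic.

Multi-mapping reads are reduced to equivalence classes (the set of
transcripts compatible with the read); an EM over the class multinomial
likelihood apportions each class's count among its member transcripts.
TPM normalizes estimated counts by effective length to parts per million.

The coverage-extent statistic measures, per gene, what fraction of the
coding sequence (mRNA) or whole transcript (lncRNA) lies between the
5'-most and 3'-most mapped reads, with cell replicates subsampled to the
paired EV replicate's mapped depth first.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import GeneModel
from .preprocess import AlignmentSet

logger = logging.getLogger("loteva")


def build_equiv_classes(alignments: Iterable[AlignmentSet]) -> Counter:
    """Count reads per compatible-transcript set; unmapped reads are skipped."""
    classes: Counter = Counter()
    n_unmapped = 0
    for a in alignments:
        if not a.mapped:
            n_unmapped += 1
            continue
        classes[a.compatible_transcripts] += 1
    if n_unmapped:
        logger.info("build_equiv_classes: %d unmapped reads excluded", n_unmapped)
    return classes


def effective_length(length: float, frag_len_mean: float) -> float:
    return max(1.0, length - frag_len_mean + 1.0)


def em_quantify(classes: Counter, tx_lengths: dict[str, int],
                frag_len_mean: float = 200.0, tol: float = 1e-8,
                max_iter: int = 1000) -> pd.DataFrame:
    """EM over equivalence-class counts.

    The read-generating probability of transcript t is alpha_t (its share of
    reads); a class's count is allocated among member transcripts
    proportionally to alpha.  Iterates until the largest change in alpha is
    below ``tol``.  Returns a frame indexed by transcript_id with columns
    est_counts and tpm (tpm_t = 1e6 * (est_counts_t / efflen_t) / sum).
    """
    tids = sorted(tx_lengths)
    pos = {t: i for i, t in enumerate(tids)}
    eff = np.array([effective_length(tx_lengths[t], frag_len_mean) for t in tids])
    n_tx = len(tids)
    class_members = []
    class_counts = []
    for members, count in sorted(classes.items(),
                                 key=lambda kv: sorted(kv[0])):
        idx = np.array([pos[t] for t in members if t in pos], dtype=int)
        if idx.size == 0:
            continue
        class_members.append(idx)
        class_counts.append(count)
    total = float(sum(class_counts))

    alpha = np.full(n_tx, 1.0 / n_tx)
    converged = False
    if total > 0:
        for _ in range(max_iter):
            est = np.zeros(n_tx)
            for idx, cnt in zip(class_members, class_counts):
                w = alpha[idx]
                s = w.sum()
                if s > 0:
                    est[idx] += cnt * w / s
                else:
                    est[idx] += cnt / idx.size
            new_alpha = est / total
            if np.max(np.abs(new_alpha - alpha)) < tol:
                alpha = new_alpha
                converged = True
                break
            alpha = new_alpha
        if not converged:
            logger.warning("em_quantify: no convergence after %d iterations",
                           max_iter)
        est_counts = alpha * total
    else:
        est_counts = np.zeros(n_tx)

    rate = est_counts / eff
    denom = rate.sum()
    tpm = 1e6 * rate / denom if denom > 0 else np.zeros(n_tx)
    return pd.DataFrame({"est_counts": est_counts, "tpm": tpm,
                         "eff_length": eff},
                        index=pd.Index(tids, name="transcript_id"))


def class_loglik(classes: Counter, alpha: dict[str, float]) -> float:
    """Log-likelihood of equivalence-class counts under read shares alpha."""
    ll = 0.0
    for members, count in classes.items():
        s = sum(alpha.get(t, 0.0) for t in members)
        if s <= 0:
            return -np.inf
        ll += count * np.log(s)
    return ll


def quantify_sample(alignments: Iterable[AlignmentSet],
                    tx_lengths: dict[str, int],
                    frag_len_mean: float = 200.0) -> pd.DataFrame:
    return em_quantify(build_equiv_classes(alignments), tx_lengths,
                       frag_len_mean=frag_len_mean)


def aggregate_genes(tx_tables: dict[str, pd.DataFrame],
                    genes: Sequence[GeneModel],
                    detection_groups: Optional[dict[str, list[str]]] = None,
                    detection_tpm: float = 1.0) -> pd.DataFrame:
    """Sum transcript est_counts / tpm to gene level across samples.

    ``tx_tables`` maps sample_id -> em_quantify output.  ``detection_groups``
    maps a group name to its replicate sample ids; a gene is detected in a
    group when its mean TPM across the group's replicates is at least
    ``detection_tpm``.  Returns a long frame (gene_id, sample, est_counts,
    tpm) with detection flags in ``.attrs["detected"]``.
    """
    tx2gene = {}
    for g in genes:
        for t in g.transcripts:
            tx2gene[t.transcript_id] = g.gene_id
    rows = []
    for sample, tab in tx_tables.items():
        unknown = set(tab.index) - set(tx2gene)
        if unknown:
            raise ValueError(f"transcripts with unknown parent gene: {sorted(unknown)[:5]}")
        gg = tab.assign(gene_id=[tx2gene[t] for t in tab.index]) \
                .groupby("gene_id")[["est_counts", "tpm"]].sum()
        gg["sample"] = sample
        rows.append(gg.reset_index())
    long = pd.concat(rows, ignore_index=True)

    detected = {}
    if detection_groups:
        wide = long.pivot(index="gene_id", columns="sample", values="tpm").fillna(0.0)
        for group, samples in detection_groups.items():
            detected[group] = wide[samples].mean(axis=1) >= detection_tpm
    long.attrs["detected"] = detected
    return long


def counts_matrix(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long gene table into a gene x sample est_counts matrix."""
    return gene_table.pivot(index="gene_id", columns="sample",
                            values="est_counts").fillna(0.0)


def coverage_extent(alignments_by_sample: dict[str, list[AlignmentSet]],
                    genes: Sequence[GeneModel],
                    cell_samples: Sequence[str], ev_samples: Sequence[str],
                    seed: int = 0) -> pd.DataFrame:
    """Depth-matched read-coverage extent per gene and compartment.

    Cell replicate i is subsampled (uniformly, without replacement, seeded)
    to the mapped read count of EV replicate i.  For each gene the extent is
    (3'-most read end - 5'-most read start), clipped to the region — the CDS
    of the primary transcript for mRNA, the whole transcript for lncRNA —
    divided by the region length, then averaged across replicates.  Genes
    with no in-region reads in any replicate of a compartment are excluded.
    """
    if len(cell_samples) != len(ev_samples):
        raise ValueError("cell and EV sample lists must pair up")
    rng = np.random.default_rng(seed)

    region = {}
    region_kind = {}
    tx_of = {}
    for g in genes:
        t = g.primary_transcript
        tx_of[t.transcript_id] = g.gene_id
        if g.biotype_class == "mRNA" and t.cds is not None:
            region[g.gene_id] = t.cds
            region_kind[g.gene_id] = "CDS"
        else:
            region[g.gene_id] = (0, t.length)
            region_kind[g.gene_id] = "transcript"

    def mapped(sample):
        return [a for a in alignments_by_sample[sample] if a.mapped]

    per_rep: dict[str, list[dict[str, float]]] = {"cell": [], "ev": []}
    for cs, es in zip(cell_samples, ev_samples):
        ev_al = mapped(es)
        cell_al = mapped(cs)
        if len(cell_al) > len(ev_al):
            take = rng.choice(len(cell_al), size=len(ev_al), replace=False)
            cell_al = [cell_al[i] for i in take]
        for comp, als in (("cell", cell_al), ("ev", ev_al)):
            span: dict[str, tuple[int, int]] = {}
            for a in als:
                gid = tx_of.get(a.primary_transcript)
                if gid is None:
                    continue
                rs, re_ = region[gid]
                s = max(a.offset, rs)
                e = min(a.offset + a.aligned_length, re_)
                if s >= e:
                    continue
                if gid in span:
                    lo, hi = span[gid]
                    span[gid] = (min(lo, s), max(hi, e))
                else:
                    span[gid] = (s, e)
            fracs = {}
            for gid, (lo, hi) in span.items():
                rs, re_ = region[gid]
                fracs[gid] = (hi - lo) / (re_ - rs)
            per_rep[comp].append(fracs)

    rows = []
    for comp, reps in per_rep.items():
        seen = set().union(*[set(r) for r in reps]) if reps else set()
        for gid in sorted(seen):
            vals = [r[gid] for r in reps if gid in r]
            rows.append((gid, comp, float(np.mean(vals)), len(vals)))
    df = pd.DataFrame(rows, columns=["gene_id", "compartment", "fraction",
                                     "n_replicates"])
    df["region"] = [region_kind[g] for g in df["gene_id"]]
    return df
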