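"""Self-contained validation studies over synthetic data.

Each function builds its own inputs from the generative model (or from
constructed fixtures), runs the pipeline stage under study, and returns
the measured quantities.  The brute-force references used here (all-pairs
duplicate clustering, grid-search likelihood maximization, exact
hypergeometric enumeration) are deliberately independent reimplementations
of the quantities they check.

Study sizes (2000 genes, depth 1e6, 3 replicates per group, 10 seeds for
replicated claims) are the package's standard desk-scale conditions.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd

from .diffabund import (anticorrelation, inhibitor_contrast, packaging_delta,
                        test_differential)
from .features import compare_groups, estimate_half_life, extract_features
from .motifs import builtin_rbp_motifs, motif_enrichment, scan_pwm
from .preprocess import AlignmentSet, dedup_umi
from .quantify import class_loglik, em_quantify
from .synthetic import (SortingParams, build_transcriptome, effective_lengths,
                        sample_counts, simulate_steady_states)

DEPTH = 1_000_000
N_GENES = 2000
N_REPS = 3


# --------------------------------------------------------------- dedup oracle

def dedup_bruteforce(alignments: Sequence[AlignmentSet],
                     read_length: int = 75) -> set[str]:
    """O(n^2) all-pairs duplicate clustering; returns retained read ids.

    Within each (sample, transcript, UMI) group, repeatedly anchor the
    unassigned read with the smallest (offset, read_id), gather every
    unassigned read within the window of that anchor, and keep the anchor.
    """
    window = math.ceil(read_length / 2)
    groups: dict[tuple, list[AlignmentSet]] = {}
    kept: set[str] = set()
    for a in alignments:
        if not a.mapped:
            kept.add(a.read_id)
            continue
        groups.setdefault((a.sample_id, a.primary_transcript, a.umi), []).append(a)
    for members in groups.values():
        remaining = list(members)
        while remaining:
            anchor = min(remaining, key=lambda x: (x.offset, x.read_id))
            cluster = [x for x in remaining
                       if abs(x.offset - anchor.offset) <= window
                       and x.offset >= anchor.offset]
            kept.add(anchor.read_id)
            ids = {c.read_id for c in cluster}
            remaining = [x for x in remaining if x.read_id not in ids]
    return kept


def random_alignments(rng: np.random.Generator, n: int = 500,
                      n_tx: int = 5, n_umi: int = 8,
                      max_offset: int = 200) -> list[AlignmentSet]:
    umis = ["".join(rng.choice(list("ACGT"), 8)) for _ in range(n_umi)]
    out = []
    for i in range(n):
        tid = f"T{rng.integers(n_tx)}"
        out.append(AlignmentSet(
            read_id=f"r{i:04d}", umi=umis[rng.integers(n_umi)], sample_id="s1",
            compatible_transcripts=frozenset([tid]), primary_transcript=tid,
            offset=int(rng.integers(0, max_offset)), aligned_length=70))
    return out


def dedup_oracle_study(seed: int, n_seeds: int = 20,
                       n_reads: int = 500) -> float:
    """Fraction of random instances where greedy dedup matches the oracle."""
    agree = 0
    for k in range(n_seeds):
        rng = np.random.default_rng(seed * 1000 + k)
        als = random_alignments(rng, n=n_reads)
        kept, _ = dedup_umi(als, read_length=75)
        if {a.read_id for a in kept} == dedup_bruteforce(als):
            agree += 1
    return agree / n_seeds


# ------------------------------------------------------------------ EM oracle

def em_gridsearch(classes: Counter, tx_lengths: dict[str, int]) -> dict[str, float]:
    """Brute-force maximization of the class multinomial likelihood over
    the 3-transcript simplex of read shares (coarse grid + local refinement)."""
    tids = sorted(tx_lengths)
    assert len(tids) == 3

    def evaluate(g1, g2):
        a1, a2 = np.meshgrid(g1, g2, indexing="ij")
        a3 = 1.0 - a1 - a2
        valid = a3 >= -1e-12
        alpha = {tids[0]: a1, tids[1]: a2, tids[2]: np.maximum(a3, 0.0)}
        ll = np.zeros_like(a1)
        for members, count in classes.items():
            s = sum(alpha[t] for t in members)
            with np.errstate(divide="ignore"):
                ll += count * np.log(np.maximum(s, 1e-300))
        ll[~valid] = -np.inf
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        return float(a1[i, j]), float(a2[i, j])

    b1, b2 = evaluate(np.arange(0, 1.001, 1e-3), np.arange(0, 1.001, 1e-3))
    g1 = np.arange(max(0, b1 - 2e-3), min(1, b1 + 2e-3) + 1e-6, 1e-5)
    g2 = np.arange(max(0, b2 - 2e-3), min(1, b2 + 2e-3) + 1e-6, 1e-5)
    b1, b2 = evaluate(g1, g2)
    return {tids[0]: b1, tids[1]: b2, tids[2]: max(1.0 - b1 - b2, 0.0)}


def em_oracle_study(seed: int) -> dict:
    """EM vs grid search on a mixed 3-transcript toy; TPM sum; monotonicity."""
    rng = np.random.default_rng(seed)
    tx_lengths = {"T1": 1000, "T2": 1500, "T3": 800}
    classes = Counter({
        frozenset(["T1"]): 40,
        frozenset(["T2"]): 25,
        frozenset(["T1", "T2"]): 60,
        frozenset(["T2", "T3"]): 30,
        frozenset(["T1", "T2", "T3"]): 45,
    })
    res = em_quantify(classes, tx_lengths, frag_len_mean=200.0, tol=1e-12)
    total = res["est_counts"].sum()
    alpha_em = (res["est_counts"] / total).to_dict()
    alpha_grid = em_gridsearch(classes, tx_lengths)
    max_rel_err = max(
        abs(alpha_em[t] - alpha_grid[t]) / max(alpha_grid[t], 1e-9)
        for t in tx_lengths)

    # monotone likelihood over random instances
    n_viol = 0
    for _ in range(100):
        cls = Counter()
        for _ in range(rng.integers(2, 6)):
            members = frozenset(
                rng.choice(["T1", "T2", "T3"], rng.integers(1, 4), replace=False))
            cls[members] += int(rng.integers(1, 50))
        prev = -np.inf
        alpha = {t: 1 / 3 for t in tx_lengths}
        for _ in range(25):
            ll = class_loglik(cls, alpha)
            if ll < prev - 1e-9:
                n_viol += 1
                break
            prev = ll
            est = {t: 0.0 for t in tx_lengths}
            for members, count in cls.items():
                s = sum(alpha[t] for t in members)
                for t in members:
                    est[t] += count * alpha[t] / s
            tot = sum(est.values())
            alpha = {t: v / tot for t, v in est.items()}
    return {"max_rel_err": max_rel_err,
            "tpm_sum": float(res["tpm"].sum()),
            "monotonicity_violations": n_viol}


# ------------------------------------------------------------------ DE studies

def _tpm_from_counts(counts: pd.DataFrame, efflen: pd.Series) -> pd.DataFrame:
    rate = counts.div(efflen.reindex(counts.index), axis=0)
    return 1e6 * rate / rate.sum(axis=0)


def _ev_cell_contrast(truth: pd.DataFrame, efflen: pd.Series, seed: int,
                      depth: int = DEPTH) -> pd.DataFrame:
    cc = sample_counts(truth, "cell", depth, N_REPS, seed=seed,
                       length_weight=efflen)
    ce = sample_counts(truth, "ev", depth, N_REPS, seed=seed + 1,
                       length_weight=efflen)
    counts = pd.concat([cc, ce], axis=1)
    tpm = _tpm_from_counts(counts, efflen)
    detected = tpm[list(cc.columns)].mean(axis=1) >= 1.0
    return test_differential(counts, list(cc.columns), list(ce.columns),
                             detected=detected)


def _condition_contrast(truth_a: pd.DataFrame, truth_b: pd.DataFrame,
                        efflen: pd.Series, seed: int,
                        compartment: str = "cell",
                        depth: int = DEPTH) -> pd.DataFrame:
    ca = sample_counts(truth_a, compartment, depth, N_REPS, seed=seed,
                       length_weight=efflen)
    cb = sample_counts(truth_b, compartment, depth, N_REPS, seed=seed + 1,
                       length_weight=efflen).rename(columns=lambda c: c + "_b")
    counts = pd.concat([ca, cb], axis=1)
    tpm = _tpm_from_counts(counts, efflen)
    detected = tpm[list(ca.columns)].mean(axis=1) >= 1.0
    return test_differential(counts, list(ca.columns), list(cb.columns),
                             detected=detected)


def de_null_study(seed: int, n_genes: int = N_GENES,
                  depth: int = DEPTH) -> float:
    """Fraction of padj < 0.1 calls when the two groups share one truth."""
    p = SortingParams()
    tx = build_transcriptome(n_genes, p, seed=seed)
    truth = simulate_steady_states(tx, p, seed=seed + 1)["basal"]
    efflen = effective_lengths(tx, p.frag_len_mean)
    res = _condition_contrast(truth, truth, efflen, seed + 2)
    return float((res["padj"] < 0.1).mean())


def de_spike_study(seed: int, n_genes: int = N_GENES,
                   depth: int = DEPTH) -> dict:
    """Sensitivity and FDP for planted |log2 packaging| >= 1.5 in 10% of genes."""
    p = SortingParams(spike_fraction=0.1)
    tx = build_transcriptome(n_genes, p, seed=seed)
    truth = simulate_steady_states(tx, p, seed=seed + 1)["basal"]
    efflen = effective_lengths(tx, p.frag_len_mean)
    res = _ev_cell_contrast(truth, efflen, seed + 2, depth=depth)
    labels = truth.set_index("gene_id")["true_label"].reindex(res.index)
    called = res["padj"] < 0.1
    is_true = labels.isin(["enriched", "depleted"])
    sensitivity = float((called & is_true).sum() / is_true.sum())
    fdp = float((called & ~is_true).sum() / max(1, called.sum()))
    return {"sensitivity": sensitivity, "fdp": fdp,
            "n_true": int(is_true.sum()), "n_called": int(called.sum())}


def anticorrelation_study(coupling: float, seed: int,
                          n_genes: int = N_GENES) -> dict:
    """One seed of the packaging-vs-cell-change anticorrelation recovery."""
    p = SortingParams(coupling=coupling)
    tx = build_transcriptome(n_genes, p, seed=seed)
    truth = simulate_steady_states(tx, p, seed=seed + 1)
    efflen = effective_lengths(tx, p.frag_len_mean)
    diff_basal = _ev_cell_contrast(truth["basal"], efflen, seed + 2)
    diff_treated = _ev_cell_contrast(truth["treated"], efflen, seed + 4)
    cell_changes = _condition_contrast(truth["basal"], truth["treated"],
                                       efflen, seed + 6)
    deltas = packaging_delta(diff_treated, diff_basal)
    rep = anticorrelation(deltas, cell_changes)
    return {"r": rep.result.statistic, "p": rep.result.p_value,
            "slope": rep.slope, "n": rep.n}


def inhibitor_study(strength: float, seed: int,
                    n_genes: int = N_GENES) -> dict:
    """One seed of the export-inhibitor cellular-accumulation contrast."""
    p = SortingParams(inhibitor_strength=strength)
    tx = build_transcriptome(n_genes, p, seed=seed)
    truth = simulate_steady_states(tx, p, seed=seed + 1)
    efflen = effective_lengths(tx, p.frag_len_mean)
    diff_basal = _ev_cell_contrast(truth["basal"], efflen, seed + 2)
    cell_changes = _condition_contrast(truth["basal"], truth["inhibitor"],
                                       efflen, seed + 4)
    enriched = diff_basal.index[diff_basal["status"] == "enriched"]
    background = diff_basal.index[(diff_basal["status"] != "enriched")
                                  & (diff_basal["status"] != "not_tested")]
    res = inhibitor_contrast(cell_changes, enriched, background)
    return {"t": res.statistic, "p": res.p_value,
            "mean_difference": res.extra["mean_difference"],
            "n_enriched": res.extra["n_enriched"]}


def feature_recovery_study(seed: int, n_genes: int = N_GENES) -> dict:
    """One seed of the planted feature-effect recovery.

    Uses the default sorting coefficients (shorter, exon-dense, GC-rich and
    motif-bearing transcripts exported more) and checks each direction in
    the enriched-vs-depleted comparison, plus GGAG-motif enrichment against
    the unchanged background.
    """
    p = SortingParams()
    tx = build_transcriptome(n_genes, p, seed=seed)
    truth = simulate_steady_states(tx, p, seed=seed + 1)
    efflen = effective_lengths(tx, p.frag_len_mean)
    diff = _ev_cell_contrast(truth["basal"], efflen, seed + 2)
    enriched = list(diff.index[diff["status"] == "enriched"])
    depleted = list(diff.index[diff["status"] == "depleted"])
    feats = extract_features(tx.genes)
    rep = compare_groups(feats, enriched, depleted,
                         ["length", "exons_per_kb", "gc_pct"])
    seqs = {g.gene_id: g.primary_transcript.sequence for g in tx.genes}
    hits = scan_pwm(seqs, builtin_rbp_motifs())
    unchanged = list(diff.index[diff["padj"] >= 0.5])
    enr_tab = motif_enrichment(hits, enriched, unchanged)
    return {
        "shorter": bool(rep.loc["length", "median_enriched"]
                        < rep.loc["length", "median_depleted"]),
        "more_exon_dense": bool(rep.loc["exons_per_kb", "median_enriched"]
                                > rep.loc["exons_per_kb", "median_depleted"]),
        "higher_gc": bool(rep.loc["gc_pct", "median_enriched"]
                          > rep.loc["gc_pct", "median_depleted"]),
        "motif_enriched": bool(enr_tab.loc["SYN_GGAG01", "enriched"]
                               or enr_tab.loc["SYN_GGAG02", "enriched"]),
        "n_enriched": len(enriched), "n_depleted": len(depleted),
    }


# ------------------------------------------------------------------ half-life

def halflife_study(seed: int, n_genes: int = 400,
                   depth: int = 3_000_000) -> dict:
    """Noiseless exactness and noisy recovery of the half-life estimator.

    The noisy arm simulates a transcription-shutoff timecourse (0, 1, 2, 4,
    6, 8 h; 3 replicate libraries per timepoint, counts gamma-Poisson at
    ``depth``) and reports the median absolute relative error over genes
    with TPM >= 10 at t = 0.
    """
    rng = np.random.default_rng(seed)
    times = np.array([0.0, 1.0, 2.0, 4.0, 6.0, 8.0])

    # noiseless geometric decay
    t_half = rng.uniform(1.0, 8.0, 50)
    decay = np.exp(-np.outer(np.log(2) / t_half, times))
    noiseless = pd.DataFrame(decay, index=[f"g{i}" for i in range(50)],
                             columns=[f"t{t}" for t in times])
    est0 = estimate_half_life(noiseless, times)
    max_err_noiseless = float(np.max(np.abs(est0.to_numpy() - t_half) / t_half))

    # NB-noised counts
    t_half = rng.uniform(1.0, 8.0, n_genes)
    base = rng.lognormal(np.log(200.0), 1.5, n_genes)
    share = base / base.sum()
    mean_tc = share[:, None] * np.exp(-np.outer(np.log(2) / t_half, times))
    est_tc = np.zeros_like(mean_tc)
    for j in range(times.size):
        mu = depth * mean_tc[:, j] / mean_tc[:, 0].sum()
        reps = np.stack([
            rng.poisson(rng.gamma(1 / 0.05, mu * 0.05)) for _ in range(3)
        ])
        est_tc[:, j] = reps.mean(axis=0)
    tc = pd.DataFrame(est_tc, index=[f"g{i}" for i in range(n_genes)],
                      columns=[f"t{t}" for t in times])
    est = estimate_half_life(tc, times)
    tpm0 = 1e6 * est_tc[:, 0] / est_tc[:, 0].sum()
    ok = tpm0 >= 10.0
    rel_err = np.abs(est.to_numpy()[ok] - t_half[ok]) / t_half[ok]
    return {"max_err_noiseless": max_err_noiseless,
            "median_rel_err_noisy": float(np.nanmedian(rel_err)),
            "n_eval": int(ok.sum())}


# ------------------------------------------------------------------- coverage

def coverage_study(seed: int) -> dict:
    """Coverage-extent checks on constructed alignments.

    End-to-end tiling of every transcript must give fraction exactly 1.0;
    the cell compartment is additionally depth-matched down to the EV read
    count by seeded subsampling.
    """
    from .quantify import coverage_extent

    p = SortingParams()
    tx = build_transcriptome(40, p, seed=seed)
    read_len = 70
    by_sample: dict[str, list[AlignmentSet]] = {}
    for rep in (1, 2, 3):
        for comp, step in (("cell", 10), ("ev", 25)):
            sample = f"basal_{comp}_rep{rep}"
            als = []
            for g in tx.genes:
                t = g.primary_transcript
                last = max(0, t.length - read_len)
                offsets = sorted(set(list(range(0, last + 1, step)) + [last]))
                for i, off in enumerate(offsets):
                    als.append(AlignmentSet(
                        read_id=f"{sample}:{g.gene_id}:{i}", umi="ACGTACGT",
                        sample_id=sample,
                        compatible_transcripts=frozenset([t.transcript_id]),
                        primary_transcript=t.transcript_id,
                        offset=off, aligned_length=read_len))
            by_sample[sample] = als
    cells = [f"basal_cell_rep{r}" for r in (1, 2, 3)]
    evs = [f"basal_ev_rep{r}" for r in (1, 2, 3)]
    cov = coverage_extent(by_sample, tx.genes, cells, evs, seed=seed)
    ev_cov = cov[cov["compartment"] == "ev"]
    return {
        "min_fraction_ev_tiled": float(ev_cov["fraction"].min()),
        "n_genes": int(ev_cov["gene_id"].nunique()),
    }
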