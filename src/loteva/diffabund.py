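"""Differential abundance, packaging change, and the downstream contrasts.

A transparent negative-binomial Wald test: median-of-ratios size factors,
gene-wise method-of-moments dispersion (floored at 1e-8, capped at 10),
log2 fold differences of normalized group means with pseudo-count 0.5, and
a moment-based standard error (delta method on var = mu + alpha mu^2).
No dispersion shrinkage, no LFC shrinkage, no independent filtering.

Significance threshold is padj < 0.1 throughout; genes must pass the
detection rule (mean TPM >= 1 in at least one group) to be tested.

The packaging change for a gene is
    delta = log2fd(EV vs cell, experimental) - log2fd(EV vs cell, basal)
and the anticorrelation, distribution-shift and inhibitor analyses act on
those quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .models import StatResult
from .stats import bh_adjust, pearson, welch_t

logger = logging.getLogger("loteva")

PADJ_THRESHOLD = 0.1
DISPERSION_FLOOR = 1e-8
DISPERSION_CAP = 10.0
PSEUDOCOUNT = 0.5


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Uses only genes with positive counts in every sample (the geometric
    mean reference is undefined otherwise).
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in all samples")
    logmat = np.log(mat[positive])
    logref = logmat.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logmat - logref, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _moment_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Per-gene NB dispersion alpha from within-group moments of normalized counts.

    With few replicates the gene-wise moment estimate is noisy and often
    underestimates the true dispersion by chance, which would make the Wald
    test anticonservative; each gene's estimate is therefore floored at the
    pooled ratio-of-sums moment estimate over all genes (a global floor,
    not a fitted trend).
    """
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for idx in groups:
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += v - m
        den += m ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    alpha = np.clip(alpha, DISPERSION_FLOOR, DISPERSION_CAP)
    if alpha.size > 1 and den.sum() > 0:
        pooled = np.clip(num.sum() / den.sum(), DISPERSION_FLOOR, DISPERSION_CAP)
        alpha = np.maximum(alpha, pooled)
    return alpha


def test_differential(counts: pd.DataFrame,
                      group1: Sequence[str], group2: Sequence[str],
                      detected: Optional[pd.Series] = None,
                      size_factors: Optional[pd.Series] = None,
                      padj_threshold: float = PADJ_THRESHOLD) -> pd.DataFrame:
    """NB Wald test of group2 vs group1 (log2fd > 0 means higher in group2).

    ``detected`` flags the testing universe (genes passing the detection
    rule); untested genes are reported with status ``not_tested``.  Returns
    a frame indexed by gene_id with log2fd, se, p, padj, base_mean,
    dispersion and status in {enriched, depleted, unchanged, not_tested}.
    """
    g1 = list(group1)
    g2 = list(group2)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need >= 2 replicates per group")
    all_samples = g1 + g2
    sub = counts[all_samples]
    if size_factors is None:
        size_factors = estimate_size_factors(sub)
    sf = size_factors[all_samples].to_numpy()
    norm = sub.to_numpy(dtype=float) / sf
    i1 = np.arange(len(g1))
    i2 = np.arange(len(g1), len(all_samples))

    m1 = norm[:, i1].mean(axis=1)
    m2 = norm[:, i2].mean(axis=1)
    log2fd = np.log2((m2 + PSEUDOCOUNT) / (m1 + PSEUDOCOUNT))
    alpha = _moment_dispersion(norm, [i1, i2])

    # delta-method variance of log2(mean + pseudocount) under NB moments:
    # Var(K_ij / s_j) = mu_i / s_j + alpha_i mu_i^2
    def group_var(mean, idx):
        mu = np.maximum(mean, PSEUDOCOUNT)
        per_rep = mu[:, None] / sf[idx][None, :] + alpha[:, None] * mu[:, None] ** 2
        var_mean = per_rep.sum(axis=1) / len(idx) ** 2
        return var_mean / ((mu + PSEUDOCOUNT) ** 2 * np.log(2) ** 2)

    se = np.sqrt(group_var(m1, i1) + group_var(m2, i2))
    wald = log2fd / se
    p = 2.0 * scipy.stats.norm.sf(np.abs(wald))

    res = pd.DataFrame({
        "log2fd": log2fd, "se": se, "p": p,
        "base_mean": norm.mean(axis=1), "dispersion": alpha,
    }, index=counts.index)

    if detected is None:
        tested = pd.Series(True, index=counts.index)
    else:
        tested = detected.reindex(counts.index).fillna(False).astype(bool)
    res["padj"] = np.nan
    res.loc[tested, "padj"] = bh_adjust(res.loc[tested, "p"].to_numpy())

    status = np.full(len(res), "unchanged", dtype=object)
    status[~tested.to_numpy()] = "not_tested"
    sig = tested.to_numpy() & (res["padj"].to_numpy() < padj_threshold)
    status[sig & (log2fd > 0)] = "enriched"
    status[sig & (log2fd < 0)] = "depleted"
    res["status"] = status
    res.index.name = "gene_id"
    return res


def packaging_delta(diff_exp: pd.DataFrame,
                    diff_basal: pd.DataFrame) -> pd.Series:
    """Change in EV packaging: log2fd(exp EV vs cell) - log2fd(basal EV vs cell)."""
    shared = diff_exp.index.intersection(diff_basal.index)
    if shared.empty:
        raise ValueError("no shared genes between the two contrasts")
    delta = diff_exp.loc[shared, "log2fd"] - diff_basal.loc[shared, "log2fd"]
    delta.name = "delta_packaging"
    return delta


@dataclass
class CorrelationReport:
    result: StatResult
    slope: float
    n: int
    table: pd.DataFrame


def anticorrelation(deltas: pd.Series, cell_changes: pd.DataFrame,
                    biotypes: Optional[pd.Series] = None,
                    scope: str = "both") -> CorrelationReport:
    """Correlate packaging change with cellular log2 fold change.

    ``scope`` restricts to one biotype class ('mRNA', 'lncRNA') or 'both'.
    Returns Pearson r/p, the least-squares slope of delta on cell log2fd,
    and the paired table.
    """
    shared = deltas.index.intersection(cell_changes.index)
    tab = pd.DataFrame({
        "delta_packaging": deltas.loc[shared],
        "cell_log2fd": cell_changes.loc[shared, "log2fd"],
    })
    if biotypes is not None and scope != "both":
        keep = biotypes.reindex(tab.index) == scope
        tab = tab[keep.fillna(False)]
    if len(tab) < 3:
        raise ValueError("fewer than 3 shared genes")
    res = pearson(tab["cell_log2fd"], tab["delta_packaging"])
    slope = float(np.polyfit(tab["cell_log2fd"], tab["delta_packaging"], 1)[0])
    return CorrelationReport(result=res, slope=slope, n=len(tab), table=tab)


def distribution_shift(diff_basal: pd.DataFrame, diff_treated: pd.DataFrame,
                       up_genes: Sequence[str], down_genes: Sequence[str],
                       ) -> dict[str, dict]:
    """Shift of EV-vs-cell log2fd distributions between conditions.

    For genes increased (``up_genes``) or decreased (``down_genes``) in
    cells by the treatment, compare the EV-vs-cell log2fd distribution in
    the treated condition against basal (Welch test + medians).  Under
    positive coupling the up set shifts negative and the down set positive.
    """
    out = {}
    for label, genes in (("up", up_genes), ("down", down_genes)):
        genes = [g for g in genes
                 if g in diff_basal.index and g in diff_treated.index]
        if len(genes) < 2:
            logger.warning("distribution_shift: %s set too small, skipped", label)
            continue
        basal = diff_basal.loc[genes, "log2fd"].to_numpy()
        treated = diff_treated.loc[genes, "log2fd"].to_numpy()
        if np.array_equal(basal, treated):
            res = StatResult(statistic=0.0, p_value=1.0)
        else:
            res = welch_t(treated, basal)
        out[label] = {
            "result": res,
            "median_basal": float(np.median(basal)),
            "median_treated": float(np.median(treated)),
            "shift": float(np.median(treated) - np.median(basal)),
            "n": len(genes),
        }
    return out


def inhibitor_contrast(cell_changes: pd.DataFrame,
                       ev_enriched: Sequence[str],
                       background: Sequence[str]) -> StatResult:
    """Welch test: cellular log2fd of EV-enriched genes vs background genes.

    ``cell_changes`` is the inhibitor-vs-control contrast in cells;
    a positive mean difference means export-blocked transcripts accumulate.
    """
    enr = cell_changes.loc[cell_changes.index.intersection(ev_enriched), "log2fd"]
    bg = cell_changes.loc[cell_changes.index.intersection(background), "log2fd"]
    if len(enr) < 2 or len(bg) < 2:
        raise ValueError("each gene set needs >= 2 genes with results")
    res = welch_t(enr.to_numpy(), bg.to_numpy())
    res.extra.update({
        "mean_enriched": float(enr.mean()),
        "mean_background": float(bg.mean()),
        "mean_difference": float(enr.mean() - bg.mean()),
        "n_enriched": int(len(enr)),
        "n_background": int(len(bg)),
    })
    return res
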