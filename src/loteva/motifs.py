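"""PWM motif scanning with an exact DP null distribution, and Fisher-based
motif enrichment between gene sets.

Scanning scores each window with the log2 likelihood ratio of the position
probability matrix against the background; the hit threshold for a motif is
the smallest score whose exact null p-value (computed by dynamic programming
over the discretized score distribution under the background) is at or
below ``p_thresh``.  Scanning is sense-strand only, since the substrate is
single-stranded RNA.  Matrices over the RNA alphabet are mapped U -> T at
load time.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .stats import bh_adjust, fisher_exact

logger = logging.getLogger("loteva")

_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_EPS = 1e-9


@dataclass
class PWM:
    """A position probability matrix with its background distribution."""

    motif_id: str
    matrix: np.ndarray                       # (width, 4) in A, C, G, T order
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must be (width, 4)")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        return np.log2((self.matrix + _EPS) / (self.background + _EPS))


def score_null_distribution(pwm: PWM, scale: int = 1000
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of window scores under the background model.

    Scores are discretized to 1/scale resolution; returns (scores, probs)
    sorted ascending.
    """
    lom = np.rint(pwm.log_odds() * scale).astype(np.int64)
    dist: dict[int, float] = {0: 1.0}
    for j in range(pwm.width):
        new: dict[int, float] = defaultdict(float)
        for s, pr in dist.items():
            for b in range(4):
                new[s + lom[j, b]] += pr * pwm.background[b]
        dist = dict(new)
    scores = np.array(sorted(dist))
    probs = np.array([dist[s] for s in scores])
    return scores / scale, probs


def score_threshold(pwm: PWM, p_thresh: float = 1e-4,
                    scale: int = 1000) -> float:
    """Smallest score whose exact null tail probability is <= p_thresh.

    For a narrow motif no score may reach the requested p (a w-mer's best
    match has null probability >= 4^-w); the threshold then clamps to the
    maximum achievable score, so an exact consensus match still registers.
    """
    scores, probs = score_null_distribution(pwm, scale=scale)
    tail = np.cumsum(probs[::-1])[::-1]
    ok = tail <= p_thresh
    if not ok.any():
        return float(scores[-1])
    return float(scores[np.argmax(ok)])


def scan_sequence(pwm: PWM, seq: str,
                  threshold: Optional[float] = None) -> tuple[bool, float]:
    """Best window log-odds score on the sense strand, and whether it passes.

    A sequence shorter than the motif yields (False, -inf).
    """
    if threshold is None:
        threshold = score_threshold(pwm)
    seq = seq.upper().replace("U", "T")
    w = pwm.width
    n = len(seq) - w + 1
    if n < 1:
        return False, float("-inf")
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    idx = np.full(codes.size, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        idx[codes == ord(b)] = i
    # quantize to the same grid as the null distribution so threshold
    # comparisons are exact
    lom = np.rint(pwm.log_odds() * 1000) / 1000
    min_pen = float(lom.min() - 10.0)  # non-ACGT letters can never help
    scores = np.zeros(n)
    for j in range(w):
        col = idx[j:j + n]
        contrib = np.where(col >= 0, lom[j, np.clip(col, 0, 3)], min_pen)
        scores += contrib
    best = float(scores.max())
    return best >= threshold - 1e-9, best


def scan_pwm(sequences: dict[str, str], pwms: Sequence[PWM],
             p_thresh: float = 1e-4) -> pd.DataFrame:
    """Hit flags per gene x motif at the exact-null threshold.

    Best scores are stored in ``.attrs['best_scores']``.
    """
    thresholds = {m.motif_id: score_threshold(m, p_thresh) for m in pwms}
    hits = {}
    scores = {}
    for m in pwms:
        col_h, col_s = {}, {}
        for gid, seq in sequences.items():
            h, s = scan_sequence(m, seq, threshold=thresholds[m.motif_id])
            col_h[gid], col_s[gid] = h, s
        hits[m.motif_id] = col_h
        scores[m.motif_id] = col_s
    df = pd.DataFrame(hits).sort_index()
    df.attrs["best_scores"] = pd.DataFrame(scores).sort_index()
    df.attrs["thresholds"] = thresholds
    return df


def motif_enrichment(hits: pd.DataFrame, foreground: Iterable[str],
                     background: Iterable[str],
                     padj_threshold: float = 0.1) -> pd.DataFrame:
    """One-sided Fisher enrichment of motif hits in foreground genes.

    ``foreground`` (e.g. EV-enriched) and ``background`` (e.g. unchanged)
    must be disjoint.  Returns one row per motif with the 2x2 table counts,
    odds ratio, p, BH-adjusted p and the enrichment call (padj < 0.1).
    """
    fg = [g for g in foreground if g in hits.index]
    bg = [g for g in background if g in hits.index]
    if set(fg) & set(bg):
        raise ValueError("foreground and background must be disjoint")
    if not fg or not bg:
        raise ValueError("both gene sets must be nonempty")
    rows = []
    for motif in hits.columns:
        h_f = int(hits.loc[fg, motif].sum())
        h_b = int(hits.loc[bg, motif].sum())
        table = [[h_f, len(fg) - h_f], [h_b, len(bg) - h_b]]
        res = fisher_exact(table, alternative="greater")
        rows.append({
            "motif_id": motif, "hits_fg": h_f, "n_fg": len(fg),
            "hits_bg": h_b, "n_bg": len(bg),
            "odds_ratio": res.statistic, "p": res.p_value,
        })
    df = pd.DataFrame(rows).set_index("motif_id")
    df["padj"] = bh_adjust(df["p"].to_numpy())
    df["enriched"] = df["padj"] < padj_threshold
    return df


# ----------------------------------------------------------------- MEME I/O

def write_meme(pwms: Sequence[PWM], path) -> None:
    """Write position probability matrices in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write("A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*bg))
        for m in pwms:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {m.width} "
                     f"nsites= 100000 E= 0\n")
            for row in m.matrix:
                fh.write(" {:8.6f} {:8.6f} {:8.6f} {:8.6f}\n".format(*row))
            fh.write("\n")


def load_meme(path) -> list[PWM]:
    """Load MEME minimal-format motifs; RNA (ACGU) matrices map U -> T."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
        out = []
        for rec in records:
            letters = sorted(rec.counts.keys())
            order = ["A", "C", "G", "T" if "T" in letters else "U"]
            mat = np.array([[rec.counts[b][i] for b in order]
                            for i in range(rec.length)], dtype=float)
            mat = mat / mat.sum(axis=1, keepdims=True)
            bg = rec.background or {b: 0.25 for b in order}
            background = np.array([bg[b] for b in order], dtype=float)
            out.append(PWM(motif_id=rec.name, matrix=mat,
                           background=background / background.sum()))
    return out


def _consensus_pwm(motif_id: str, consensus: str, strength: float = 0.85) -> PWM:
    consensus = consensus.upper().replace("U", "T")
    mat = np.full((len(consensus), 4), (1.0 - strength) / 3.0)
    for j, b in enumerate(consensus):
        mat[j, _BASE_INDEX[b]] = strength
    return PWM(motif_id=motif_id, matrix=mat)


def builtin_rbp_motifs() -> list[PWM]:
    """Small synthetic RBP motif set for simulations and tests.

    SYN_GGAG01/02 carry the GGAG core planted by the synthetic generator,
    SYN_UAG01 a UAG-containing motif, SYN_CTRL01 an unrelated control.
    These are synthetic stand-ins, not curated RBP matrices.
    """
    return [
        _consensus_pwm("SYN_GGAG01", "AGGAGGC", 0.9),
        _consensus_pwm("SYN_GGAG02", "TAGGAGG", 0.8),
        _consensus_pwm("SYN_UAG01", "TTAGTAG", 0.85),
        _consensus_pwm("SYN_CTRL01", "CATCGAT", 0.85),
    ]
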