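"""Synthetic transcriptome and read generator with planted sorting structure.

The generative model treats the cellular abundance of each transcript as a
first-order homeostasis between transcription (rate sigma, molecules/h),
decay (rate delta, /h) and export into extracellular vesicles (rate
epsilon, /h):

    dc/dt = sigma - (delta + epsilon) * c   =>   c* = sigma / (delta + epsilon)

EV output flux is epsilon * c*, measured compositionally (sequencing sees
proportions).  The export rate is feature-driven on a log2 scale:

    log2(epsilon/delta) = beta0 + beta . z(features) + noise

so transcript length, exon density, GC content, planted motif presence and
half-life steer packaging, and the planted effects are recoverable by the
analysis pipeline.  A treated condition shifts transcription of a gene
subset and couples packaging to that shift with coefficient ``coupling``
(lambda): d log2 packaging = -lambda * d log2 sigma + Gaussian noise.  An
inhibitor condition scales epsilon by (1 - inhibitor_strength), raising
cellular abundance most for strongly exported genes.

Reads carry 8-nt UMIs, geometric PCR duplication, substitution errors, a
5-nt adapter prefix, and declared fractions of rRNA and low-complexity
contamination, mirroring a low-input UMI library at the contract level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .io import ensure_dir, revcomp, write_bed, write_fasta, write_gtf
from .models import GeneModel, Interval, Read, TranscriptModel

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SortingParams:
    """All tunable parameters of the generative model (see module docstring)."""

    # transcriptome shape
    lnc_fraction: float = 0.2
    median_length: float = 1400.0
    length_sigma: float = 0.6
    min_length: int = 300
    max_length: int = 8000
    exons_per_kb_median: float = 1.5
    exons_per_kb_sigma: float = 0.5
    gc_mean: float = 0.47
    gc_sd: float = 0.05
    utr5_frac: float = 0.10
    utr3_frac: float = 0.30
    motif_prob: float = 0.3
    motif_seq: str = "TAGGAGGC"
    n_rrna: int = 3

    # kinetics (per-gene rates drawn lognormally)
    sigma_log_mean: float = math.log(50.0)
    sigma_sigma: float = 1.0
    halflife_log_mean: float = math.log(4.0)   # hours
    halflife_sigma: float = 0.6

    # sorting coefficients, log2 scale on z-scored features
    beta0: float = -3.5
    beta_len: float = -0.5
    beta_exon: float = 0.3
    beta_gc: float = 0.2
    beta_motif: float = 1.0
    beta_halflife: float = 0.3
    basal_noise_sd: float = 0.5

    # condition structure
    coupling: float = 0.3                      # lambda >= 0
    packaging_noise_sd: float = 0.25
    treated_fraction: float = 0.3
    treated_shift_min: float = 0.5
    treated_shift_max: float = 2.0
    inhibitor_strength: float = 0.8            # i in [0, 1]
    inhibitor_fraction: float = 1.0

    # spike mode: plant a clean enriched/depleted structure, features off
    spike_fraction: float = 0.0
    spike_log2_min: float = 1.5
    spike_log2_max: float = 2.5

    # library
    n_replicates: int = 3
    pcr_dup_mean: float = 2.0                  # d >= 1
    error_rate: float = 0.002
    rrna_read_fraction: float = 0.05
    lowcomplexity_read_fraction: float = 0.02
    frag_len_mean: float = 200.0
    frag_len_sd: float = 40.0
    umi_length: int = 8
    read_length: int = 75
    adapter: str = "TACGC"
    seed: int = 0

    def __post_init__(self):
        if self.coupling < 0:
            raise ValueError("coupling (lambda) must be >= 0")
        if not 0.0 <= self.inhibitor_strength <= 1.0:
            raise ValueError("inhibitor_strength must lie in [0, 1]")
        if self.pcr_dup_mean < 1.0:
            raise ValueError("pcr_dup_mean must be >= 1")


@dataclass
class Transcriptome:
    genes: list[GeneModel]
    genome: dict[str, str]
    rrna: dict[str, str]
    clip_peaks: list[Interval]
    features: pd.DataFrame

    def write(self, outdir) -> None:
        ensure_dir(outdir)
        import os
        write_gtf(self.genes, os.path.join(outdir, "genes.gtf"))
        write_fasta(self.genome, os.path.join(outdir, "genome.fa"))
        write_fasta(self.rrna, os.path.join(outdir, "rrna.fa"))
        write_bed(self.clip_peaks, os.path.join(outdir, "clip_peaks.bed"))
        self.features.to_csv(os.path.join(outdir, "features_truth.tsv"),
                             sep="\t", index=False)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode()


def _split_lengths(rng: np.random.Generator, total: int, parts: int,
                   min_part: int = 30) -> list[int]:
    """Split ``total`` into ``parts`` pieces of at least ``min_part``."""
    parts = max(1, min(parts, total // min_part))
    if parts == 1:
        return [total]
    w = rng.dirichlet(np.full(parts, 2.0))
    lens = np.maximum(min_part, np.floor(w * total).astype(int))
    # fix rounding so the pieces sum exactly
    lens[-1] = total - lens[:-1].sum()
    while lens[-1] < min_part:
        j = int(np.argmax(lens[:-1]))
        move = min(lens[j] - min_part, min_part - lens[-1])
        if move <= 0:
            break
        lens[j] -= move
        lens[-1] += move
    return [int(x) for x in lens]


def build_transcriptome(n_genes: int, params: Optional[SortingParams] = None,
                        seed: int = 0) -> Transcriptome:
    """Generate an annotated single-chromosome transcriptome.

    One transcript per gene.  mRNA genes carry a 5'UTR/CDS/3'UTR partition;
    a configurable fraction of sequences carries planted motif instances
    (CLIP peaks are emitted at the first planted instance of each);
    antisense lncRNAs are embedded in long introns of protein-coding hosts
    on the opposite strand so span-overlap pairing is exercised.  A small
    separate rRNA set supports the contamination screen.  Deterministic for
    a fixed seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    p = params or SortingParams()
    rng = np.random.default_rng(seed)
    chrom = "chr1"
    motif = p.motif_seq.upper().replace("U", "T")

    n_lnc = int(round(n_genes * p.lnc_fraction))
    lnc_sub = rng.choice(["lincRNA", "antisense_RNA", "processed_pseudogene"],
                         size=n_lnc, p=[0.55, 0.35, 0.10])
    biotypes = ["protein_coding"] * (n_genes - n_lnc) + list(lnc_sub)
    rng.shuffle(biotypes)

    antisense_specs = [i for i, b in enumerate(biotypes) if b == "antisense_RNA"]
    linear_idx = [i for i, b in enumerate(biotypes) if b != "antisense_RNA"]

    segments: list[str] = []
    cursor = 0
    genes: dict[int, GeneModel] = {}
    feat_rows = []
    motif_tx_pos: dict[str, list[int]] = {}
    host_introns: list[tuple[str, int, int, str]] = []  # (gene_id, start, end, strand)

    def emit(seq: str) -> tuple[int, int]:
        nonlocal cursor
        segments.append(seq)
        s = cursor
        cursor += len(seq)
        return s, cursor

    for i in linear_idx:
        bt = biotypes[i]
        gid = f"G{i:05d}"
        L = int(np.clip(rng.lognormal(math.log(p.median_length), p.length_sigma),
                        p.min_length, p.max_length))
        epk = rng.lognormal(math.log(p.exons_per_kb_median), p.exons_per_kb_sigma)
        n_exons = max(1, int(round(epk * L / 1000)))
        gc = float(np.clip(rng.normal(p.gc_mean, p.gc_sd), 0.30, 0.65))
        seq = _random_seq(rng, L, gc)

        cds = None
        if bt == "protein_coding":
            u5 = max(30, int(round(p.utr5_frac * L)))
            u3 = max(50, int(round(p.utr3_frac * L)))
            if L - u5 - u3 < 90:
                u5, u3 = 30, 50
            cds = (u5, L - u3)

        has_motif = rng.random() < p.motif_prob
        positions: list[int] = []
        if has_motif and L > len(motif) + 4:
            n_copies = int(rng.integers(1, 4))
            if cds is not None and (L - cds[1]) > len(motif) + 4:
                lo, hi = cds[1], L - len(motif)      # plant in 3'UTR
            else:
                lo, hi = 0, L - len(motif)
            for _ in range(n_copies):
                pos = int(rng.integers(lo, hi))
                seq = seq[:pos] + motif + seq[pos + len(motif):]
                positions.append(pos)

        exon_lens = _split_lengths(rng, L, n_exons)
        n_exons = len(exon_lens)
        intron_lens = rng.integers(60, 800, size=max(0, n_exons - 1))
        strand = "+" if rng.random() < 0.5 else "-"

        emit(_random_seq(rng, int(rng.integers(500, 2000)), 0.42))  # intergenic gap
        tx_parts = []
        off = 0
        for le in exon_lens:
            tx_parts.append(seq[off:off + le])
            off += le
        g_exons: list[tuple[int, int]] = []
        intron_ivs: list[tuple[int, int]] = []
        if strand == "+":
            for j, part in enumerate(tx_parts):
                g_exons.append(emit(part))
                if j < n_exons - 1:
                    intron_ivs.append(emit(_random_seq(rng, int(intron_lens[j]), 0.42)))
        else:
            for j in range(n_exons - 1, -1, -1):
                g_exons.append(emit(revcomp(tx_parts[j])))
                if j > 0:
                    intron_ivs.append(emit(_random_seq(rng, int(intron_lens[j - 1]), 0.42)))
            g_exons = g_exons[::-1]  # 5'->3' = descending genomic for minus strand

        span = (min(s for s, _ in g_exons), max(e for _, e in g_exons))
        tx = TranscriptModel(transcript_id=f"{gid}.t1", gene_id=gid,
                             exons=g_exons, sequence=seq, strand=strand,
                             cds=cds, is_primary=True)
        tx.validate()
        genes[i] = GeneModel(gene_id=gid, chrom=chrom, strand=strand, span=span,
                             raw_biotype=bt, transcripts=[tx])
        if positions:
            motif_tx_pos[gid] = positions
        if bt == "protein_coding":
            for s, e in intron_ivs:
                if e - s >= 400:
                    host_introns.append((gid, s, e, strand))
        feat_rows.append((gid, bt, L, n_exons, gc, bool(positions)))

    emit(_random_seq(rng, int(rng.integers(500, 2000)), 0.42))
    genome_arr = bytearray("".join(segments).encode())

    # carve antisense lncRNAs into host introns, opposite strand
    rng.shuffle(host_introns)
    hosts = list(host_introns)
    for i in antisense_specs:
        gid = f"G{i:05d}"
        bt = "antisense_RNA"
        if not hosts:
            bt = "lincRNA"  # no host available: fall back to intergenic
        if bt == "antisense_RNA":
            _, hs, he, hstrand = hosts.pop()
            La = int(rng.integers(300, min(1500, he - hs - 40) + 1))
            start = int(rng.integers(hs + 10, he - La - 10))
            strand = "-" if hstrand == "+" else "+"
        else:
            La = int(rng.integers(300, 1500))
            strand = "+" if rng.random() < 0.5 else "-"
        gc = float(np.clip(rng.normal(p.gc_mean, p.gc_sd), 0.30, 0.65))
        seq = _random_seq(rng, La, gc)
        has_motif = rng.random() < p.motif_prob
        positions = []
        if has_motif:
            pos = int(rng.integers(0, La - len(motif)))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
            positions = [pos]
        if bt == "antisense_RNA":
            genomic = seq if strand == "+" else revcomp(seq)
            genome_arr[start:start + La] = genomic.encode()
            g_exons = [(start, start + La)]
        else:
            start = len(genome_arr)
            genomic = seq if strand == "+" else revcomp(seq)
            genome_arr.extend(genomic.encode())
            genome_arr.extend(_random_seq(rng, int(rng.integers(500, 2000)), 0.42).encode())
            g_exons = [(start, start + La)]
        tx = TranscriptModel(transcript_id=f"{gid}.t1", gene_id=gid,
                             exons=g_exons, sequence=seq, strand=strand,
                             is_primary=True)
        tx.validate()
        genes[i] = GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                             span=(g_exons[0][0], g_exons[0][1]),
                             raw_biotype=bt, transcripts=[tx])
        if positions:
            motif_tx_pos[gid] = positions
        feat_rows.append((gid, bt, La, 1, gc, bool(positions)))

    gene_list = [genes[i] for i in sorted(genes)]
    genome = {chrom: genome_arr.decode()}

    peaks = []
    by_id = {g.gene_id: g for g in gene_list}
    for gid, positions in sorted(motif_tx_pos.items()):
        tx = by_id[gid].primary_transcript
        gpos = tx.tx_to_genomic(positions[0])
        s = max(0, gpos - 20)
        peaks.append(Interval(chrom=chrom, start=s, end=gpos + len(motif) + 20,
                              name=f"peak_{gid}"))

    rrna = {}
    for j in range(p.n_rrna):
        Lr = int(rng.integers(1200, 5200))
        rrna[f"rRNA_{j + 1}"] = _random_seq(rng, Lr, 0.55)

    feats = pd.DataFrame(feat_rows, columns=[
        "gene_id", "raw_biotype", "length", "n_exons", "gc", "has_motif",
    ]).sort_values("gene_id").reset_index(drop=True)
    feats["exons_per_kb"] = feats["n_exons"] / (feats["length"] / 1000.0)

    return Transcriptome(genes=gene_list, genome=genome, rrna=rrna,
                         clip_peaks=peaks, features=feats)


# ------------------------------------------------------------ steady states

def steady_state_cell(sigma, delta, epsilon):
    """Closed-form steady state of dc/dt = sigma - (delta + epsilon) c."""
    sigma = np.asarray(sigma, float)
    rate = np.asarray(delta, float) + np.asarray(epsilon, float)
    if np.any(rate <= 0):
        raise ValueError("delta + epsilon must be positive")
    return sigma / rate


def _zscore(v):
    v = np.asarray(v, float)
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def simulate_steady_states(txome: Transcriptome,
                           params: Optional[SortingParams] = None,
                           seed: int = 0) -> dict[str, pd.DataFrame]:
    """Compute per-gene truth tables for the basal/treated/inhibitor conditions.

    Each table carries the kinetic rates, the steady-state cell abundance,
    compositional cell and EV fractions, and the true log2 packaging
    log2(ev_frac / cell_frac).  The treated table adds the transcription
    shift ``dlog2_sigma``; the inhibitor table adds the ``affected`` flag.
    """
    p = params or SortingParams()
    rng = np.random.default_rng(seed)
    feats = txome.features
    n = len(feats)

    sigma = rng.lognormal(p.sigma_log_mean, p.sigma_sigma, n)
    halflife = rng.lognormal(p.halflife_log_mean, p.halflife_sigma, n)
    delta = math.log(2) / halflife

    if p.spike_fraction > 0:
        spike = np.zeros(n)
        n_spiked = int(round(n * p.spike_fraction))
        idx = rng.choice(n, n_spiked, replace=False)
        mag = rng.uniform(p.spike_log2_min, p.spike_log2_max, n_spiked)
        sign = np.where(rng.random(n_spiked) < 0.5, 1.0, -1.0)
        spike[idx] = sign * mag
        eps_ref = 2.0 ** p.beta0 * float(np.median(delta))
        epsilon = eps_ref * 2.0 ** spike
        score = p.beta0 + spike  # for bookkeeping only
        true_label = np.where(spike > 0, "enriched",
                              np.where(spike < 0, "depleted", "null"))
    else:
        z = np.column_stack([
            _zscore(np.log2(feats["length"])),
            _zscore(feats["exons_per_kb"]),
            _zscore(feats["gc"]),
            feats["has_motif"].astype(float) - feats["has_motif"].mean(),
            _zscore(np.log2(halflife)),
        ])
        betas = np.array([p.beta_len, p.beta_exon, p.beta_gc, p.beta_motif,
                          p.beta_halflife])
        score = p.beta0 + z @ betas + rng.normal(0, p.basal_noise_sd, n)
        epsilon = delta * 2.0 ** score
        true_label = np.full(n, "", dtype=object)

    def make_table(sig, eps, **extra) -> pd.DataFrame:
        c = steady_state_cell(sig, delta, eps)
        flux = eps * c
        cell_frac = c / c.sum()
        ev_frac = flux / flux.sum()
        df = pd.DataFrame({
            "gene_id": feats["gene_id"].to_numpy(),
            "biotype_class": [
                "mRNA" if b == "protein_coding" else "lncRNA"
                for b in feats["raw_biotype"]
            ],
            "sigma": sig, "delta": delta, "epsilon": eps,
            "halflife_h": halflife,
            "cell_abund": c, "cell_frac": cell_frac, "ev_frac": ev_frac,
            "log2_packaging": np.log2(ev_frac / cell_frac),
            "true_label": true_label,
        })
        for k, v in extra.items():
            df[k] = v
        return df

    out = {"basal": make_table(sigma, epsilon, dlog2_sigma=0.0)}

    # treated: shift transcription of a gene subset, couple packaging
    n_treated = int(round(n * p.treated_fraction))
    tre_idx = rng.choice(n, n_treated, replace=False)
    dls = np.zeros(n)
    mag = rng.uniform(p.treated_shift_min, p.treated_shift_max, n_treated)
    sign = np.where(rng.random(n_treated) < 0.5, 1.0, -1.0)
    dls[tre_idx] = sign * mag
    sigma_t = sigma * 2.0 ** dls
    s_t = (np.log2(epsilon / delta) - p.coupling * dls
           + rng.normal(0, p.packaging_noise_sd, n))
    eps_t = delta * 2.0 ** s_t
    out["treated"] = make_table(sigma_t, eps_t, dlog2_sigma=dls)

    # inhibitor: block export for an affected subset
    aff = rng.random(n) < p.inhibitor_fraction
    eps_i = np.where(aff, (1.0 - p.inhibitor_strength) * epsilon, epsilon)
    out["inhibitor"] = make_table(sigma, eps_i, affected=aff, dlog2_sigma=0.0)
    return out


def true_packaging_delta(truth: dict[str, pd.DataFrame],
                         experimental: str = "treated",
                         basal: str = "basal") -> pd.Series:
    a = truth[experimental].set_index("gene_id")["log2_packaging"]
    b = truth[basal].set_index("gene_id")["log2_packaging"]
    return a - b


# ------------------------------------------------------------ count sampling

def effective_lengths(txome: Transcriptome, frag_len_mean: float) -> pd.Series:
    lens = {g.gene_id: g.primary_transcript.length for g in txome.genes}
    s = pd.Series(lens).sort_index()
    return np.maximum(1.0, s - frag_len_mean + 1.0)


def sample_counts(truth: pd.DataFrame, compartment: str, depth: int,
                  n_reps: int, dispersion: float = 0.05, seed: int = 0,
                  length_weight: Optional[pd.Series] = None) -> pd.DataFrame:
    """Draw gene-level deduplicated molecule counts for one sample group.

    This is the count-level image of the read simulator: gamma-Poisson
    (negative binomial) counts around expected proportions x depth, with
    read probability optionally weighted by effective length.
    """
    col = {"cell": "cell_frac", "ev": "ev_frac"}[compartment]
    pgene = truth.set_index("gene_id")[col]
    if length_weight is not None:
        pgene = pgene * length_weight.reindex(pgene.index)
    pgene = pgene / pgene.sum()
    rng = np.random.default_rng(seed)
    mu = pgene.to_numpy() * depth
    cols = {}
    for r in range(n_reps):
        if dispersion > 0:
            lam = rng.gamma(1.0 / dispersion, mu * dispersion)
        else:
            lam = mu
        cols[f"{compartment}_rep{r + 1}"] = rng.poisson(lam)
    return pd.DataFrame(cols, index=pgene.index)


# ------------------------------------------------------------ read simulation

_LC_MOTIFS = ["A", "T", "AC", "AG", "AT", "CT"]


def _random_umis(rng, n, k):
    idx = rng.integers(0, 4, size=(n, k))
    return ["".join("ACGT"[j] for j in row) for row in idx]


def _add_errors(rng, seq: str, n_err: int) -> str:
    s = list(seq)
    for pos in rng.integers(0, len(s), n_err):
        cur = s[pos]
        alt = "ACGT"[int(rng.integers(0, 4))]
        while alt == cur:
            alt = "ACGT"[int(rng.integers(0, 4))]
        s[pos] = alt
    return "".join(s)


def simulate_reads(txome: Transcriptome, truth: pd.DataFrame,
                   params: Optional[SortingParams] = None,
                   n_reads: int = 100_000, seed: int = 0,
                   condition: str = "basal",
                   compartments: Iterable[str] = ("cell", "ev"),
                   ) -> tuple[dict[str, list[Read]], pd.DataFrame]:
    """Simulate UMI-tagged FASTQ-ready reads for every replicate of a condition.

    ``n_reads`` is the approximate per-sample read target.  Unique molecules
    are drawn multinomially with probability proportional to abundance x
    effective length; each molecule gets a uniform fragment position and a
    random UMI, then Geometric(mean d) PCR copies sharing UMI and position;
    substitution errors at ``error_rate``; declared rRNA / low-complexity
    fractions are appended.  Reads are ``read_length`` nt beginning with the
    synthetic adapter.  Returns (reads per sample, true unique-molecule
    counts per gene x sample).
    """
    p = params or SortingParams()
    if n_reads < p.n_replicates:
        raise ValueError("n_reads must be >= the replicate count")
    seqs = {g.gene_id: g.primary_transcript.sequence for g in txome.genes}
    gene_ids = sorted(seqs)
    lens = np.array([len(seqs[g]) for g in gene_ids])
    insert = p.read_length - len(p.adapter)
    eff = np.maximum(1.0, lens - p.frag_len_mean + 1.0)
    rrna_names = sorted(txome.rrna)

    ss = np.random.SeedSequence(seed)
    out: dict[str, list[Read]] = {}
    truth_counts = {}
    truth_idx = truth.set_index("gene_id")

    for comp in compartments:
        frac = truth_idx[{"cell": "cell_frac", "ev": "ev_frac"}[comp]]
        pgene = frac.reindex(gene_ids).to_numpy() * eff
        pgene = pgene / pgene.sum()
        for rep in range(1, p.n_replicates + 1):
            sample = f"{condition}_{comp}_rep{rep}"
            rng = np.random.default_rng(ss.spawn(1)[0])
            n_rr = int(round(p.rrna_read_fraction * n_reads))
            n_lc = int(round(p.lowcomplexity_read_fraction * n_reads))
            n_tx = n_reads - n_rr - n_lc
            n_mol = max(1, int(round(n_tx / p.pcr_dup_mean)))
            counts = rng.multinomial(n_mol, pgene)
            truth_counts[sample] = pd.Series(counts, index=gene_ids)

            reads: list[Read] = []
            gi = np.repeat(np.arange(len(gene_ids)), counts)
            starts = np.floor(
                rng.random(n_mol) * np.maximum(1, lens[gi] - insert + 1)
            ).astype(int)
            umis = _random_umis(rng, n_mol, p.umi_length)
            copies = rng.geometric(1.0 / p.pcr_dup_mean, n_mol)
            for m in range(n_mol):
                g = gene_ids[gi[m]]
                frag = seqs[g][starts[m]:starts[m] + insert]
                if len(frag) < insert:
                    frag = frag + "A" * (insert - len(frag))
                base = p.adapter + frag
                for _ in range(copies[m]):
                    reads.append(Read(read_id="", umi=umis[m], sequence=base,
                                      sample_id=sample))
            for _ in range(n_rr):
                name = rrna_names[int(rng.integers(0, len(rrna_names)))]
                rs = txome.rrna[name]
                st = int(rng.integers(0, max(1, len(rs) - insert + 1)))
                frag = rs[st:st + insert]
                if len(frag) < insert:
                    frag = frag + "A" * (insert - len(frag))
                reads.append(Read(read_id="",
                                  umi=_random_umis(rng, 1, p.umi_length)[0],
                                  sequence=p.adapter + frag, sample_id=sample))
            for _ in range(n_lc):
                mot = _LC_MOTIFS[int(rng.integers(0, len(_LC_MOTIFS)))]
                junk = (mot * p.read_length)[: p.read_length]
                reads.append(Read(read_id="",
                                  umi=_random_umis(rng, 1, p.umi_length)[0],
                                  sequence=junk, sample_id=sample))
            if p.error_rate > 0:
                n_err = rng.binomial(p.read_length, p.error_rate, len(reads))
                for ri in np.nonzero(n_err)[0]:
                    reads[ri].sequence = _add_errors(rng, reads[ri].sequence,
                                                     int(n_err[ri]))
            order = rng.permutation(len(reads))
            reads = [reads[j] for j in order]
            for j, r in enumerate(reads):
                r.read_id = f"{sample}:r{j:07d}"
            out[sample] = reads

    truth_df = pd.DataFrame(truth_counts)
    truth_df.index.name = "gene_id"
    return out, truth_df
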