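# loteva

**Long Transcript EV Abundance analysis**: a tested pipeline for asking which
long RNAs (mRNA and lncRNA) a cell packages into its extracellular vesicles
(EVs), how that packaging changes with the cell's condition, and what it does
to the cell's own transcriptome — paired with a kinetic synthetic-data
generator so every stage can be validated without external sequencing data.

## Who this is for

Groups doing cell-vs-EV RNA-seq with UMI-tagged low-input libraries, and
anyone who wants a transparent, self-contained reimplementation of the
analysis stages such experiments need: low-complexity and rRNA read
filtering, transcriptome pseudo-alignment, UMI/positional duplicate removal,
equivalence-class EM quantification, negative-binomial differential
abundance, transcript-feature and RBP-motif characterization of the
EV-enriched set, and condition contrasts built on the packaging statistic.

## The model at the core

Cellular abundance of each transcript is a first-order homeostasis between
transcription (σ, molecules/h), decay (δ, /h) and export into EVs (ε, /h):

    dc/dt = σ − (δ + ε)·c      ⇒      c* = σ / (δ + ε)

EV output flux is ε·c*, observed compositionally (sequencing measures
proportions). Per-gene packaging is the log2 fold difference of EV versus
cell abundance; the **packaging change** between two conditions is

    ΔP = log2(EV−cell fold difference, experimental)
       − log2(EV−cell fold difference, basal)

The synthetic generator makes this model generative: export odds
log2(ε/δ) are a linear function of transcript features (length, exon
density, GC, a planted motif, half-life) plus noise, a treated condition
couples packaging to transcription shifts with coefficient λ
(Δlog2 packaging = −λ·Δlog2 σ + noise), and an inhibitor condition scales
ε by (1 − i). Every analysis stage is validated by recovering these
planted structures.

A gene is *detected* when its mean TPM across replicates is ≥ 1, and
*EV-enriched*/*EV-depleted* when the EV-vs-cell contrast gives BH-adjusted
p < 0.1 with the corresponding sign. Duplicate reads are those sharing a
UMI that map within half a read length (38 bp for 75-nt reads) of each
other on the same transcript.

## Worked example

Simulate a 2000-gene transcriptome with coupling λ = 0.3, draw replicate
count matrices for cells and EVs at 1M reads, call differential packaging,
and test whether packaging changes anticorrelate with cellular changes:

```python
import pandas as pd
from loteva import (SortingParams, build_transcriptome, simulate_steady_states,
                    sample_counts, test_differential, packaging_delta,
                    anticorrelation)
from loteva.synthetic import effective_lengths

params = SortingParams(coupling=0.3)
txome = build_transcriptome(n_genes=2000, params=params, seed=1)
truth = simulate_steady_states(txome, params, seed=2)
efflen = effective_lengths(txome, params.frag_len_mean)

def ev_vs_cell(cond, seed):
    cell = sample_counts(truth[cond], "cell", depth=1_000_000, n_reps=3,
                         seed=seed, length_weight=efflen)
    ev = sample_counts(truth[cond], "ev", depth=1_000_000, n_reps=3,
                       seed=seed + 1, length_weight=efflen)
    counts = pd.concat([cell, ev], axis=1)
    return test_differential(counts, list(cell.columns), list(ev.columns))

basal = ev_vs_cell("basal", seed=10)
treated = ev_vs_cell("treated", seed=20)
print(basal["status"].value_counts().to_dict())

cell_b = sample_counts(truth["basal"], "cell", 1_000_000, 3, seed=30,
                       length_weight=efflen)
cell_t = sample_counts(truth["treated"], "cell", 1_000_000, 3, seed=31,
                       length_weight=efflen).rename(columns=lambda c: c + "_t")
cell_changes = test_differential(pd.concat([cell_b, cell_t], axis=1),
                                 list(cell_b.columns),
                                 [c + "_t" for c in cell_b.columns])

deltas = packaging_delta(treated, basal)
rep = anticorrelation(deltas, cell_changes)
print(f"r = {rep.result.statistic:.3f}, p = {rep.result.p_value:.2e}, "
      f"slope = {rep.slope:.3f} (n = {rep.n})")
```

Output:

```
{'unchanged': 794, 'enriched': 612, 'depleted': 594}
r = -0.386, p = 3.74e-72, slope = -0.258 (n = 2000)
```

612 genes are called EV-enriched and 594 EV-depleted at padj < 0.1; the
packaging change is negatively correlated with the cellular change
(r = −0.39), and the regression slope −0.26 recovers the planted coupling
−λ = −0.3 up to the attenuation expected from measurement noise in the
cellular fold changes.

The read-level path is available through the CLI:

```
loteva simulate --config sim.yaml --seed 4 --outdir sim/
loteva preprocess --fastq basal_cell_rep1=sim/basal_cell_rep1.fastq ... \
    --annotation sim/genes.gtf --genome sim/genome.fa --rrna sim/rrna.fa \
    --out abundance.tsv
loteva diff --counts abundance.tsv --group1 <cells> --group2 <evs> --out diff.tsv
```

plus `loteva coverage`, `loteva packaging`, `loteva inhibitor`,
`loteva features`, `loteva motifs` and `loteva clip` for the downstream
stages.

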