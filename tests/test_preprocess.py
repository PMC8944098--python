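"""Read-level stages: trimming, complexity filter, rRNA screen,
pseudo-alignment and UMI/positional dedup."""

import math

import numpy as np
import pytest

from loteva.models import Read
from loteva.preprocess import (AlignmentSet, TranscriptomeIndex,
                               build_rrna_kmers, complexity_score, dedup_umi,
                               filter_low_complexity, preprocess_sample,
                               pseudoalign, screen_rrna, trim_reads)
from loteva.studies import dedup_bruteforce, random_alignments
from loteva.synthetic import SortingParams, simulate_reads


def _read(seq, rid="r1", umi="ACGTACGT"):
    return Read(read_id=rid, umi=umi, sequence=seq, quality="I" * len(seq),
                sample_id="s1")


class TestTrim:
    def test_removes_adapter(self):
        out = list(trim_reads([_read("A" * 75)], n_trim=5))
        assert len(out[0].sequence) == 70
        assert len(out[0].quality) == 70

    def test_zero_trim_is_identity(self):
        r = _read("ACGTACGT" * 4)
        out = list(trim_reads([r], n_trim=0))
        assert out[0].sequence == r.sequence

    def test_short_read_discarded(self):
        assert list(trim_reads([_read("A" * 24)], n_trim=5, min_length=20)) == []


class TestComplexity:
    def test_dinucleotide_repeat_removed(self):
        seq = "AC" * 25
        # two distinct trimers at equal frequency over 48 windows
        expected = 100 * math.log(2) / math.log(48)
        assert complexity_score(seq) == pytest.approx(expected)
        assert expected < 70
        assert list(filter_low_complexity([_read(seq)])) == []

    def test_homopolymer_scores_zero(self):
        assert complexity_score("A" * 40) == 0.0

    def test_random_reads_retained(self):
        rng = np.random.default_rng(5)
        reads = [_read("".join(rng.choice(list("ACGT"), 70)), rid=f"r{i}")
                 for i in range(1000)]
        kept = list(filter_low_complexity(reads))
        assert len(kept) / len(reads) > 0.99


class TestRrnaScreen:
    def test_reference_read_flagged_and_foreign_kept(self, small_txome):
        kmers = build_rrna_kmers(small_txome.rrna, k=25)
        rrna_seq = next(iter(small_txome.rrna.values()))
        reads = [_read(rrna_seq[100:170], rid="rr"),
                 _read(small_txome.genes[0].primary_transcript.sequence[:70],
                       rid="tx")]
        kept, n = screen_rrna(reads, kmers, k=25)
        assert n == 1
        assert [r.read_id for r in kept] == ["tx"]

    def test_simulated_rrna_reads_removed(self, small_txome):
        kmers = build_rrna_kmers(small_txome.rrna, k=25)
        rng = np.random.default_rng(6)
        reads = []
        for name, seq in small_txome.rrna.items():
            for i in range(300):
                s = int(rng.integers(0, len(seq) - 70))
                reads.append(_read(seq[s:s + 70], rid=f"{name}:{i}"))
        _, n = screen_rrna(reads, kmers, k=25)
        assert n >= 0.99 * len(reads)

    def test_read_shorter_than_k_rejected(self):
        with pytest.raises(ValueError):
            screen_rrna([_read("A" * 25)], {"X" * 26}, k=26)

    def test_empty_reference_keeps_everything(self):
        kept, n = screen_rrna([_read("ACGT" * 20)], set(), k=25)
        assert n == 0 and len(kept) == 1


class TestPseudoalign:
    def test_unique_and_shared_regions(self):
        rng = np.random.default_rng(8)
        shared = "".join(rng.choice(list("ACGT"), 120))
        u1 = "".join(rng.choice(list("ACGT"), 150))
        u2 = "".join(rng.choice(list("ACGT"), 150))
        from loteva.models import GeneModel, TranscriptModel

        def gene(gid, seq):
            t = TranscriptModel(transcript_id=f"{gid}.t", gene_id=gid,
                                exons=[(0, len(seq))], sequence=seq)
            return GeneModel(gene_id=gid, chrom="c", strand="+",
                             span=(0, len(seq)), raw_biotype="protein_coding",
                             transcripts=[t])
        g1, g2 = gene("g1", u1 + shared), gene("g2", u2 + shared)
        index = TranscriptomeIndex([g1, g2], k=21)

        unique_read = _read(u1[10:80], rid="u")
        shared_read = _read(shared[20:90], rid="s")
        random_read = _read("".join(rng.choice(list("ACGT"), 70)), rid="x")
        out = {a.read_id: a for a in
               pseudoalign([unique_read, shared_read, random_read], index)}
        assert out["u"].compatible_transcripts == frozenset(["g1.t"])
        assert out["u"].offset == 10
        assert out["s"].compatible_transcripts == frozenset(["g1.t", "g2.t"])
        assert not out["x"].mapped


def _als(specs):
    """specs: (read_id, umi, transcript, offset)"""
    return [AlignmentSet(read_id=r, umi=u, sample_id="s1",
                         compatible_transcripts=frozenset([t]),
                         primary_transcript=t, offset=o, aligned_length=70)
            for r, u, t, o in specs]


class TestDedup:
    def test_window_is_half_read_length(self):
        # 75-nt reads: offsets 38 apart merge, 40 apart do not
        near = _als([("a", "U1", "T1", 0), ("b", "U1", "T1", 38)])
        far = _als([("a", "U1", "T1", 0), ("b", "U1", "T1", 40)])
        assert len(dedup_umi(near, read_length=75)[0]) == 1
        assert len(dedup_umi(far, read_length=75)[0]) == 2

    def test_distinct_umis_kept(self):
        als = _als([("a", "U1", "T1", 0), ("b", "U2", "T1", 0)])
        kept, removed = dedup_umi(als, read_length=75)
        assert len(kept) == 2 and removed == 0

    def test_retains_cluster_anchor(self):
        # first read by offset survives; ties on offset break by read_id
        als = _als([("z", "U1", "T1", 0), ("a", "U1", "T1", 5)])
        kept, _ = dedup_umi(als, read_length=75)
        assert kept[0].read_id == "z"
        tied = _als([("z", "U1", "T1", 0), ("a", "U1", "T1", 0)])
        kept, _ = dedup_umi(tied, read_length=75)
        assert kept[0].read_id == "a"

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        als = random_alignments(rng, n=400)
        once, _ = dedup_umi(als, read_length=75)
        twice, removed = dedup_umi(once, read_length=75)
        assert removed == 0
        assert {a.read_id for a in once} == {a.read_id for a in twice}

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(10)
        als = random_alignments(rng, n=500)
        kept, _ = dedup_umi(als, read_length=75)
        assert {a.read_id for a in kept} == dedup_bruteforce(als)

    def test_unmapped_reads_pass_through(self):
        a = AlignmentSet(read_id="u", umi="U", sample_id="s1")
        kept, _ = dedup_umi([a], read_length=75)
        assert kept[0].read_id == "u"


class TestPipelineRecovery:
    def test_dedup_recovers_molecule_counts(self, small_txome, small_truth):
        """At zero error and zero jitter the deduplicated read count per gene
        equals the true molecule count, up to birthday-bound UMI collisions."""
        p = SortingParams(error_rate=0.0, pcr_dup_mean=2.0,
                          rrna_read_fraction=0.0,
                          lowcomplexity_read_fraction=0.0, n_replicates=1)
        reads, mol = simulate_reads(small_txome, small_truth["basal"], p,
                                    n_reads=12_000, seed=15,
                                    compartments=("cell",))
        sample = next(iter(reads))
        index = TranscriptomeIndex(small_txome.genes, k=21)
        deduped, stats = preprocess_sample(
            iter(reads[sample]), index, set(), n_trim=5, read_length=75)
        from collections import Counter
        rec = Counter()
        for a in deduped:
            if a.mapped:
                rec[a.primary_transcript.rsplit(".", 1)[0]] += 1
        true = mol[sample]
        total_rec = sum(rec.values())
        # collision bound: pairs within a gene sharing one of 4^8 UMIs and
        # overlapping positions
        lens = {g.gene_id: g.primary_transcript.length
                for g in small_txome.genes}
        bound = sum(
            (m * (m - 1) / 2) / 4 ** 8 * min(1.0, 77.0 / max(1, lens[g] - 69))
            for g, m in true.items())
        assert abs(total_rec - true.sum()) <= max(3, 2 * bound + 3)
        diffs = sum(abs(rec.get(g, 0) - c) for g, c in true.items())
        assert diffs <= max(4, 4 * bound + 4)
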