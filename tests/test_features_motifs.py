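"""Feature extraction, group comparisons, half-life fitting, PWM scanning
with its exact null, CLIP overlap, and lncRNA pairing."""

import itertools

import numpy as np
import pandas as pd
import pytest

from loteva.features import (clip_target_enrichment, compare_groups,
                             count_overlapping, estimate_half_life,
                             extract_features, genes_bound_by_peaks,
                             pair_correlation)
from loteva.models import GeneModel, Interval, TranscriptModel
from loteva.motifs import (PWM, builtin_rbp_motifs, load_meme,
                           motif_enrichment, scan_pwm, scan_sequence,
                           score_threshold, write_meme)


def _gene(gid, seq, biotype="protein_coding", cds=None, n_exons=1,
          chrom="c", strand="+", span=None):
    L = len(seq)
    step = L // n_exons
    exons = [(i * step, (i + 1) * step if i < n_exons - 1 else L)
             for i in range(n_exons)]
    t = TranscriptModel(transcript_id=f"{gid}.t1", gene_id=gid, exons=exons,
                        sequence=seq, cds=cds, strand=strand)
    return GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                     span=span or (0, L), raw_biotype=biotype,
                     transcripts=[t])


class TestExtractFeatures:
    def test_exon_density_and_gc(self):
        g = _gene("g1", "GC" * 1000, biotype="lincRNA", n_exons=4)
        feats = extract_features([g])
        assert feats.loc["g1", "exons_per_kb"] == pytest.approx(2.0)
        assert feats.loc["g1", "gc_pct"] == pytest.approx(100.0)

    def test_are_density_counts_overlapping_pentamers(self):
        # 3'UTR ATTTATTTA: two overlapping ATTTA pentamers in 9 nt
        utr3 = "ATTTATTTA"
        seq = "G" * 30 + "C" * 60 + utr3
        g = _gene("g1", seq, cds=(30, 90))
        feats = extract_features([g])
        assert feats.loc["g1", "utr5_len"] == 30
        assert feats.loc["g1", "cds_len"] == 60
        assert feats.loc["g1", "utr3_len"] == 9
        assert feats.loc["g1", "are_per_kb_3utr"] == pytest.approx(2 / 0.009)
        assert feats.loc["g1", "are_per_kb_5utr"] == 0.0

    def test_are_count_matches_naive_scan(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            seq = "".join(rng.choice(list("AT"), 60))
            naive = sum(seq[i:i + 5] == "ATTTA" for i in range(len(seq) - 4))
            assert count_overlapping(seq, "ATTTA") == naive

    def test_pure_and_deterministic(self):
        g = _gene("g1", "ACGT" * 100, biotype="lincRNA")
        a = extract_features([g])
        b = extract_features([g])
        pd.testing.assert_frame_equal(a, b)


class TestCompareGroups:
    def test_identical_sets_give_p_one(self):
        rng = np.random.default_rng(14)
        feats = pd.DataFrame({"length": rng.integers(300, 3000, 20)},
                             index=[f"g{i}" for i in range(20)])
        out = compare_groups(feats, feats.index[:10], feats.index[:10],
                             ["length"])
        assert out.loc["length", "p"] == pytest.approx(1.0)

    def test_constant_field_skipped(self):
        feats = pd.DataFrame({"const": 1.0},
                             index=[f"g{i}" for i in range(10)])
        out = compare_groups(feats, feats.index[:5], feats.index[5:],
                             ["const"])
        assert out.empty

    def test_empty_group_rejected(self):
        feats = pd.DataFrame({"length": [1.0]}, index=["g0"])
        with pytest.raises(ValueError):
            compare_groups(feats, [], ["g0"], ["length"])


class TestHalfLife:
    def test_exact_geometric_decay(self):
        tc = pd.DataFrame([[1.0, 0.5, 0.25]], index=["g1"],
                          columns=["t0", "t1", "t2"])
        est = estimate_half_life(tc, [0.0, 1.0, 2.0])
        assert est["g1"] == pytest.approx(1.0)

    def test_constant_abundance_is_stable(self):
        tc = pd.DataFrame([[2.0, 2.0, 2.0]], index=["g1"],
                          columns=["t0", "t1", "t2"])
        est = estimate_half_life(tc, [0.0, 1.0, 2.0])
        assert np.isnan(est["g1"])

    def test_too_few_positive_points_undefined(self):
        tc = pd.DataFrame([[1.0, 0.0, 0.0]], index=["g1"],
                          columns=["t0", "t1", "t2"])
        est = estimate_half_life(tc, [0.0, 1.0, 2.0])
        assert np.isnan(est["g1"])

    def test_requires_three_timepoints(self):
        tc = pd.DataFrame([[1.0, 0.5]], index=["g1"], columns=["t0", "t1"])
        with pytest.raises(ValueError):
            estimate_half_life(tc, [0.0, 1.0])


class TestPWMScan:
    def test_indicator_motif_hits_its_site(self):
        mat = np.zeros((4, 4))
        for j, b in enumerate("GGAG"):
            mat[j, "ACGT".index(b)] = 1.0
        pwm = PWM(motif_id="ind", matrix=mat)
        hit, _ = scan_sequence(pwm, "UUGGAGUU")
        assert hit
        miss, _ = scan_sequence(pwm, "UUUUUUUU")
        assert not miss

    def test_sequence_shorter_than_motif_is_no_hit(self):
        pwm = builtin_rbp_motifs()[0]
        hit, score = scan_sequence(pwm, "ACG")
        assert not hit and score == float("-inf")

    def test_threshold_matches_bruteforce_enumeration(self):
        pwm = PWM(motif_id="w5", matrix=np.array([
            [0.7, 0.1, 0.1, 0.1],
            [0.1, 0.7, 0.1, 0.1],
            [0.25, 0.25, 0.25, 0.25],
            [0.1, 0.1, 0.1, 0.7],
            [0.4, 0.4, 0.1, 0.1],
        ]))
        lom = np.rint(pwm.log_odds() * 1000) / 1000
        scores = sorted(
            (sum(lom[j, b] for j, b in enumerate(word)),
             np.prod([pwm.background[b] for b in word]))
            for word in itertools.product(range(4), repeat=5))
        # smallest score with exact tail probability <= 1e-3
        best = None
        tail = 0.0
        for s, pr in reversed(scores):
            tail += pr
            if tail <= 1e-3 + 1e-12:
                best = s
        assert score_threshold(pwm, p_thresh=1e-3) == pytest.approx(best,
                                                                    abs=2e-3)

    def test_hits_invariant_to_flanking_sequence(self):
        pwm = builtin_rbp_motifs()[0]
        core = "AGGAGGC"
        assert scan_sequence(pwm, core)[0]
        assert scan_sequence(pwm, "TTTT" + core + "CCCC")[0]
        assert not scan_sequence(pwm, "T" * 30)[0]

    def test_scan_pwm_table(self):
        pwms = builtin_rbp_motifs()
        seqs = {"g1": "TTTTAGGAGGCTTTT", "g2": "T" * 15}
        hits = scan_pwm(seqs, pwms)
        assert bool(hits.loc["g1", "SYN_GGAG01"])
        assert not bool(hits.loc["g2", "SYN_GGAG01"])


class TestMotifEnrichment:
    def test_identical_rates_not_enriched(self):
        hits = pd.DataFrame({"m": [True, False] * 10},
                            index=[f"g{i}" for i in range(20)])
        out = motif_enrichment(hits, [f"g{i}" for i in range(0, 10)],
                               [f"g{i}" for i in range(10, 20)])
        assert out.loc["m", "p"] > 0.5

    def test_zero_hit_motif_retained_with_p_one(self):
        hits = pd.DataFrame({"m": [False] * 20},
                            index=[f"g{i}" for i in range(20)])
        out = motif_enrichment(hits, [f"g{i}" for i in range(10)],
                               [f"g{i}" for i in range(10, 20)])
        assert out.loc["m", "p"] == pytest.approx(1.0)

    def test_overlapping_sets_rejected(self):
        hits = pd.DataFrame({"m": [True] * 5},
                            index=[f"g{i}" for i in range(5)])
        with pytest.raises(ValueError):
            motif_enrichment(hits, ["g0", "g1"], ["g1", "g2"])


class TestMemeIO:
    def test_round_trip(self, tmp_path):
        pwms = builtin_rbp_motifs()
        path = tmp_path / "motifs.meme"
        write_meme(pwms, path)
        back = load_meme(path)
        assert [m.motif_id for m in back] == [m.motif_id for m in pwms]
        for a, b in zip(pwms, back):
            assert np.allclose(a.matrix, b.matrix, atol=1e-5)


class TestClipOverlap:
    def test_peak_inside_span_binds(self):
        g = _gene("g1", "A" * 500, span=(1000, 1500))
        bound = genes_bound_by_peaks(
            [Interval(chrom="c", start=1100, end=1150)], [g])
        assert bool(bound["g1"])

    def test_abutting_peak_does_not_bind(self):
        g = _gene("g1", "A" * 500, span=(1000, 1500))
        bound = genes_bound_by_peaks(
            [Interval(chrom="c", start=1500, end=1600)], [g])
        assert not bool(bound["g1"])

    def test_no_peaks_gives_p_one(self):
        g = _gene("g1", "A" * 500)
        _, res = clip_target_enrichment([], [g], ["g1"], ["g1"])
        assert res.p_value == 1.0

    def test_planted_peaks_enrich_motif_genes(self, small_txome, small_truth):
        truth = small_truth["basal"].set_index("gene_id")
        has_motif = small_txome.features.set_index("gene_id")["has_motif"]
        enriched = list(truth.index[
            (truth["log2_packaging"] > truth["log2_packaging"].median())])
        expressed = list(truth.index)
        bound, res = clip_target_enrichment(small_txome.clip_peaks,
                                            small_txome.genes,
                                            enriched, expressed)
        # planted peaks sit at motif genes, so bound tracks the motif flag
        overlap = (bound.reindex(has_motif.index) == has_motif).mean()
        assert overlap > 0.9


class TestPairing:
    def _diff(self, mapping):
        return pd.DataFrame({"log2fd": pd.Series(mapping)})

    def test_duplicated_log2fd_gives_r_one(self):
        genes = []
        diff = {}
        rng = np.random.default_rng(15)
        for i in range(5):
            pc = _gene(f"p{i}", "A" * 400, span=(i * 2000, i * 2000 + 1500),
                       strand="+")
            lnc = _gene(f"l{i}", "A" * 200, biotype="antisense_RNA",
                        span=(i * 2000 + 200, i * 2000 + 500), strand="-")
            genes += [pc, lnc]
            v = float(rng.normal())
            diff[f"p{i}"] = v
            diff[f"l{i}"] = v
        rep = pair_correlation(genes, self._diff(diff), "antisense_pc")
        assert rep.result.statistic == pytest.approx(1.0)
        assert len(rep.table) == 5

    def test_antisense_without_overlap_excluded(self):
        pc = _gene("p0", "A" * 400, span=(0, 1000), strand="+")
        lnc_far = _gene("l0", "A" * 200, biotype="antisense_RNA",
                        span=(5000, 5300), strand="-")
        diff = self._diff({"p0": 1.0, "l0": 2.0})
        with pytest.raises(ValueError):  # no pairs at all -> fewer than 3
            pair_correlation([pc, lnc_far], diff, "antisense_pc")

    def test_lincrna_pairs_with_nearest_neighbor(self):
        pcs = [_gene(f"p{i}", "A" * 400, span=(i * 10_000, i * 10_000 + 1000))
               for i in range(3)]
        lincs = [_gene(f"l{i}", "A" * 200, biotype="lincRNA",
                       span=(i * 10_000 + 1500, i * 10_000 + 1800))
                 for i in range(3)]
        diff = self._diff({"p0": 1.0, "p1": 5.0, "p2": 2.0,
                           "l0": 0.1, "l1": 0.2, "l2": 0.3})
        rep = pair_correlation(pcs + lincs, diff, "lincRNA_neighbor")
        pairs = dict(zip(rep.table["lnc_gene"], rep.table["pc_gene"]))
        assert pairs == {"l0": "p0", "l1": "p1", "l2": "p2"}

    def test_independent_partners_uncorrelated(self):
        """With partner enrichment assigned independently, paired log2fd
        values show no correlation (the null expectation)."""
        from loteva.synthetic import SortingParams, build_transcriptome
        tx = build_transcriptome(1200, SortingParams(lnc_fraction=0.3),
                                 seed=16)
        rng = np.random.default_rng(17)
        diff = pd.DataFrame(
            {"log2fd": rng.normal(size=len(tx.genes))},
            index=[g.gene_id for g in tx.genes])
        rep = pair_correlation(tx.genes, diff, "antisense_pc")
        assert len(rep.table) >= 50
        assert abs(rep.result.statistic) < 0.15
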