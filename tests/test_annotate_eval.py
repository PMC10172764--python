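import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from zflipon.annotate_eval import (
    ConfusionCounts,
    FeatureAnnotation,
    Haplotype,
    classify_feature,
    confusion_counts,
    confusion_metrics,
    contingency_ratio,
    enrichment_table,
    haplotype_score,
    junction_windows,
    junction_windows_to_fasta,
    overlap_recovery,
    repeat_scores,
    roc_auc,
)
from zflipon.genomeio import GenomeSequence, Interval, ScoreTrack


class TestConfusionMetrics:
    def test_closed_form_example(self):
        cc = ConfusionCounts(TP=89, FN=11, FP=25, TN=875)
        assert cc.recall == pytest.approx(0.89)
        assert cc.precision == pytest.approx(89 / 114)
        assert cc.f1 == pytest.approx(2 * cc.precision * cc.recall / (cc.precision + cc.recall))

    def test_perfect_prediction(self):
        truth = np.array([0, 1, 1, 0, 1])
        m = confusion_metrics(truth.astype(float), truth)
        assert (m["precision"], m["recall"], m["f1"]) == (1.0, 1.0, 1.0)

    def test_zero_denominator_gives_nan(self):
        m = confusion_metrics(np.zeros(5), np.zeros(5, int))
        assert np.isnan(m["precision"]) and np.isnan(m["recall"])

    def test_matches_brute_force_counting(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 200))
            p = rng.random(n)
            t = rng.integers(0, 2, n)
            cc = confusion_counts(p, t)
            tp = sum(1 for i in range(n) if p[i] >= 0.5 and t[i])
            fp = sum(1 for i in range(n) if p[i] >= 0.5 and not t[i])
            fn = sum(1 for i in range(n) if p[i] < 0.5 and t[i])
            tn = n - tp - fp - fn
            assert (cc.TP, cc.FP, cc.FN, cc.TN) == (tp, fp, fn, tn)
            assert cc.total == n


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1])) == 1.0

    def test_constant_scores_give_half(self):
        assert roc_auc(np.full(10, 0.3), np.array([0, 1] * 5)) == 0.5

    def test_matches_sklearn_on_random_data(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 300))
            p = rng.random(n)
            t = rng.integers(0, 2, n)
            if t.min() == t.max():
                continue
            assert roc_auc(p, t) == pytest.approx(roc_auc_score(t, p), abs=1e-12)

    def test_degenerate_labels_give_nan(self):
        assert np.isnan(roc_auc(np.random.rand(5), np.ones(5, int)))


@pytest.fixture
def annotation():
    # one + strand gene at [5000, 8000): 5'UTR 5000-5200, exons, 3'UTR
    return FeatureAnnotation(
        tss=[Interval("c", 5000, 5001, strand="+")],
        utr5=[Interval("c", 5000, 5200)],
        exons=[Interval("c", 5000, 5600), Interval("c", 7000, 7400)],
        genes=[Interval("c", 5000, 8000, strand="+")],
        utr3=[Interval("c", 7800, 8000)],
    )


class TestClassifyFeature:
    def test_upstream_of_tss_is_promoter(self, annotation):
        assert classify_feature(Interval("c", 4480, 4520), annotation) == "Promoter (<=3 kb)"

    def test_exon_far_from_tss(self, annotation):
        assert classify_feature(Interval("c", 7100, 7200), annotation) == "Exon"

    def test_intron(self, annotation):
        assert classify_feature(Interval("c", 6000, 6100), annotation) == "Intron"

    def test_distal_intergenic(self, annotation):
        assert classify_feature(Interval("c", 20_000, 20_100), annotation) == "Distal Intergenic"

    def test_downstream_within_300(self, annotation):
        assert classify_feature(Interval("c", 8100, 8200), annotation) == "Downstream (<=300)"

    def test_unannotated_chrom_falls_through(self, annotation):
        assert classify_feature(Interval("chrU", 10, 20), annotation) == "Distal Intergenic"

    def test_utr5_beats_exon(self, annotation):
        # midpoint inside both the 5'UTR and the first exon
        assert classify_feature(Interval("c", 5100, 5150), annotation) == "5' UTR"


class TestOverlapRecovery:
    def test_single_bp_intersection_counts_as_shared(self):
        exp = [Interval("c", 0, 10), Interval("c", 100, 120), Interval("c", 300, 310)]
        pred = [Interval("c", 9, 50), Interval("c", 500, 600)]
        table = overlap_recovery(exp, pred)
        row = table.iloc[0]
        assert (row["shared"], row["experimental_only"]) == (1, 2)
        assert row["percent"] == pytest.approx(100 / 3)

    def test_full_containment_gives_100(self):
        exp = [Interval("c", 10, 20)]
        pred = [Interval("c", 0, 100)]
        assert overlap_recovery(exp, pred).iloc[0]["percent"] == 100.0

    def test_printed_table_ratios(self):
        # shared / (shared + experimental-only), at the printed precision
        assert contingency_ratio(26_751, 26_751 + 2_040, decimals=2) == 92.91
        assert contingency_ratio(1_650, 1_650 + 81, decimals=2) == 95.32


class TestEnrichment:
    def test_two_class_example(self):
        t = enrichment_table({"A": 50, "B": 50}, {"A": 10, "B": 90})
        a = t[t["class"] == "A"].iloc[0]
        assert (a["observed_pct"], a["expected_pct"], a["difference_pp"]) == (50.0, 10.0, 40.0)

    def test_background_distribution_gives_zero_difference(self):
        t = enrichment_table({"A": 30, "B": 70}, {"A": 300, "B": 700})
        assert np.allclose(t["difference_pp"], 0.0)

    def test_columns_sum_to_100(self, rng):
        hits = {f"c{i}": int(rng.integers(1, 100)) for i in range(6)}
        bg = {f"c{i}": int(rng.integers(1, 1000)) for i in range(6)}
        t = enrichment_table(hits, bg)
        assert t["observed_pct"].sum() == pytest.approx(100.0)
        assert t["expected_pct"].sum() == pytest.approx(100.0)


class TestRepeatScores:
    def test_constant_track(self):
        track = ScoreTrack("c", np.full(100, 2.5))
        t = repeat_scores(track, {"(CG)n": [Interval("c", 10, 30)]})
        row = t.iloc[0]
        assert row["mean_base_score"] == row["max_base_score"] == 2.5
        assert row["bases_in_repeats"] == 20

    def test_matches_brute_force_aggregation(self, rng):
        vals = rng.random(500)
        track = ScoreTrack("c", vals)
        fams = {
            "a": [Interval("c", 10, 60), Interval("c", 40, 90)],
            "b": [Interval("c", 200, 260)],
        }
        t = repeat_scores(track, fams).set_index("family")
        mask = np.zeros(500, bool)
        mask[10:90] = True
        assert t.loc["a", "mean_base_score"] == pytest.approx(vals[mask].mean())
        assert t.loc["a", "max_base_score"] == pytest.approx(vals[mask].max())
        assert t.loc["b", "bases_in_repeats"] == 60

    def test_empty_family_row_omitted(self):
        track = ScoreTrack("c", np.ones(50))
        t = repeat_scores(track, {"ghost": [Interval("other", 0, 10)]})
        assert len(t) == 0


class TestJunctionWindows:
    def test_boundary_window_coordinates(self):
        genome = GenomeSequence("c", "A" * 300)
        (w1, w2) = junction_windows([Interval("c", 100, 120)], genome)
        assert (w1.start, w1.end, w1.side) == (95, 106, "start")
        assert (w2.start, w2.end, w2.side) == (114, 125, "end")

    def test_contig_edge_windows_dropped(self):
        genome = GenomeSequence("c", "A" * 50)
        ws = junction_windows([Interval("c", 2, 20)], genome)
        assert [w.side for w in ws] == ["end"]

    def test_window_count_conservation(self, rng):
        genome = GenomeSequence("c", "".join(rng.choice(list("ACGT"), 1000)))
        segs = []
        for _ in range(30):
            s = int(rng.integers(0, 980))
            segs.append(Interval("c", s, s + int(rng.integers(2, 20))))
        ws = junction_windows(segs, genome)
        dropped = sum(1 for seg in segs for c in (seg.start, seg.end - 1) if c < 5 or c + 6 > 1000)
        assert len(ws) == 2 * len(segs) - dropped
        assert all(len(w.seq) == 11 for w in ws)

    def test_fasta_export_headers_declare_convention(self, tmp_path):
        genome = GenomeSequence("c", "ACGT" * 100)
        ws = junction_windows([Interval("c", 100, 120)], genome)
        out = tmp_path / "j.fa"
        junction_windows_to_fasta(ws, out)
        text = out.read_text()
        assert text.count(">") == 2 and "center=boundary_base" in text


class TestHaplotypes:
    def test_example_sum(self):
        assert haplotype_score([+1, +1, -1, 0]) == 1

    def test_all_zero(self):
        assert haplotype_score([0, 0, 0]) == 0

    @given(st.lists(st.sampled_from([-1, 0, 1]), min_size=1, max_size=20))
    def test_antisymmetry(self, dirs):
        assert haplotype_score([-d for d in dirs]) == -haplotype_score(dirs)

    def test_haplotype_record_invariants(self):
        h = Haplotype(alleles=("A", "G", "T"), directions=(1, -1, 0))
        assert h.score == 0
        assert abs(h.score) <= len(h.alleles)
        with pytest.raises(ValueError):
            Haplotype(alleles=("A",), directions=(2,))


class TestContingencyRatio:
    def test_printed_values(self):
        assert contingency_ratio(655, 108_517) == 0.6
        assert contingency_ratio(1_093, 1_160) == 94.2
        assert contingency_ratio(109, 115, decimals=0) == 95.0
        assert contingency_ratio(372, 4_343) == 8.6
        assert contingency_ratio(124, 4_343) == 2.9

    def test_zero_numerator(self):
        assert contingency_ratio(0, 100) == 0.0

    def test_half_up_rounding(self):
        assert contingency_ratio(5, 1000) == 0.5
        assert contingency_ratio(125, 1000, decimals=1) == 12.5
        assert contingency_ratio(1, 16, decimals=2) == 6.25

    def test_matches_plain_division_before_rounding(self, rng):
        for _ in range(100):
            n = int(rng.integers(0, 1000))
            d = int(rng.integers(1, 10_000))
            assert contingency_ratio(n, d, decimals=6) == pytest.approx(100 * n / d, abs=5e-7)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            contingency_ratio(1, 0)
        with pytest.raises(ValueError):
            contingency_ratio(-1, 10)
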