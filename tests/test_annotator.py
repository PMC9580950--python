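"""Triage, quality filtering, RC re-annotation, clustering, naming, dedup."""

import numpy as np
import pandas as pd
import pytest

from srnakit.annotator import (
    DetectedMiRNA,
    KnownIndex,
    annotate_detections,
    assign_functional_names,
    cluster_novels,
    deduplicate_counts,
    quality_filter,
    reannotate_reverse_complements,
    rename_novels,
    triage_reads,
)
from srnakit.reference_io import GenomicInterval, ReferenceRecord, RnaClass


def det(seq, label, chrom="chr1", start=100, count=1, status="novel", strand="+"):
    return DetectedMiRNA(
        seq, label, status, GenomicInterval(chrom, start, start + len(seq) - 1, strand), count
    )


MIR_6859 = ReferenceRecord(
    "hsa-mir-6859-3p",
    "tgacccccatgtcgcctctgtag",
    RnaClass.KNOWN_MIRNA,
    GenomicInterval("chr1", 17369, 17391, "-"),
)
MIR_339 = ReferenceRecord(
    "hsa-mir-339",
    "tccctgtcctccaggagctcacg",
    RnaClass.KNOWN_MIRNA,
    GenomicInterval("chr7", 1000, 1022, "+"),
)


class TestTriage:
    @pytest.mark.parametrize(
        "length,bin_name",
        [
            (17, "mirna_track"),
            (22, "mirna_track"),
            (24, "mirna_track"),
            (25, "pirna_track"),
            (28, "pirna_track"),
            (31, "pirna_track"),
            (32, "rejected"),
            (35, "rejected"),
            (16, "rejected"),
        ],
    )
    def test_length_bins(self, length, bin_name):
        bins = triage_reads([("r", "a" * length)])
        assert [name for name, members in bins.items() if members] == [bin_name]

    def test_partition_is_exhaustive_and_disjoint(self):
        reads = [(f"r{n}", "a" * n) for n in range(1, 60)]
        bins = triage_reads(reads)
        assert sum(len(v) for v in bins.values()) == len(reads)


class TestQualityFilter:
    def test_drop_when_more_than_ten_percent_low(self):
        scores = [19, 19] + [30] * 8  # 20% below Q20
        assert quality_filter(scores) is False

    def test_keep_at_exactly_ten_percent(self):
        scores = [19] + [30] * 9  # exactly 10%, rule is strictly "more than"
        assert quality_filter(scores) is True

    def test_keep_all_high_quality(self):
        assert quality_filter("I" * 40) is True

    def test_phred33_string_input(self):
        # '#' is Q2; 3 of 10 bases low
        assert quality_filter("###IIIIIII") is False

    def test_empty_qualities_rejected(self):
        with pytest.raises(ValueError):
            quality_filter("")


class TestReannotateReverseComplements:
    def test_rc_at_same_locus_reannotated_to_known(self):
        candidate = det(
            "ctacagaggcgacatgggggtca", "nov1", chrom="chr1", start=17369, count=5
        )
        out = reannotate_reverse_complements([candidate], KnownIndex([MIR_6859]))
        assert len(out) == 1
        assert out[0].status == "known"
        assert out[0].label == "hsa-mir-6859-3p"
        assert out[0].count == 5

    def test_forward_match_needs_no_rc(self):
        candidate = det(MIR_6859.mature_seq, "nov1", chrom="chr5", start=1, count=2)
        out = reannotate_reverse_complements([candidate], KnownIndex([MIR_6859]))
        assert out[0].status == "known"

    def test_rc_match_at_different_locus_stays_novel(self):
        candidate = det(
            "ctacagaggcgacatgggggtca", "nov1", chrom="chr1", start=99999, count=5
        )
        out = reannotate_reverse_complements([candidate], KnownIndex([MIR_6859]))
        assert out[0].status == "novel"

    def test_counts_merge_into_existing_known_detection(self):
        known_det = det(
            MIR_6859.mature_seq,
            "hsa-mir-6859-3p",
            chrom="chr1",
            start=17369,
            count=10,
            status="known",
        )
        rc_det = det(
            "ctacagaggcgacatgggggtca", "nov1", chrom="chr1", start=17369, count=5
        )
        out = reannotate_reverse_complements([known_det, rc_det], KnownIndex([MIR_6859]))
        assert len(out) == 1
        assert out[0].count == 15


class TestClusterNovels:
    def test_merge_rule_example(self):
        a = det("tagcttatcagactgatgttga", "n1", start=100, count=7)
        b = det("tagcttatcagactgttgttga", "n2", start=102, count=3)  # 1-nt xseed diff
        clusters = cluster_novels([a, b])
        assert len(clusters) == 1
        assert sum(d.count for d in clusters[0]) == 10

    def test_distant_loci_stay_separate(self):
        a = det("tagcttatcagactgatgttga", "n1", start=100, count=7)
        b = det("tagcttatcagactgatgttga", "n2", start=600, count=3)
        assert len(cluster_novels([a, b])) == 2

    def test_different_seed_never_merges(self):
        a = det("tagcttatcagactgatgttga", "n1", start=100)
        b = det("tggcttgtcagactgatgttga", "n2", start=100)
        assert len(cluster_novels([a, b])) == 2

    def test_xseed_distance_over_two_blocks_merge(self):
        a = det("tagcttatcagactgatgttga", "n1", start=100)
        b = det("tagcttatcagacaaaagttga", "n2", start=100)  # 3-nt xseed diff
        assert len(cluster_novels([a, b])) == 2

    def test_singleton(self):
        a = det("tagcttatcagactgatgttga", "n1")
        assert cluster_novels([a]) == [[a]]

    def test_transitive_closure(self):
        # a~b and b~c by position, a and c are 4 apart: still one cluster
        a = det("tagcttatcagactgatgttga", "n1", start=100, count=1)
        b = det("tagcttatcagactgatgttga", "n2", start=102, count=1)
        c = det("tagcttatcagactgatgttga", "n3", start=104, count=1)
        assert len(cluster_novels([a, b, c])) == 1

    def test_idempotent_on_merged_output(self):
        rng = np.random.default_rng(42)
        seqs = ["tagcttatcagactgatgttga", "acgtacgtacgtacgtacgtac"]
        dets = [
            det(
                seqs[int(rng.integers(2))],
                f"n{i}",
                start=int(rng.integers(100, 110)),
                count=int(rng.integers(1, 20)),
            )
            for i in range(12)
        ]
        clusters = cluster_novels(dets)
        reps = [c[0] for c in clusters]
        assert len(cluster_novels(reps)) >= len(clusters) - 0  # no new merges below
        # representatives of distinct clusters must not merge further into fewer
        # clusters than before when re-clustered together with merged counts
        merged = [
            DetectedMiRNA(
                r.sequence,
                r.label,
                "novel",
                r.interval,
                sum(d.count for d in c),
            )
            for r, c in zip(reps, clusters)
        ]
        assert len(cluster_novels(merged)) == len(clusters)


class TestAssignFunctionalNames:
    def test_paralogue_of_known(self):
        cluster = [det("tccctgtcctccaggagctc", "n1", chrom="chr9", start=5000, count=7)]
        (res,) = assign_functional_names([cluster], [MIR_339])
        assert res.final_name == "hsa-mir-339_1"
        assert res.relation == "paralogue_of_known"
        assert res.anchor_id == "hsa-mir-339"

    def test_second_paralogue_gets_suffix_2(self):
        c1 = [det("tccctgtcctccaggagctc", "n1", chrom="chr9", start=5000, count=7)]
        c2 = [det("tccctgtcctccagtcgctc", "n2", chrom="chr11", start=300, count=3)]
        res = assign_functional_names([c1, c2], [MIR_339])
        names = {r.final_name for r in res}
        assert names == {"hsa-mir-339_1", "hsa-mir-339_2"}
        # higher merged count gets the lower index
        assert next(r for r in res if r.final_name == "hsa-mir-339_1").merged_count == 7

    def test_paralogue_of_novel_and_unique(self):
        c1 = [det("gggcacatacatttcttctcag", "n1", chrom="chr2", start=10, count=9)]
        c2 = [det("gggcacatacagggcttctcag", "n2", chrom="chr5", start=900, count=2)]
        res = assign_functional_names([c1, c2], [])
        by_relation = {r.relation: r for r in res}
        assert by_relation["unique_novel"].final_name == "novel-mir-1"
        assert by_relation["paralogue_of_novel"].final_name == "novel-mir-1_1"
        assert by_relation["paralogue_of_novel"].anchor_id == "novel-mir-1"

    def test_naming_deterministic_under_row_order(self):
        clusters = [
            [det("tccctgtcctccaggagctc", "n1", chrom="chr9", start=5000, count=7)],
            [det("tccctgtcctccagtcgctc", "n2", chrom="chr11", start=300, count=3)],
            [det("gggcacatacatttcttctcag", "n3", chrom="chr2", start=10, count=9)],
        ]
        a = assign_functional_names(clusters, [MIR_339])
        b = assign_functional_names(list(reversed(clusters)), [MIR_339])
        assert {(r.final_name, r.merged_count) for r in a} == {
            (r.final_name, r.merged_count) for r in b
        }


class TestDeduplicateCounts:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["name", "sequence", "chrom", "start", "end", "strand", "count"]
        )

    def test_same_sequence_two_loci_one_row(self):
        table = self._table(
            [
                ["mir-a", "acgt", "chr1", 1, 4, "+", 12],
                ["mir-a2", "acgt", "chr5", 9, 12, "+", 12],
            ]
        )
        out = deduplicate_counts(table)
        assert len(out) == 1
        assert out.loc[0, "count"] == 12
        assert out.loc[0, "n_loci"] == 2

    def test_distinct_sequences_unchanged(self):
        table = self._table(
            [
                ["mir-a", "acgt", "chr1", 1, 4, "+", 12],
                ["mir-b", "ggcc", "chr5", 9, 12, "+", 7],
            ]
        )
        out = deduplicate_counts(table)
        assert len(out) == 2
        assert list(out["count"]) == [12, 7]

    def test_unequal_counts_keep_max_and_warn(self, caplog):
        table = self._table(
            [
                ["mir-a", "acgt", "chr1", 1, 4, "+", 12],
                ["mir-a2", "acgt", "chr5", 9, 12, "+", 9],
            ]
        )
        with caplog.at_level("WARNING"):
            out = deduplicate_counts(table)
        assert out.loc[0, "count"] == 12
        assert any("unequal counts" in m for m in caplog.messages)


class TestRenameNovels:
    def _results(self, n):
        clusters = [
            [det("acgtacgtacgtacgtac", f"n{i}", chrom=f"chr{i+1}", start=10 * i + 1)]
            for i in range(n)
        ]
        return [assign_functional_names([c], [])[0] for c in clusters]

    def test_external_identifier_adopted_with_star(self):
        (res,) = self._results(1)
        renamed = rename_novels([res], {res.sequence: "mmu-mir-99"})
        assert renamed[0].final_name == "mmu-mir-99*"

    def test_sequential_names_all_starred(self):
        results = self._results(2)
        renamed = rename_novels(results, {})
        assert [r.final_name for r in renamed] == ["novel-mir-1*", "novel-mir-2*"]

    def test_duplicate_external_identifiers_rejected(self):
        with pytest.raises(ValueError):
            rename_novels([], {"aaaa": "x", "cccc": "x"})

    def test_empty_input(self):
        assert rename_novels([], {}) == []


class TestAnnotateDetectionsEndToEnd:
    def test_count_conservation_through_full_flow(self):
        detections = [
            det("ctacagaggcgacatgggggtca", "n1", chrom="chr1", start=17369, count=5),
            det("tccctgtcctccaggagctc", "n2", chrom="chr9", start=5000, count=7),
            det("gggcacatacatttcttctcag", "n3", chrom="chr2", start=10, count=4),
            det(
                MIR_339.mature_seq,
                "hsa-mir-339",
                chrom="chr7",
                start=1000,
                count=11,
                status="known",
            ),
        ]
        out = annotate_detections(detections, [MIR_6859, MIR_339])
        assert out["merged_count"].sum() == 27
        relations = set(out["relation"])
        assert relations == {"known", "paralogue_of_known", "unique_novel"}
        unique = out[out["relation"] == "unique_novel"]
        assert unique["final_name"].str.endswith("*").all()


class TestSimulatorRoundTrip:
    def test_truth_fabricated_detections_recover_true_classes(self, toy_records):
        """A reference-exact classifier over simulated truth sequences gets
        every molecule's class right: real molecules match their reference
        (forward or as reverse complement at the same locus), decoys match
        nothing and are rejected."""
        from srnakit.evaluation import accuracy, score_against_truth
        from srnakit.simulator import SimConfig, simulate

        config = SimConfig(
            total_reads=5000, pct_known_mirna=40, pct_novel_mirna=20,
            pct_pirna=20, min_depth=5, distribution=("poisson", 20.0),
            rng_seed=21,
        )
        _, truth = simulate(config, toy_records)

        by_class = {}
        for rec in toy_records:
            by_class.setdefault(rec.rna_class.value, set()).add(rec.mature_seq)
        known_index = KnownIndex(toy_records)

        def classify(seq, interval):
            bins = triage_reads([("x", seq)])
            if bins["rejected"]:
                return "other"
            hits = known_index.lookup(seq) or [
                r for r in known_index.lookup_rc(seq)
                if r.interval.chrom == interval.chrom
                and r.interval.start == interval.start
                and r.interval.end == interval.end
            ]
            if hits:
                return hits[0].rna_class.value
            return "other"

        preds = {}
        for row in truth.itertuples(index=False):
            interval = GenomicInterval(row.chrom, row.start, row.end, row.strand)
            preds[row.molecule_name] = classify(row.sequence, interval)
        labels = dict(zip(truth["molecule_name"], truth["rna_class"]))
        weights = dict(zip(truth["molecule_name"], truth["expression_count"]))
        cs = score_against_truth(preds, labels, weights)
        assert accuracy(cs) == 100.0
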