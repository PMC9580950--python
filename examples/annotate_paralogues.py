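"""Annotate novel-miRNA candidates: RC re-annotation and paralogue naming.

Three candidate detections go in: one is the reverse complement of a known
miRNA at that miRNA's own locus (it is re-annotated as the known miRNA),
one shares a known miRNA's seed at a different locus (it becomes paralogue
``<known>_1``), and one matches nothing (it becomes a starred unique
novel).
"""

from srnakit import (
    DetectedMiRNA,
    GenomicInterval,
    ReferenceRecord,
    RnaClass,
    annotate_detections,
)

known = [
    ReferenceRecord("hsa-mir-6859-3p", "tgacccccatgtcgcctctgtag",
                    RnaClass.KNOWN_MIRNA, GenomicInterval("chr1", 17369, 17391, "-")),
    ReferenceRecord("hsa-mir-339", "tccctgtcctccaggagctcacg",
                    RnaClass.KNOWN_MIRNA, GenomicInterval("chr7", 1000, 1022, "+")),
]
detections = [
    # reverse complement of hsa-mir-6859-3p, mapped at its locus
    DetectedMiRNA("ctacagaggcgacatgggggtca", "cand-1", "novel",
                  GenomicInterval("chr1", 17369, 17391, "+"), 5),
    # same seed as hsa-mir-339, different chromosome
    DetectedMiRNA("tccctgtcctccaggagctc", "cand-2", "novel",
                  GenomicInterval("chr9", 5000, 5019, "+"), 7),
    # matches nothing known
    DetectedMiRNA("aaaaaaagggggggaaccgtca", "cand-3", "novel",
                  GenomicInterval("chr3", 100, 121, "+"), 4),
]

result = annotate_detections(detections, known)
print(result[["final_name", "relation", "anchor_id", "merged_count"]].to_string())
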