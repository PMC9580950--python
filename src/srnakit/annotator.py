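"""Post-alignment annotation of small-RNA detections.

Implements the pipeline-side logic that turns raw aligned-read candidates
into a final annotated count table:

* length triage into miRNA (17-24 nt) and piRNA (25-31 nt) tracks,
  rejecting everything else;
* Phred quality filtering (drop a read if more than 10% of bases fall
  below Q20);
* reverse-complement re-annotation: a "novel" candidate whose reverse
  complement equals a known mature sequence at the same genomic location
  is really that known miRNA sequenced from the opposite strand, and its
  counts are merged into the known entry;
* seed-based clustering of novel candidates (identical seed, <=2-nt xseed
  difference, <=2-nt genomic-position difference merge into one molecule);
* functional naming: a cluster sharing a known miRNA's seed at a different
  locus is a paralogue and is named ``<known>_n``; one sharing another
  novel's seed is named ``novel-mir-x_n``;
* count-table deduplication (the same mature sequence reported at several
  loci collapses to one row);
* final renaming of novel miRNAs, with a ``*`` suffix marking putative
  names.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .reference_io import (
    DEFAULT_SEED_RANGE,
    GenomicInterval,
    ReferenceRecord,
    RnaClass,
    decompose,
    reverse_complement,
)

logger = logging.getLogger(__name__)

MIRNA_LENGTH_RANGE = (17, 24)
PIRNA_LENGTH_RANGE = (25, 31)

#: Columns of the annotated output table produced by :func:`annotate_detections`.
ANNOTATION_COLUMNS = [
    "final_name",
    "relation",
    "anchor_id",
    "merged_count",
    "member_ids",
    "sequence",
    "chrom",
    "start",
    "end",
    "strand",
]


@dataclass(frozen=True)
class DetectedMiRNA:
    """One post-alignment candidate: sequence, provisional label, locus, count."""

    sequence: str
    label: str
    status: str  # "known" or "novel"
    interval: GenomicInterval
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.status not in ("known", "novel"):
            raise ValueError(f"status must be 'known' or 'novel', got {self.status!r}")
        if self.status == "known" and not self.label:
            raise ValueError("known detection requires a non-empty label")


@dataclass(frozen=True)
class AnnotationResult:
    """A finally-named molecule with the detections merged into it."""

    final_name: str
    member_ids: tuple[str, ...]
    merged_count: int
    relation: str  # known | paralogue_of_known | paralogue_of_novel | unique_novel
    anchor_id: str
    sequence: str
    interval: GenomicInterval


class KnownIndex:
    """Exact-match lookup of known mature sequences, with RC queries."""

    def __init__(self, records: Iterable[ReferenceRecord]):
        self._by_seq: dict[str, list[ReferenceRecord]] = {}
        for rec in records:
            self._by_seq.setdefault(rec.mature_seq, []).append(rec)

    def lookup(self, sequence: str) -> list[ReferenceRecord]:
        return self._by_seq.get(sequence.lower(), [])

    def lookup_rc(self, sequence: str) -> list[ReferenceRecord]:
        return self._by_seq.get(reverse_complement(sequence.lower()), [])

    def find_by_id(self, known_id: str) -> ReferenceRecord:
        for recs in self._by_seq.values():
            for rec in recs:
                if rec.id == known_id:
                    return rec
        raise KeyError(known_id)


def triage_reads(
    reads: Iterable[tuple[str, str]]
) -> dict[str, list[tuple[str, str]]]:
    """Partition ``(id, sequence)`` reads by insert length.

    17-24 nt go to the miRNA track, 25-31 nt to the piRNA track; reads of
    >=32 nt — and those too short to be a miRNA (<=16 nt) — are rejected.
    The partition is exhaustive and depends on length only.
    """
    bins: dict[str, list[tuple[str, str]]] = {
        "mirna_track": [],
        "pirna_track": [],
        "rejected": [],
    }
    for read in reads:
        n = len(read[1])
        if MIRNA_LENGTH_RANGE[0] <= n <= MIRNA_LENGTH_RANGE[1]:
            bins["mirna_track"].append(read)
        elif PIRNA_LENGTH_RANGE[0] <= n <= PIRNA_LENGTH_RANGE[1]:
            bins["pirna_track"].append(read)
        else:
            bins["rejected"].append(read)
    return bins


def quality_filter(
    read_qualities: Sequence[int] | str,
    max_low_fraction: float = 0.10,
    q_threshold: int = 20,
) -> bool:
    """Return True (keep) unless *more than* ``max_low_fraction`` of bases
    have Phred quality below ``q_threshold``.

    Accepts either a list of Phred scores or a Phred+33 quality string.
    The boundary is strict: exactly 10% low-quality bases is kept.
    """
    if isinstance(read_qualities, str):
        scores = [ord(c) - 33 for c in read_qualities]
    else:
        scores = list(read_qualities)
    if not scores:
        raise ValueError("empty quality string")
    low = sum(1 for q in scores if q < q_threshold)
    return low / len(scores) <= max_low_fraction


def _same_locus(a: GenomicInterval, b: GenomicInterval) -> bool:
    # Strand deliberately ignored: an RC read maps to the opposite strand
    # of the known miRNA it came from.
    return a.chrom == b.chrom and a.start == b.start and a.end == b.end


def reannotate_reverse_complements(
    detections: Sequence[DetectedMiRNA], known_index: KnownIndex
) -> list[DetectedMiRNA]:
    """Re-annotate novel candidates that are really known miRNAs.

    A candidate whose forward sequence equals an indexed known mature is
    relabelled known directly.  Otherwise, if its reverse complement equals
    a known mature *at the same genomic location*, it is relabelled to that
    known id.  Counts of candidates relabelled to the same known id are
    merged with any existing known detection of that id.  Total counts are
    conserved.
    """
    out: list[DetectedMiRNA] = []
    merged_into_known: dict[str, int] = {}
    for det in detections:
        if det.status == "known":
            out.append(det)
            continue
        hit = None
        for rec in known_index.lookup(det.sequence):
            hit = rec
            break
        if hit is None:
            for rec in known_index.lookup_rc(det.sequence):
                if _same_locus(rec.interval, det.interval):
                    hit = rec
                    break
        if hit is None:
            out.append(det)
        else:
            merged_into_known[hit.id] = merged_into_known.get(hit.id, 0) + det.count
            logger.debug("re-annotated %s -> known %s", det.label, hit.id)
    if merged_into_known:
        final: list[DetectedMiRNA] = []
        seen: set[str] = set()
        for det in out:
            if det.status == "known" and det.label in merged_into_known:
                extra = merged_into_known.pop(det.label)
                det = replace(det, count=det.count + extra)
                seen.add(det.label)
            final.append(det)
        # relabelled candidates with no pre-existing known detection
        for known_id, count in merged_into_known.items():
            rec = known_index.find_by_id(known_id)
            final.append(
                DetectedMiRNA(
                    sequence=rec.mature_seq,
                    label=known_id,
                    status="known",
                    interval=rec.interval,
                    count=count,
                )
            )
        out = final
    return out


def _mergeable(
    a: DetectedMiRNA,
    b: DetectedMiRNA,
    seed_range: tuple[int, int],
    max_xseed_dist: int = 2,
    max_pos_dist: int = 2,
) -> bool:
    if a.interval.chrom != b.interval.chrom or a.interval.strand != b.interval.strand:
        return False
    if abs(a.interval.start - b.interval.start) > max_pos_dist:
        return False
    da = decompose(a.sequence, seed_range)
    db = decompose(b.sequence, seed_range)
    if da.seed != db.seed:
        return False
    if len(da.xseed) != len(db.xseed):
        return False
    return sum(x != y for x, y in zip(da.xseed, db.xseed)) <= max_xseed_dist


def cluster_novels(
    detections: Sequence[DetectedMiRNA],
    seed_range: tuple[int, int] = DEFAULT_SEED_RANGE,
) -> list[list[DetectedMiRNA]]:
    """Merge novel detections that are the same molecule.

    Two detections merge iff their seed sequences are identical, their
    xseed sequences differ by at most 2 nt (equal length), and their
    genomic start positions differ by at most 2 nt on the same chromosome
    and strand.  Merging is the transitive closure over such pairs.
    Clusters are returned with members ordered by descending count, then
    smallest start, then sequence.
    """
    n = len(detections)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            if _mergeable(detections[i], detections[j], seed_range):
                union(i, j)

    groups: dict[int, list[DetectedMiRNA]] = {}
    for i, det in enumerate(detections):
        groups.setdefault(find(i), []).append(det)

    def member_key(d: DetectedMiRNA):
        return (-d.count, d.interval.start, d.sequence)

    clusters = [sorted(g, key=member_key) for g in groups.values()]
    clusters.sort(key=lambda g: member_key(g[0]))
    return clusters


def cluster_representative(cluster: Sequence[DetectedMiRNA]) -> DetectedMiRNA:
    """Highest-count member; ties by smallest start then sequence."""
    return min(cluster, key=lambda d: (-d.count, d.interval.start, d.sequence))


def assign_functional_names(
    clusters: Sequence[Sequence[DetectedMiRNA]],
    known_records: Sequence[ReferenceRecord],
    seed_range: tuple[int, int] = DEFAULT_SEED_RANGE,
) -> list[AnnotationResult]:
    """Name novel clusters by seed identity against known (then novel) anchors.

    A cluster sharing a known miRNA's seed at a different locus becomes a
    paralogue ``<known>_n``; at the same locus it is the known miRNA
    itself.  A cluster sharing the seed of an earlier unique novel at a
    different locus becomes ``<novel>_n``.  Paralogue indices ``n`` are
    assigned in descending merged-count order (tie: locus), so naming is
    deterministic for any input order.
    """
    known_by_seed: dict[str, ReferenceRecord] = {}
    for rec in sorted(known_records, key=lambda r: r.id):
        seed = decompose(rec.mature_seq, seed_range).seed
        known_by_seed.setdefault(seed, rec)

    ordered = sorted(
        clusters,
        key=lambda c: (
            -sum(d.count for d in c),
            cluster_representative(c).interval.chrom,
            cluster_representative(c).interval.start,
            cluster_representative(c).sequence,
        ),
    )
    results: list[AnnotationResult] = []
    paralogue_counter: dict[str, int] = {}
    novel_by_seed: dict[str, AnnotationResult] = {}
    novel_serial = 0
    for cluster in ordered:
        rep = cluster_representative(cluster)
        merged_count = sum(d.count for d in cluster)
        members = tuple(d.label for d in cluster)
        seed = decompose(rep.sequence, seed_range).seed
        known = known_by_seed.get(seed)
        if known is not None:
            if _same_locus(known.interval, rep.interval):
                relation, anchor, name = "known", known.id, known.id
            else:
                n = paralogue_counter.get(known.id, 0) + 1
                paralogue_counter[known.id] = n
                relation, anchor, name = (
                    "paralogue_of_known",
                    known.id,
                    f"{known.id}_{n}",
                )
        elif seed in novel_by_seed:
            anchor_res = novel_by_seed[seed]
            n = paralogue_counter.get(anchor_res.final_name, 0) + 1
            paralogue_counter[anchor_res.final_name] = n
            relation, anchor = "paralogue_of_novel", anchor_res.final_name
            name = f"{anchor_res.final_name}_{n}"
        else:
            novel_serial += 1
            relation, anchor, name = "unique_novel", "", f"novel-mir-{novel_serial}"
        result = AnnotationResult(
            final_name=name,
            member_ids=members,
            merged_count=merged_count,
            relation=relation,
            anchor_id=anchor,
            sequence=rep.sequence,
            interval=rep.interval,
        )
        if relation == "unique_novel":
            novel_by_seed[seed] = result
        results.append(result)
    return results


def deduplicate_counts(count_table: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows reporting the same mature sequence at multiple loci.

    Input rows are keyed by (name, sequence, locus) with a ``count``
    column.  Duplicated sequences are the same molecule aligned at several
    genomic locations, so they carry the same count and collapse to a
    single row listing all loci; the count is taken once, not summed.
    Unequal counts for the same sequence are inconsistent input: the
    maximum is kept and a warning logged.
    """
    required = {"name", "sequence", "chrom", "start", "end", "strand", "count"}
    missing = required - set(count_table.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    rows = []
    for seq, group in count_table.groupby("sequence", sort=False):
        counts = group["count"].unique()
        if len(counts) > 1:
            logger.warning(
                "sequence %s reported with unequal counts %s; keeping max",
                seq,
                sorted(counts),
            )
        best = group.loc[group["count"].idxmax()]
        loci = [
            f"{r.chrom}:{r.start}-{r.end}({r.strand})"
            for r in group.itertuples(index=False)
        ]
        rows.append(
            {
                "name": best["name"],
                "sequence": seq,
                "count": int(group["count"].max()),
                "loci": ";".join(loci),
                "n_loci": len(loci),
            }
        )
    return pd.DataFrame(rows, columns=["name", "sequence", "count", "loci", "n_loci"])


def rename_novels(
    novel_results: Sequence[AnnotationResult],
    external_id_map: Mapping[str, str] | None = None,
) -> list[AnnotationResult]:
    """Apply final novel-miRNA names, ``*``-suffixed as putative.

    Sequences present in the user-supplied ``external_id_map`` (a mature
    sequence -> identifier table, e.g. annotations from another organism)
    adopt that identifier; the rest are renamed sequentially.  Every final
    name ends with ``*``.
    """
    external_id_map = dict(external_id_map or {})
    ids = list(external_id_map.values())
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate identifiers in external id map")
    renamed: list[AnnotationResult] = []
    serial = 0
    for res in novel_results:
        mapped = external_id_map.get(res.sequence.lower())
        if mapped is not None:
            name = f"{mapped}*"
        else:
            serial += 1
            name = f"novel-mir-{serial}*"
        renamed.append(replace(res, final_name=name))
    return renamed


def detections_from_frame(frame: pd.DataFrame) -> list[DetectedMiRNA]:
    """Build detections from a CSV-shaped table
    (sequence, label, status, chrom, start, end, strand, count)."""
    return [
        DetectedMiRNA(
            sequence=str(r.sequence).lower(),
            label=str(r.label),
            status=str(r.status),
            interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end), str(r.strand)),
            count=int(r.count),
        )
        for r in frame.itertuples(index=False)
    ]


def annotate_detections(
    detections: Sequence[DetectedMiRNA],
    known_records: Sequence[ReferenceRecord],
    external_id_map: Mapping[str, str] | None = None,
    seed_range: tuple[int, int] = DEFAULT_SEED_RANGE,
) -> pd.DataFrame:
    """End-to-end annotation: RC re-annotation, clustering, naming, renaming.

    Returns one row per final molecule with columns
    :data:`ANNOTATION_COLUMNS`.  Unique novels get sequential ``*`` names;
    paralogues keep their anchor-derived ``_n`` labels.
    """
    after_rc = reannotate_reverse_complements(detections, KnownIndex(known_records))
    knowns = [d for d in after_rc if d.status == "known"]
    novels = [d for d in after_rc if d.status == "novel"]
    clusters = cluster_novels(novels, seed_range)
    named = assign_functional_names(clusters, known_records, seed_range)
    uniques = [r for r in named if r.relation == "unique_novel"]
    renamed = {id(r): nr for r, nr in zip(uniques, rename_novels(uniques, external_id_map))}
    rows = []
    for det in knowns:
        rows.append(
            {
                "final_name": det.label,
                "relation": "known",
                "anchor_id": det.label,
                "merged_count": det.count,
                "member_ids": det.label,
                "sequence": det.sequence,
                "chrom": det.interval.chrom,
                "start": det.interval.start,
                "end": det.interval.end,
                "strand": det.interval.strand,
            }
        )
    for res in named:
        final = renamed.get(id(res), res)
        rows.append(
            {
                "final_name": final.final_name,
                "relation": res.relation,
                "anchor_id": res.anchor_id,
                "merged_count": res.merged_count,
                "member_ids": ";".join(res.member_ids),
                "sequence": res.sequence,
                "chrom": res.interval.chrom,
                "start": res.interval.start,
                "end": res.interval.end,
                "strand": res.interval.strand,
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
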