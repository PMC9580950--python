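"""Reference handling and sequence primitives for small-RNA work.

Mature miRNA/piRNA references live in FASTA (sequences) plus a GFF3
companion (genomic coordinates, miRBase-style dialect).  This module reads
those into :class:`ReferenceRecord` objects and houses the sequence
primitives the rest of the package builds on: seed/xseed decomposition of a
mature sequence and Watson-Crick reverse complementation.

Conventions
-----------
* Coordinates are GFF3: 1-based, inclusive, stranded.
* The internal alphabet is DNA in lower case; ``U``/``u`` in input is
  normalised to ``t`` on load.
* The seed region defaults to mature positions 2-8 (1-based), the field
  convention for target recognition; it is configurable everywhere it is
  used.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Sequence, TextIO

import gffutils
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

#: Default 1-based inclusive seed region of a mature miRNA.
DEFAULT_SEED_RANGE: tuple[int, int] = (2, 8)

_COMPLEMENT = str.maketrans("acgtuACGTU", "tgcaaTGCAA")
_VALID_BASES = frozenset("acgtuACGTU")
_VALID_DNA = frozenset("acgt")


class RnaClass(str, Enum):
    """The four read classes used throughout simulation and scoring."""

    KNOWN_MIRNA = "known_miRNA"
    NOVEL_MIRNA = "novel_miRNA"
    KNOWN_PIRNA = "known_piRNA"
    OTHER = "other"


#: GFF3 feature types recognised as mature small-RNA records.
FEATURE_CLASS_MAP = {
    "miRNA": RnaClass.KNOWN_MIRNA,
    "novel_miRNA": RnaClass.NOVEL_MIRNA,
    "piRNA": RnaClass.KNOWN_PIRNA,
}


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded 1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.start < 1:
            raise ValueError(f"1-based coordinates required, got start={self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ReferenceRecord:
    """One mature miRNA/piRNA/novel-miRNA sequence with its locus."""

    id: str
    mature_seq: str
    rna_class: RnaClass
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if not self.mature_seq:
            raise ValueError(f"empty mature sequence for {self.id}")


@dataclass(frozen=True)
class SeedDecomposition:
    """A mature sequence split into its seed and xseed parts.

    ``xseed`` keeps the non-seed nucleotides in their original order, so
    re-inserting ``seed`` at ``seed_range`` reconstructs the input exactly.
    """

    seed: str
    xseed: str
    seed_range: tuple[int, int]

    def reassemble(self) -> str:
        s, _ = self.seed_range
        return self.xseed[: s - 1] + self.seed + self.xseed[s - 1 :]


def normalize_sequence(seq: str) -> str:
    """Lower-case a nucleotide string and map RNA ``u`` to DNA ``t``.

    Raises ``ValueError`` on any non-ACGTU character.
    """
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)!r}")
    return seq.lower().replace("u", "t")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (case preserved, U treated as T)."""
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def decompose(
    mature_seq: str, seed_range: tuple[int, int] = DEFAULT_SEED_RANGE
) -> SeedDecomposition:
    """Split a mature sequence into seed and xseed regions.

    ``seed_range`` is 1-based inclusive and must lie within the sequence.
    """
    start, end = seed_range
    if start < 1 or start > end:
        raise ValueError(f"invalid seed range {seed_range}")
    if end > len(mature_seq):
        raise ValueError(
            f"seed range {seed_range} exceeds sequence length {len(mature_seq)}"
        )
    seed = mature_seq[start - 1 : end]
    xseed = mature_seq[: start - 1] + mature_seq[end:]
    return SeedDecomposition(seed=seed, xseed=xseed, seed_range=seed_range)


def _scan_gff3(path: str | Path) -> None:
    """Pre-validate a GFF3 file so errors can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            if len(stripped.split("\t")) != 9:
                raise ValueError(f"malformed GFF3 line {lineno} in {path}")


def _feature_name(feature: gffutils.Feature) -> str | None:
    for key in ("Name", "ID"):
        values = feature.attributes.get(key)
        if values:
            return values[0]
    return None


def load_reference(
    fasta_path: str | Path, gff3_path: str | Path
) -> list[ReferenceRecord]:
    """Load mature references from a FASTA + GFF3 pair.

    Every FASTA id must resolve (via the ``Name`` or ``ID`` attribute) to a
    GFF3 feature of a recognised type (``miRNA``, ``novel_miRNA``,
    ``piRNA``); other feature types are ignored with a logged count.  The
    feature span must match the sequence length.
    """
    _scan_gff3(gff3_path)
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    features: dict[str, tuple[RnaClass, GenomicInterval]] = {}
    ignored = 0
    for feature in db.all_features():
        rna_class = FEATURE_CLASS_MAP.get(feature.featuretype)
        if rna_class is None:
            ignored += 1
            continue
        name = _feature_name(feature)
        if name is None:
            ignored += 1
            continue
        features[name] = (
            rna_class,
            GenomicInterval(feature.seqid, feature.start, feature.end, feature.strand),
        )
    if ignored:
        logger.info("ignored %d GFF3 features of unrecognised type/name", ignored)

    records: list[ReferenceRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(fasta_path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        if entry.id not in features:
            raise ValueError(f"no GFF3 coordinates found for FASTA id {entry.id!r}")
        rna_class, interval = features[entry.id]
        seq = normalize_sequence(str(entry.seq))
        if interval.length != len(seq):
            raise ValueError(
                f"{entry.id!r}: interval length {interval.length} != "
                f"sequence length {len(seq)}"
            )
        records.append(ReferenceRecord(entry.id, seq, rna_class, interval))
    if not records:
        raise ValueError(f"no records loaded from {fasta_path}")
    return records


def _open_text(path: str | Path, mode: str) -> TextIO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq(
    records: Iterable[tuple[str, str, str]], path: str | Path
) -> int:
    """Write ``(id, sequence, quality)`` triples as FASTQ (gzip by suffix)."""
    n = 0
    with _open_text(path, "w") as out:
        for name, seq, qual in records:
            if len(seq) != len(qual):
                raise ValueError(f"quality length mismatch for read {name!r}")
            out.write(f"@{name}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(id, sequence, quality)`` triples from FASTQ (gzip by suffix)."""
    with _open_text(path, "r") as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq, qual


def write_reference(
    records: Sequence[ReferenceRecord], fasta_path: str | Path, gff3_path: str | Path
) -> None:
    """Write records as a FASTA + GFF3 pair readable by :func:`load_reference`."""
    inverse = {v: k for k, v in FEATURE_CLASS_MAP.items()}
    with open(fasta_path, "w") as fa:
        for rec in records:
            fa.write(f">{rec.id}\n{rec.mature_seq}\n")
    with open(gff3_path, "w") as gff:
        gff.write("##gff-version 3\n")
        for rec in records:
            iv = rec.interval
            gff.write(
                "\t".join(
                    [
                        iv.chrom,
                        "srnakit",
                        inverse[rec.rna_class],
                        str(iv.start),
                        str(iv.end),
                        ".",
                        iv.strand,
                        ".",
                        f"ID={rec.id};Name={rec.id}",
                    ]
                )
                + "\n"
            )
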