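"""Deterministic toy reference sets for offline testing and simulation.

Fabricates unique random mature sequences — miRNA and novel miRNA of
17-24 nt, piRNA of 25-31 nt — laid out at non-overlapping loci across a
configurable number of chromosomes, and writes them as the FASTA + GFF3
pair that :func:`srnakit.reference_io.load_reference` reads.  These
synthetic records stand in for real reference databases so the whole
package runs with no downloads.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .reference_io import (
    GenomicInterval,
    ReferenceRecord,
    RnaClass,
    write_reference,
)

MIRNA_LENGTHS = (17, 24)
PIRNA_LENGTHS = (25, 31)
_GAP = 100  # bp between consecutive fixture loci on a chromosome


def _random_unique_sequences(
    n: int,
    length_range: tuple[int, int],
    rng: np.random.Generator,
    taken: set[str],
) -> list[str]:
    bases = np.array(list("acgt"))
    out: list[str] = []
    while len(out) < n:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(bases[rng.integers(0, 4, size=length)])
        if seq in taken:
            continue
        taken.add(seq)
        out.append(seq)
    return out


def make_fixture_records(
    n_mirna: int = 10,
    n_pirna: int = 5,
    n_novel: int = 3,
    n_chromosomes: int = 2,
    rng_seed: int = 7,
) -> list[ReferenceRecord]:
    """Build an in-memory toy reference set (deterministic under the seed)."""
    if min(n_mirna, n_pirna, n_novel) < 0 or n_chromosomes < 1:
        raise ValueError("counts must be non-negative and n_chromosomes >= 1")
    if n_mirna + n_pirna + n_novel == 0:
        raise ValueError("at least one record must be requested")
    rng = np.random.default_rng(rng_seed)
    taken: set[str] = set()
    plan = [
        ("mir", RnaClass.KNOWN_MIRNA, n_mirna, MIRNA_LENGTHS),
        ("novel-mir", RnaClass.NOVEL_MIRNA, n_novel, MIRNA_LENGTHS),
        ("pir", RnaClass.KNOWN_PIRNA, n_pirna, PIRNA_LENGTHS),
    ]
    cursor = {f"chr{i + 1}": 1 for i in range(n_chromosomes)}
    chrom_names = list(cursor)
    records: list[ReferenceRecord] = []
    serial = 0
    for prefix, rna_class, count, lengths in plan:
        for i, seq in enumerate(
            _random_unique_sequences(count, lengths, rng, taken), start=1
        ):
            chrom = chrom_names[serial % n_chromosomes]
            serial += 1
            start = cursor[chrom]
            end = start + len(seq) - 1
            cursor[chrom] = end + _GAP
            strand = "+" if rng.integers(2) == 0 else "-"
            records.append(
                ReferenceRecord(
                    id=f"toy-{prefix}-{i}",
                    mature_seq=seq,
                    rna_class=rna_class,
                    interval=GenomicInterval(chrom, start, end, strand),
                )
            )
    return records


def make_fixtures(
    fasta_path: str | Path,
    gff3_path: str | Path,
    n_mirna: int = 10,
    n_pirna: int = 5,
    n_novel: int = 3,
    n_chromosomes: int = 2,
    rng_seed: int = 7,
) -> list[ReferenceRecord]:
    """Write a toy FASTA + GFF3 reference pair; returns the records."""
    records = make_fixture_records(n_mirna, n_pirna, n_novel, n_chromosomes, rng_seed)
    write_reference(records, fasta_path, gff3_path)
    return records
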