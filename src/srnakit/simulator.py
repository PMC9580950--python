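"""Synthetic small-RNA-seq read simulation with machine-readable ground truth.

The simulator emits a FASTQ file whose reads are a configured mixture of
unaltered known miRNAs, novel miRNAs and known piRNAs plus "other" decoy
reads derived from real references by >=2-nt alterations in the seed and/or
xseed region.  Decoys act as true negatives: a correct analysis pipeline
must reject them.  Alongside the FASTQ, a ground-truth CSV records every
molecule's identity, class, locus, expression count, CIGAR and — for decoys
— the source reference and alteration mode, so pipeline output can be
scored exactly.

Read allocation is proportional to the number of references per chromosome;
per-molecule expression is drawn from a Poisson or gamma distribution with
a configurable minimum-depth floor.  Reads are padded with adapter and
primer sequence to a fixed read length (default 75 nt).  Identical
configuration and seed produce byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .reference_io import (
    DEFAULT_SEED_RANGE,
    GenomicInterval,
    ReferenceRecord,
    RnaClass,
    decompose,
    reverse_complement,
    write_fastq,
)

#: Illumina TruSeq small-RNA 3' adapter and its RT primer, the common
#: defaults for this library type; both are overridable.
DEFAULT_ADAPTER = "tggaattctcgggtgccaagg"
DEFAULT_PRIMER = "gccttggcacccgagaattcca"

#: Exact order of the ground-truth CSV columns.
TRUTH_COLUMNS = [
    "molecule_name",
    "rna_class",
    "sequence",
    "chrom",
    "start",
    "end",
    "strand",
    "expression_count",
    "cigar",
    "source_id",
    "alteration_mode",
]

_ALT_MODES = ("seed", "xseed", "both")


@dataclass(frozen=True)
class SimConfig:
    """All simulator knobs.

    ``pct_*`` are read-level percentages; the decoy ("other") share is the
    closure ``100 - (pct_known_mirna + pct_novel_mirna + pct_pirna)``.
    ``error_profile`` gives the fractions of decoys altered in the seed
    only, the xseed only, or both; it must sum to 1.  ``distribution`` is
    ``("poisson", mean)`` or ``("gamma", shape, scale)``.
    """

    total_reads: int = 50_000
    pct_known_mirna: float = 40.0
    pct_novel_mirna: float = 20.0
    pct_pirna: float = 20.0
    error_profile: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    min_depth: int = 10
    distribution: tuple = ("poisson", 50.0)
    read_length: int = 75
    adapter_seq: str = DEFAULT_ADAPTER
    primer_seq: str = DEFAULT_PRIMER
    quality_char: str = "I"
    seed_range: tuple[int, int] = DEFAULT_SEED_RANGE
    n_alterations: int = 2
    rc_mode: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        for name in ("pct_known_mirna", "pct_novel_mirna", "pct_pirna"):
            value = getattr(self, name)
            if not 0 <= value <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {value}")
        if self.pct_known_mirna + self.pct_novel_mirna + self.pct_pirna > 100 + 1e-9:
            raise ValueError("class percentages sum to more than 100")
        if abs(sum(self.error_profile) - 1.0) > 1e-9:
            raise ValueError("error_profile fractions must sum to 1")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.n_alterations < 2:
            raise ValueError("n_alterations must be >= 2")
        kind = self.distribution[0]
        params = self.distribution[1:]
        if kind not in ("poisson", "gamma"):
            raise ValueError(f"unknown distribution {kind!r}")
        if kind == "poisson" and len(params) != 1:
            raise ValueError("poisson distribution takes one parameter (mean)")
        if kind == "gamma" and len(params) != 2:
            raise ValueError("gamma distribution takes two parameters (shape, scale)")
        if any(p <= 0 for p in params):
            raise ValueError("distribution parameters must be positive")
        if len(self.quality_char) != 1 or not (33 <= ord(self.quality_char) <= 126):
            raise ValueError("quality_char must be a single printable Phred+33 symbol")

    @property
    def pct_other(self) -> float:
        return 100.0 - (self.pct_known_mirna + self.pct_novel_mirna + self.pct_pirna)

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "distribution" in raw:
            raw["distribution"] = tuple(raw["distribution"])
        if "error_profile" in raw:
            raw["error_profile"] = tuple(raw["error_profile"])
        if "seed_range" in raw:
            raw["seed_range"] = tuple(raw["seed_range"])
        return cls(**raw)


@dataclass
class GroundTruthEntry:
    """One simulated molecule: identity, emitted sequence, locus, count."""

    molecule_name: str
    rna_class: RnaClass
    sequence: str
    interval: GenomicInterval
    expression_count: int
    cigar: str
    source_id: str = ""
    alteration_mode: str = "none"


def largest_remainder(total: int, weights: Sequence[float]) -> list[int]:
    """Apportion ``total`` integer units proportionally to ``weights``.

    Largest-remainder rounding: quotas are floored, then leftover units go
    to the largest fractional remainders (ties broken by position).
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    wsum = float(sum(weights))
    if wsum <= 0:
        raise ValueError("weights must have a positive sum")
    quotas = [total * w / wsum for w in weights]
    floors = [math.floor(q) for q in quotas]
    leftover = total - sum(floors)
    order = sorted(range(len(weights)), key=lambda i: (-(quotas[i] - floors[i]), i))
    for i in order[:leftover]:
        floors[i] += 1
    return floors


def allocate_reads_per_chromosome(
    total_reads: int, reference_set: Sequence[ReferenceRecord]
) -> dict[str, int]:
    """Split a read budget across chromosomes, proportional to the number
    of references on each (largest-remainder rounding)."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if not reference_set:
        raise ValueError("reference set is empty")
    counts: dict[str, int] = {}
    for rec in reference_set:
        counts[rec.interval.chrom] = counts.get(rec.interval.chrom, 0) + 1
    chroms = list(counts)
    budgets = largest_remainder(total_reads, [counts[c] for c in chroms])
    return dict(zip(chroms, budgets))


def draw_expression_profile(
    molecule_count: int,
    distribution: tuple,
    min_depth: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw per-molecule integer read counts with a minimum-depth floor.

    Poisson draws are already integral; gamma draws are rounded half-up
    before flooring at ``min_depth``.
    """
    if molecule_count < 0:
        raise ValueError("molecule_count must be non-negative")
    kind, *params = distribution
    if any(p <= 0 for p in params):
        raise ValueError("distribution parameters must be positive")
    if molecule_count == 0:
        return np.zeros(0, dtype=int)
    if kind == "poisson":
        draws = rng.poisson(params[0], size=molecule_count)
    elif kind == "gamma":
        draws = np.floor(rng.gamma(params[0], params[1], size=molecule_count) + 0.5)
    else:
        raise ValueError(f"unknown distribution {kind!r}")
    return np.maximum(draws.astype(int), min_depth)


def generate_altered_sequence(
    mature_seq: str,
    mode: str,
    rng: np.random.Generator,
    n_alterations: int = 2,
    seed_range: tuple[int, int] = DEFAULT_SEED_RANGE,
) -> str:
    """Derive a decoy from a real sequence by substituting ``n_alterations``
    bases in the seed region, the xseed region, or both.

    Each substituted base is guaranteed to differ from the original, so the
    Hamming distance inside every targeted region is exactly
    ``n_alterations`` and zero elsewhere; length is unchanged.
    """
    if mode not in _ALT_MODES:
        raise ValueError(f"mode must be one of {_ALT_MODES}, got {mode!r}")
    decompose(mature_seq, seed_range)  # bounds check
    start, end = seed_range
    seed_positions = list(range(start - 1, end))
    xseed_positions = [i for i in range(len(mature_seq)) if i not in seed_positions]
    targets: list[int] = []
    for region, positions in (("seed", seed_positions), ("xseed", xseed_positions)):
        if mode in (region, "both"):
            if len(positions) < n_alterations:
                raise ValueError(
                    f"{region} region ({len(positions)} nt) too short for "
                    f"{n_alterations} alterations"
                )
            chosen = rng.choice(len(positions), size=n_alterations, replace=False)
            targets.extend(positions[i] for i in chosen)
    bases = "acgt"
    out = list(mature_seq)
    for pos in targets:
        alternatives = [b for b in bases if b != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def assemble_read(
    mature_seq: str,
    adapter_seq: str = DEFAULT_ADAPTER,
    primer_seq: str = DEFAULT_PRIMER,
    read_length: int = 75,
) -> str:
    """Pad a mature sequence with adapter then primer to ``read_length``.

    The read always starts with the mature sequence verbatim.  If adapter
    plus primer do not reach the target length, the primer (or adapter, or
    ``a`` if both are empty) is repeated as filler; the result is truncated
    to exactly ``read_length``.
    """
    if len(mature_seq) > read_length:
        raise ValueError(
            f"mature sequence ({len(mature_seq)} nt) exceeds read length "
            f"{read_length}"
        )
    filler = primer_seq or adapter_seq or "a"
    read = mature_seq + adapter_seq
    while len(read) < read_length:
        read += filler
    return read[:read_length]


def verify_decoy(
    decoy_seq: str,
    source_seq: str,
    alteration_mode: str,
    seed_range: tuple[int, int] = DEFAULT_SEED_RANGE,
    n_alterations: int = 2,
) -> bool:
    """Check the decoy contract: >= ``n_alterations`` mismatches inside each
    declared region, zero outside, equal length."""
    if len(decoy_seq) != len(source_seq):
        return False
    dec_d = decompose(decoy_seq, seed_range)
    dec_s = decompose(source_seq, seed_range)
    seed_dist = sum(a != b for a, b in zip(dec_d.seed, dec_s.seed))
    xseed_dist = sum(a != b for a, b in zip(dec_d.xseed, dec_s.xseed))
    want_seed = alteration_mode in ("seed", "both")
    want_xseed = alteration_mode in ("xseed", "both")
    if want_seed and seed_dist < n_alterations:
        return False
    if not want_seed and seed_dist != 0:
        return False
    if want_xseed and xseed_dist < n_alterations:
        return False
    if not want_xseed and xseed_dist != 0:
        return False
    return True


def _class_pools(
    reference_set: Sequence[ReferenceRecord],
) -> dict[RnaClass, list[ReferenceRecord]]:
    pools: dict[RnaClass, list[ReferenceRecord]] = {
        RnaClass.KNOWN_MIRNA: [],
        RnaClass.NOVEL_MIRNA: [],
        RnaClass.KNOWN_PIRNA: [],
    }
    for rec in reference_set:
        if rec.rna_class in pools:
            pools[rec.rna_class].append(rec)
    return pools


def _fill_class(
    budget: int,
    refs: Sequence[ReferenceRecord],
    config: SimConfig,
    rng: np.random.Generator,
    *,
    decoy: bool,
    decoy_counter: list[int],
) -> list[GroundTruthEntry]:
    """Emit molecules for one class until its read budget is spent exactly.

    Non-decoy molecules are references sampled without replacement per
    chromosome; decoys are freshly altered copies of (re-sampled) sources.
    Depth draws below the floor are raised to it; a terminal remainder too
    small to honour the floor is folded into the last emitted molecule so
    the budget is met exactly without violating the floor.
    """
    if budget == 0:
        return []
    floor = 1 if decoy else config.min_depth
    by_chrom: dict[str, list[ReferenceRecord]] = {}
    for rec in refs:
        by_chrom.setdefault(rec.interval.chrom, []).append(rec)
    chroms = sorted(by_chrom)
    chrom_budgets = largest_remainder(
        budget, [len(by_chrom[c]) for c in chroms]
    )
    entries: list[GroundTruthEntry] = []
    carry = 0
    for chrom, chrom_budget in zip(chroms, chrom_budgets):
        remaining = chrom_budget + carry
        carry = 0
        pool = list(by_chrom[chrom])
        order = rng.permutation(len(pool))
        i = 0
        while remaining >= floor:
            if decoy:
                src = pool[int(order[i % len(pool)])]
            else:
                if i >= len(pool):
                    break  # chromosome references exhausted
                src = pool[int(order[i])]
            i += 1
            count = int(
                draw_expression_profile(1, config.distribution, floor, rng)[0]
            )
            count = min(count, remaining)
            if decoy:
                mode = _ALT_MODES[
                    int(rng.choice(3, p=np.asarray(config.error_profile)))
                ]
                decoy_counter[0] += 1
                try:
                    seq = generate_altered_sequence(
                        src.mature_seq,
                        mode,
                        rng,
                        config.n_alterations,
                        config.seed_range,
                    )
                except ValueError:
                    # region too short for this mode (e.g. tiny xseed);
                    # fall back to seed-only alteration
                    mode = "seed"
                    seq = generate_altered_sequence(
                        src.mature_seq, mode, rng, config.n_alterations,
                        config.seed_range,
                    )
                entry = GroundTruthEntry(
                    molecule_name=f"other_{decoy_counter[0]}",
                    rna_class=RnaClass.OTHER,
                    sequence=seq,
                    interval=src.interval,
                    expression_count=count,
                    cigar=f"{len(seq)}M",
                    source_id=src.id,
                    alteration_mode=mode,
                )
            else:
                entry = GroundTruthEntry(
                    molecule_name=src.id,
                    rna_class=src.rna_class,
                    sequence=src.mature_seq,
                    interval=src.interval,
                    expression_count=count,
                    cigar=f"{len(src.mature_seq)}M",
                )
            entries.append(entry)
            remaining -= count
        carry = remaining
    if carry:
        if entries:
            entries[-1].expression_count += carry
        else:
            raise ValueError(
                "class budget too small to emit a single molecule at the "
                "configured minimum depth"
            )
    return entries


def simulate(
    config: SimConfig, reference_set: Sequence[ReferenceRecord]
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Run the simulation; return FASTQ triples and the ground-truth table.

    In ``rc_mode`` every reference contributes the reverse complement of its
    mature sequence at a fixed depth of ``config.min_depth`` reads and the
    class percentages are ignored (this reproduces the reverse-complement
    benchmark design).  Otherwise the read budget is split across the four
    classes by largest-remainder rounding of the configured percentages.
    """
    if not reference_set:
        raise ValueError("reference set is empty")
    rng = np.random.default_rng(config.rng_seed)
    truth: list[GroundTruthEntry] = []
    if config.rc_mode:
        for rec in sorted(reference_set, key=lambda r: r.id):
            seq = reverse_complement(rec.mature_seq)
            truth.append(
                GroundTruthEntry(
                    molecule_name=f"{rec.id}_rc",
                    rna_class=rec.rna_class,
                    sequence=seq,
                    interval=rec.interval,
                    expression_count=config.min_depth,
                    cigar=f"{len(seq)}M",
                )
            )
    else:
        pools = _class_pools(reference_set)
        shares = [
            (RnaClass.KNOWN_MIRNA, config.pct_known_mirna),
            (RnaClass.NOVEL_MIRNA, config.pct_novel_mirna),
            (RnaClass.KNOWN_PIRNA, config.pct_pirna),
            (RnaClass.OTHER, config.pct_other),
        ]
        budgets = largest_remainder(config.total_reads, [s for _, s in shares])
        decoy_sources = pools[RnaClass.KNOWN_MIRNA] + pools[RnaClass.KNOWN_PIRNA]
        decoy_counter = [0]
        for (rna_class, share), class_budget in zip(shares, budgets):
            if class_budget == 0:
                continue
            if rna_class is RnaClass.OTHER:
                refs: Sequence[ReferenceRecord] = decoy_sources
            else:
                refs = pools[rna_class]
            if not refs:
                raise ValueError(
                    f"class {rna_class.value} requested at {share}% but no "
                    "suitable references were provided"
                )
            truth.extend(
                _fill_class(
                    class_budget,
                    refs,
                    config,
                    rng,
                    decoy=rna_class is RnaClass.OTHER,
                    decoy_counter=decoy_counter,
                )
            )

    reads: list[tuple[str, str, str]] = []
    for entry in truth:
        read_seq = assemble_read(
            entry.sequence, config.adapter_seq, config.primer_seq, config.read_length
        )
        qual = config.quality_char * len(read_seq)
        for idx in range(1, entry.expression_count + 1):
            reads.append((f"{entry.molecule_name}_{idx}", read_seq, qual))
    return reads, truth_table(truth)


def truth_table(entries: Sequence[GroundTruthEntry]) -> pd.DataFrame:
    """Render ground-truth entries as a DataFrame in the canonical column order."""
    rows = [
        {
            "molecule_name": e.molecule_name,
            "rna_class": e.rna_class.value,
            "sequence": e.sequence,
            "chrom": e.interval.chrom,
            "start": e.interval.start,
            "end": e.interval.end,
            "strand": e.interval.strand,
            "expression_count": e.expression_count,
            "cigar": e.cigar,
            "source_id": e.source_id,
            "alteration_mode": e.alteration_mode,
        }
        for e in entries
    ]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def write_outputs(
    reads: Sequence[tuple[str, str, str]],
    truth: pd.DataFrame,
    fastq_path: str,
    truth_path: str,
) -> None:
    """Write the simulated FASTQ (gzip by suffix) and ground-truth CSV."""
    write_fastq(reads, fastq_path)
    truth.to_csv(truth_path, index=False)
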