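"""Assembly partition statistics: base pairs, scaffold/contig counts, N50.

Scaffolds are grouped into user-supplied partitions (e.g. the eight
chromosome-length scaffolds vs the small and tiny leftovers); per partition
and in total we report summed base pairs, scaffold count, scaffold N50 and,
when the sequences are available, contig count and contig N50 after
splitting scaffolds at runs of N.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import ReferenceGenome

logger = logging.getLogger("tnt1map")


@dataclass
class ScaffoldRecord:
    name: str
    length: int
    partition_label: str

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"scaffold {self.name}: length must be >= 1")


@dataclass
class PartitionStats:
    partition_label: str
    total_bp: int
    n_scaffolds: int
    scaffold_n50: int
    n_contigs: int | None = None
    contig_n50: int | None = None


def compute_n50(lengths: Sequence[int]) -> int:
    """The largest length L such that pieces of length >= L sum to at least
    half of the total length."""
    if not lengths:
        raise ValueError("compute_n50: empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("compute_n50: lengths must be positive")
    total = sum(lengths)
    running = 0
    for x in sorted(lengths, reverse=True):
        running += x
        if 2 * running >= total:
            return x
    raise AssertionError("unreachable")


def contigs_from_scaffolds(
    genome: ReferenceGenome, min_n_run: int = 10
) -> dict[str, list[int]]:
    """Split each scaffold at runs of >= min_n_run consecutive N; returns
    contig lengths per scaffold.  All-N scaffolds yield no contigs (logged)."""
    if min_n_run < 1:
        raise ValueError("min_n_run must be >= 1")
    gap = re.compile("N{%d,}" % min_n_run)
    out: dict[str, list[int]] = {}
    for name, seq in genome.sequences.items():
        pieces = [len(p) for p in gap.split(seq) if p]
        if not pieces:
            logger.warning("contigs_from_scaffolds: scaffold %s is all N", name)
        out[name] = pieces
    return out


def partition_summary(
    records: Iterable[ScaffoldRecord],
    genome: ReferenceGenome | None = None,
    min_scaffold_length: int = 1000,
    min_n_run: int = 10,
) -> pd.DataFrame:
    """Per-partition and grand-total assembly statistics.

    Scaffolds shorter than ``min_scaffold_length`` are excluded before any
    counting.  Contig statistics are computed only when the genome sequences
    are provided.  Partition order follows first appearance in the records.
    """
    records = [r for r in records if r.length >= min_scaffold_length]
    if not records:
        raise ValueError("no scaffolds at or above the minimum length")
    unlabeled = [r.name for r in records if not r.partition_label]
    if unlabeled:
        raise ValueError(f"unlabeled scaffolds: {unlabeled}")
    contig_lengths = contigs_from_scaffolds(genome, min_n_run) if genome is not None else None

    order: list[str] = []
    groups: dict[str, list[ScaffoldRecord]] = {}
    for r in records:
        if r.partition_label not in groups:
            order.append(r.partition_label)
            groups[r.partition_label] = []
        groups[r.partition_label].append(r)

    def stats_for(label: str, members: list[ScaffoldRecord]) -> PartitionStats:
        lengths = [r.length for r in members]
        st = PartitionStats(
            partition_label=label,
            total_bp=sum(lengths),
            n_scaffolds=len(members),
            scaffold_n50=compute_n50(lengths),
        )
        if contig_lengths is not None:
            contigs = [c for r in members for c in contig_lengths.get(r.name, [])]
            st.n_contigs = len(contigs)
            st.contig_n50 = compute_n50(contigs) if contigs else 0
        return st

    rows = [stats_for(label, groups[label]) for label in order]
    rows.append(stats_for("total", records))
    return pd.DataFrame(
        [
            {
                "partition": s.partition_label,
                "total_bp": s.total_bp,
                "n_scaffolds": s.n_scaffolds,
                "scaffold_n50": s.scaffold_n50,
                "n_contigs": s.n_contigs,
                "contig_n50": s.contig_n50,
            }
            for s in rows
        ]
    )


def records_from_genome(
    genome: ReferenceGenome, labels: Mapping[str, str] | None = None, default_label: str = "assembly"
) -> list[ScaffoldRecord]:
    """Build scaffold records from an assembly, with optional name->label map."""
    labels = labels or {}
    return [
        ScaffoldRecord(name=n, length=l, partition_label=labels.get(n, default_label))
        for n, l in genome.lengths.items()
    ]
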