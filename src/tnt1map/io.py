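"""Readers and writers for the standard formats the pipeline touches.

FASTA in/out goes through Biopython, GFF3 parsing through gffutils, and
tabular reports through pandas.  Coordinates are 1-based inclusive
internally (the GFF3 convention); BED output converts to 0-based half-open
at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.iterators import DataIterator

logger = logging.getLogger("tnt1map")

_VALID = set("ACGTN")
# IUPAC ambiguity codes collapse to N; anything else is a parse error.
_IUPAC_TO_N = str.maketrans({c: "N" for c in "RYSWKMBDHVU"})


def normalize_sequence(seq: str, context: str = "") -> str:
    """Uppercase a nucleotide string and collapse IUPAC ambiguity codes to N."""
    s = seq.upper().translate(_IUPAC_TO_N)
    bad = set(s) - _VALID
    if bad:
        where = f" in {context}" if context else ""
        raise ValueError(f"invalid nucleotide characters {sorted(bad)}{where}")
    return s


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class ReferenceGenome:
    """An assembly: an ordered map of sequence name -> A/C/G/T/N string."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"sequence {name!r} is empty")
        self.sequences = {n: normalize_sequence(s, n) for n, s in self.sequences.items()}

    @property
    def names(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.sequences.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences


@dataclass
class GeneModel:
    """A gene span on the reference; coordinates 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval {self.start}-{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Read a FASTA assembly; duplicate names are rejected, order preserved."""
    path = Path(path)
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"{path}: duplicate sequence name {rec.id!r}")
        sequences[rec.id] = str(rec.seq)
    if not sequences:
        raise ValueError(f"{path}: no FASTA records found")
    return ReferenceGenome(sequences)


def write_fasta(path: str | Path, sequences: Mapping[str, str] | Iterable[tuple[str, str]]) -> None:
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    SeqIO.write(records, str(path), "fasta")


def read_gff3(
    path: str | Path,
    feature_type: str = "gene",
    genome: ReferenceGenome | None = None,
) -> list[GeneModel]:
    """Parse GFF3 and return records of ``feature_type`` as gene models.

    When a genome is provided, records on unknown chromosomes or extending
    past the chromosome end are skipped with a logged count.
    """
    genes: list[GeneModel] = []
    seen_ids: set[str] = set()
    n_skipped = 0
    for feat in DataIterator(str(path)):
        if feat.featuretype != feature_type:
            continue
        if feat.end < feat.start:
            raise ValueError(
                f"{path}: feature on {feat.seqid} has end < start "
                f"({feat.start}-{feat.end})"
            )
        gene_id = feat.attributes.get("ID", [None])[0] or f"{feat.seqid}:{feat.start}-{feat.end}"
        if gene_id in seen_ids:
            raise ValueError(f"{path}: duplicate gene ID {gene_id!r}")
        if genome is not None:
            if feat.seqid not in genome or feat.end > genome.lengths[feat.seqid]:
                n_skipped += 1
                continue
        seen_ids.add(gene_id)
        strand = feat.strand if feat.strand in {"+", "-"} else "+"
        genes.append(GeneModel(gene_id, feat.seqid, feat.start, feat.end, strand))
    if n_skipped:
        logger.warning("read_gff3: skipped %d records on unknown/short chromosomes", n_skipped)
    return genes


def write_gff3(path: str | Path, genes: Sequence[GeneModel], source: str = "tnt1map") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def write_bed(path: str | Path, sites: Sequence, genome: ReferenceGenome | None = None) -> None:
    """Write insertion sites as 6-column BED (0-based half-open).

    A site at 1-based position p becomes chromStart = p-1, chromEnd = p.
    """
    with open(path, "w") as fh:
        for s in sites:
            if s.position < 1:
                raise ValueError(f"site {s.fst_id}: position {s.position} < 1")
            if genome is not None:
                if s.chrom not in genome:
                    raise ValueError(f"site {s.fst_id}: unknown chromosome {s.chrom!r}")
                if s.position > genome.lengths[s.chrom]:
                    raise ValueError(
                        f"site {s.fst_id}: position {s.position} beyond end of {s.chrom}"
                    )
            fh.write(f"{s.chrom}\t{s.position - 1}\t{s.position}\t{s.fst_id}\t0\t{s.strand}\n")


def read_sites_bed(path: str | Path) -> list:
    """Read insertion sites back from a BED file written by :func:`write_bed`."""
    from .mapper import InsertionSite  # local import avoids a module cycle

    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end - start != 1:
                raise ValueError(f"{path}: expected single-base intervals, got {line!r}")
            name = parts[3] if len(parts) > 3 else f"{chrom}:{end}"
            strand = parts[5] if len(parts) > 5 else "+"
            line_id = name.split("_")[0] if "_" in name else name
            sites.append(
                InsertionSite(fst_id=name, line_id=line_id, chrom=chrom, position=end, strand=strand)
            )
    return sites


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_synteny_blocks(path: str | Path) -> dict[str, list[str]]:
    """Read a two-column TSV (block_id, gene_id) into block -> member genes."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns (block_id, gene_id)")
    block_col, gene_col = df.columns[0], df.columns[1]
    blocks: dict[str, list[str]] = {}
    for block_id, sub in df.groupby(block_col, sort=False):
        blocks[str(block_id)] = list(sub[gene_col])
    if not blocks:
        raise ValueError(f"{path}: empty synteny block table")
    return blocks
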