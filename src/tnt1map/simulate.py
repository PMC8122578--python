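"""Synthetic Tnt1 mutant-population data with ground truth.

Emulates the statistical structure of a TAIL-PCR FST dataset from an LTR
retrotransposon mutagenesis population: a random genome, non-overlapping
gene models, insertions planted uniformly across lines, and four read
classes —

* SIGNATURE: a Tnt1 end motif near the read start followed by the genomic
  flank at the insertion point (the only informative class),
* NO_SIGNATURE: motif-free flank sequence, mimicking arbitrary-degenerate
  (AD) primer products that never crossed a transposon junction,
* TOO_SHORT: reads under the minimum length,
* INTERNAL_SIGNATURE: a motif stranded in the middle of the read, too far
  from either end to certify a junction.

Read lengths are Normal(363, sd) — the empirical mean FST length — clipped
at the QC minimum; substitution errors are applied outside the planted
motif.  Class labels are content-enforced: after noise, a read that would
no longer satisfy its class definition (e.g. a substitution conjuring a
spurious motif in a contaminant) has the offending occurrence disrupted, so
the generator's labels are exact by construction at any error rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_SIGNATURE_MOTIFS, PipelineConfig
from .io import GeneModel, ReferenceGenome, reverse_complement, write_fasta, write_gff3
from .qc import FSTRecord, find_signature

logger = logging.getLogger("tnt1map")

_BASES = "ACGT"
_CLASSES = ("SIGNATURE", "NO_SIGNATURE", "TOO_SHORT", "INTERNAL_SIGNATURE")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic population.

    Defaults scale the real dataset down to a 1 Mb desk-size genome while
    keeping its ratios: ~18 FSTs per line, mean read length 363 bp, roughly
    45% contaminant reads, legume-like 34% GC.
    """

    n_chroms: int = 8
    chrom_length: int = 125_000
    gc_content: float = 0.34
    n_genes: int = 100
    gene_length: tuple[int, int] = (1_000, 4_000)
    n_lines: int = 100
    insertions_per_line: tuple[int, int] = (10, 30)
    fst_length_mean: float = 363.0
    fst_length_sd: float = 60.0
    frac_no_signature: float = 0.35
    frac_too_short: float = 0.05
    frac_internal_signature: float = 0.05
    substitution_rate: float = 0.01
    revcomp_fraction: float = 0.5
    signature_offset_jitter: int = 0
    signature_motifs: Sequence[str] = DEFAULT_SIGNATURE_MOTIFS
    min_fst_length: int = 50
    end_window: int = 28
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content must be in [0, 1]")
        fracs = (self.frac_no_signature, self.frac_too_short, self.frac_internal_signature)
        if any(not (0.0 <= f <= 1.0) for f in fracs) or sum(fracs) > 1.0:
            raise ValueError("class fractions must lie in [0,1] and sum to <= 1")
        if self.fst_length_mean < self.min_fst_length:
            raise ValueError("fst_length_mean must be >= min_fst_length")
        if not (0 <= self.signature_offset_jitter <= self.end_window - 1):
            raise ValueError("signature_offset_jitter must be in [0, end_window-1]")
        if not (0.0 <= self.substitution_rate < 1.0):
            raise ValueError("substitution_rate must be in [0, 1)")

    @property
    def frac_signature(self) -> float:
        return 1.0 - self.frac_no_signature - self.frac_too_short - self.frac_internal_signature

    @property
    def class_probs(self) -> tuple[float, float, float, float]:
        return (
            self.frac_signature,
            self.frac_no_signature,
            self.frac_too_short,
            self.frac_internal_signature,
        )


@dataclass
class TruthRecord:
    """Ground truth for one emitted FST."""

    line_id: str
    fst_id: str
    chrom: str
    position: int  # 1-based insertion coordinate (flank start)
    strand: str
    fst_class: str


# ---------------------------------------------------------------------------
# genome and genes

def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return np.frombuffer(b"ACGT", dtype=np.uint8)[idx].tobytes().decode()


def generate_genome(config: SimulationConfig, rng: np.random.Generator | None = None) -> ReferenceGenome:
    """I.i.d. random chromosomes with P(G)+P(C) = gc_content, split evenly."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    sequences = {
        f"chr{i + 1}": _random_bases(rng, config.chrom_length, config.gc_content)
        for i in range(config.n_chroms)
    }
    return ReferenceGenome(sequences)


def generate_genes(
    genome: ReferenceGenome, config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[GeneModel]:
    """Place non-overlapping gene spans, chromosomes weighted by length."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 1)
    names = genome.names
    lengths = np.array([genome.lengths[n] for n in names], dtype=float)
    weights = lengths / lengths.sum()
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    genes: list[GeneModel] = []
    lo, hi = config.gene_length
    attempts = 0
    while len(genes) < config.n_genes:
        attempts += 1
        if attempts > 100 * config.n_genes:
            raise RuntimeError("could not place non-overlapping genes; genome too crowded")
        chrom = names[rng.choice(len(names), p=weights)]
        glen = int(rng.integers(lo, hi + 1))
        if glen > genome.lengths[chrom]:
            continue
        start = int(rng.integers(1, genome.lengths[chrom] - glen + 2))
        end = start + glen - 1
        if any(s <= end and start <= e for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"gene{len(genes) + 1:05d}", chrom, start, end, strand))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


# ---------------------------------------------------------------------------
# insertions

def plant_insertions(
    genome: ReferenceGenome, config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[TruthRecord]:
    """Plant insertions uniformly over the genome (chromosome probability
    proportional to length), strands uniform, no duplicate coordinate within
    a line.  Each planted insertion is pre-assigned the class of the read it
    will yield."""
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 2)
    names = genome.names
    lengths = np.array([genome.lengths[n] for n in names], dtype=float)
    weights = lengths / lengths.sum()
    probs = np.array(config.class_probs)
    truth: list[TruthRecord] = []
    counter = 0
    lo, hi = config.insertions_per_line
    for li in range(config.n_lines):
        line_id = f"L{li + 1:04d}"
        n_ins = int(rng.integers(lo, hi + 1))
        if n_ins > int(lengths.sum()):
            raise ValueError("more insertions requested than distinct genome positions")
        taken: set[tuple[str, int]] = set()
        placed = 0
        while placed < n_ins:
            chrom = names[rng.choice(len(names), p=weights)]
            pos = int(rng.integers(1, genome.lengths[chrom] + 1))
            if (chrom, pos) in taken:
                continue
            taken.add((chrom, pos))
            counter += 1
            truth.append(
                TruthRecord(
                    line_id=line_id,
                    fst_id=f"{line_id}_FST{counter:06d}",
                    chrom=chrom,
                    position=pos,
                    strand="+" if rng.random() < 0.5 else "-",
                    fst_class=_CLASSES[rng.choice(4, p=probs)],
                )
            )
            placed += 1
    return truth


# ---------------------------------------------------------------------------
# read emission

def _flank(genome: ReferenceGenome, chrom: str, pos: int, strand: str, length: int) -> str:
    """Genomic flank of up to `length` bp starting at the insertion point and
    running in the strand's direction (reverse-complemented for '-')."""
    seq = genome.sequences[chrom]
    if strand == "+":
        return seq[pos - 1 : pos - 1 + length]
    start = max(0, pos - length)
    return reverse_complement(seq[start:pos])


def _substitute(seq: list[str], protected: set[int], rate: float, rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        if int(i) in protected:
            continue
        old = seq[int(i)]
        choices = [b for b in _BASES if b != old]
        seq[int(i)] = choices[int(rng.integers(3))]


def _disrupt_matches(
    seq: list[str],
    protected: set[int],
    config: SimulationConfig,
    rng: np.random.Generator,
    offending,
) -> bool:
    """Mutate one base inside each offending motif occurrence until none
    remain.  Returns False if every position of some occurrence is protected."""
    for _ in range(50):
        matches = [m for m in find_signature("".join(seq), config.signature_motifs, True, config.end_window) if offending(m)]
        if not matches:
            return True
        m = matches[0]
        span = [
            i
            for i in range(m.start_offset, m.start_offset + len(m.motif))
            if i not in protected
        ]
        if not span:
            return False
        i = span[int(rng.integers(len(span)))]
        old = seq[i]
        choices = [b for b in _BASES if b != old]
        seq[i] = choices[int(rng.integers(3))]
    return False


def emit_fsts(
    genome: ReferenceGenome,
    truth: Sequence[TruthRecord],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[FSTRecord], list[TruthRecord]]:
    """Emit one read per truth record; returns (reads, truth actually emitted).

    Records whose flank is fully truncated by a chromosome end (no room for
    a minimum-length read) are skipped and logged.
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed + 3)
    reads: list[FSTRecord] = []
    emitted: list[TruthRecord] = []
    n_skipped = 0
    for rec in truth:
        out = _emit_one(genome, rec, config, rng)
        if out is None:
            n_skipped += 1
            continue
        reads.append(FSTRecord(fst_id=rec.fst_id, sequence=out, line_id=rec.line_id))
        emitted.append(rec)
    if n_skipped:
        logger.info("emit_fsts: skipped %d reads truncated at chromosome ends", n_skipped)
    return reads, emitted


def _draw_length(config: SimulationConfig, rng: np.random.Generator) -> int:
    raw = int(round(rng.normal(config.fst_length_mean, config.fst_length_sd)))
    return max(config.min_fst_length, raw)


def _emit_one(
    genome: ReferenceGenome, rec: TruthRecord, config: SimulationConfig, rng: np.random.Generator
) -> str | None:
    motifs = config.signature_motifs
    if rec.fst_class == "TOO_SHORT":
        length = int(rng.integers(15, config.min_fst_length))
        seq = list(_flank(genome, rec.chrom, rec.position, rec.strand, length))
        if not seq:
            return None
        _substitute(seq, set(), config.substitution_rate, rng)
    elif rec.fst_class == "NO_SIGNATURE":
        length = _draw_length(config, rng)
        seq = list(_flank(genome, rec.chrom, rec.position, rec.strand, length))
        if len(seq) < config.min_fst_length:
            return None
        _substitute(seq, set(), config.substitution_rate, rng)
        if not _disrupt_matches(seq, set(), config, rng, lambda m: True):
            return None
    elif rec.fst_class == "SIGNATURE":
        motif = motifs[int(rng.integers(len(motifs)))]
        length = _draw_length(config, rng)
        jitter = (
            int(rng.integers(0, config.signature_offset_jitter + 1))
            if config.signature_offset_jitter
            else 0
        )
        flank_len = length - jitter - len(motif)
        flank = _flank(genome, rec.chrom, rec.position, rec.strand, flank_len)
        if jitter + len(motif) + len(flank) < config.min_fst_length:
            return None  # flank truncated at a chromosome end
        prefix = _random_bases(rng, jitter, config.gc_content) if jitter else ""
        seq = list(prefix + motif + flank)
        protected = set(range(jitter, jitter + len(motif)))
        _substitute(seq, protected, config.substitution_rate, rng)
    else:  # INTERNAL_SIGNATURE
        motif = motifs[int(rng.integers(len(motifs)))]
        min_len = 2 * config.end_window + len(motif) + 4
        length = max(_draw_length(config, rng), min_len)
        base = _flank(genome, rec.chrom, rec.position, rec.strand, length)
        if len(base) < min_len:
            return None
        length = len(base)
        offset = int(rng.integers(config.end_window, length - config.end_window - len(motif) + 1))
        seq = list(base)
        seq[offset : offset + len(motif)] = list(motif)
        protected = set(range(offset, offset + len(motif)))
        _substitute(seq, protected, config.substitution_rate, rng)
        # no occurrence may sit end-proximally, or the read would pass QC
        if not _disrupt_matches(
            seq, protected, config, rng, lambda m: m.which_end in ("head", "tail")
        ):
            return None
    read = "".join(seq)
    if rng.random() < config.revcomp_fraction:
        read = reverse_complement(read)
    return read


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: ReferenceGenome
    genes: list[GeneModel]
    truth: list[TruthRecord]
    reads: list[FSTRecord]

    @property
    def truth_df(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "line_id": t.line_id,
                    "fst_id": t.fst_id,
                    "chrom": t.chrom,
                    "position": t.position,
                    "strand": t.strand,
                    "class": t.fst_class,
                }
                for t in self.truth
            ]
        )

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fasta",
            "genes": out / "genes.gff3",
            "reads": out / "reads.fasta",
            "truth": out / "truth.tsv",
        }
        write_fasta(paths["genome"], self.genome.sequences)
        write_gff3(paths["genes"], self.genes)
        write_fasta(paths["reads"], [(r.fst_id, r.sequence) for r in self.reads])
        self.truth_df.to_csv(paths["truth"], sep="\t", index=False)
        return paths


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate genome, genes, planted insertions and reads from one seed."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.rng_seed)
    genome = generate_genome(config, rng)
    genes = generate_genes(genome, config, rng)
    truth = plant_insertions(genome, config, rng)
    reads, emitted = emit_fsts(genome, truth, config, rng)
    logger.info(
        "simulate: %d chroms x %d bp, %d genes, %d insertions, %d reads emitted",
        config.n_chroms,
        config.chrom_length,
        len(genes),
        len(truth),
        len(reads),
    )
    return SimulatedDataset(config=config, genome=genome, genes=genes, truth=emitted, reads=reads)


def toy_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The bundled <= 1 Mb toy preset used by tests and the CLI."""
    kwargs = dict(rng_seed=seed)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
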