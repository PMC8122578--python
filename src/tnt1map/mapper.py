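"""Seed-and-extend mapping of high-confidence FSTs onto the reference.

The aligner is deliberately minimal: exact k-mer seeds from a hash index,
merged per diagonal, each extended ungapped in both directions under an
x-drop rule, scored with match/mismatch, and converted to an E-value with
the ungapped Karlin-Altschul formula E = K*m*n*exp(-lambda*S).  FSTs are
near-identical to their source locus, so ungapped extension plus the >= 90%
identity and E <= 1e-5 thresholds recover what a BLASTN search would.

The insertion coordinate is called from the signature-bearing read end: the
junction base (the first genomic base adjacent to the Tnt1 motif) is
projected through the hit's diagonal, so a substitution right at the
junction does not shift the call even when it is trimmed from the local
alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from functools import lru_cache
from math import exp, log
from typing import Iterable, Mapping, Sequence

from scipy.optimize import brentq

from .config import PipelineConfig
from .io import ReferenceGenome, reverse_complement
from .qc import FSTRecord, QCOutcome
from .rounding import round_half_up

logger = logging.getLogger("tnt1map")


# ---------------------------------------------------------------------------
# reference index

@dataclass
class ReferenceIndex:
    """Hash index of every N-free k-mer in the reference."""

    k: int
    positions: dict[str, list[tuple[str, int]]]  # k-mer -> [(chrom, 0-based offset)]

    @property
    def n_positions(self) -> int:
        return sum(len(v) for v in self.positions.values())


def build_index(genome: ReferenceGenome, k: int = 15) -> ReferenceIndex:
    """Index all N-free k-mers of the genome (forward strand only; reads are
    queried in both orientations instead)."""
    if k < 1:
        raise ValueError("seed length k must be >= 1")
    if all(length < k for length in genome.lengths.values()):
        raise ValueError(f"k={k} exceeds the length of every chromosome")
    positions: dict[str, list[tuple[str, int]]] = {}
    for chrom, seq in genome.sequences.items():
        # positions of N bases, to skip windows overlapping them cheaply
        next_n = _next_n_table(seq)
        i, last = 0, len(seq) - k
        while i <= last:
            nn = next_n[i]
            if nn < i + k:  # window overlaps an N: jump past it
                i = nn + 1
                continue
            positions.setdefault(seq[i : i + k], []).append((chrom, i))
            i += 1
    return ReferenceIndex(k=k, positions=positions)


def _next_n_table(seq: str) -> list[int]:
    """next_n[i] = smallest j >= i with seq[j] == 'N', or len(seq)."""
    n = len(seq)
    out = [n] * (n + 1)
    nxt = n
    for i in range(n - 1, -1, -1):
        if seq[i] == "N":
            nxt = i
        out[i] = nxt
    return out


# ---------------------------------------------------------------------------
# Karlin-Altschul statistics

@lru_cache(maxsize=None)
def karlin_lambda(
    match: int, mismatch: int, base_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for lambda > 0 by root
    finding (Brent bracketing, which refines an initial bisection bracket).

    Requires a negative expected score, otherwise lambda is undefined.
    """
    p = base_freqs
    p_match = sum(x * x for x in p)
    p_mis = 1.0 - p_match
    expected = p_match * match + p_mis * mismatch
    if expected >= 0:
        raise ValueError("expected score per aligned pair must be negative")

    def f(lam: float) -> float:
        return p_match * exp(lam * match) + p_mis * exp(lam * mismatch) - 1.0

    lo, hi = 1e-9, 2.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e4:
            raise RuntimeError("failed to bracket lambda")
    return float(brentq(f, lo, hi, xtol=1e-12))


def score_to_evalue(
    score: float,
    read_len: int,
    genome_len: int,
    config: PipelineConfig | None = None,
    base_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25),
) -> float:
    """Ungapped Karlin-Altschul E-value: E = K * m * n * exp(-lambda * S).

    m is the read length and n the total (concatenated) genome length; no
    edge-effect correction is applied.
    """
    config = config or PipelineConfig()
    lam = karlin_lambda(config.match_score, config.mismatch_score, base_freqs)
    return config.evalue_k * read_len * genome_len * exp(-lam * score)


# ---------------------------------------------------------------------------
# alignment

@dataclass
class AlignmentHit:
    """One ungapped local alignment of a read to the reference.

    ref_start/ref_end and read_start/read_end are 1-based inclusive;
    read coordinates always refer to the read as given (not its reverse
    complement), so for minus-strand hits read_start pairs with ref_end.
    """

    fst_id: str
    chrom: str
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    strand: str
    matches: int
    aln_len: int
    score: int
    evalue: float

    @property
    def identity(self) -> float:
        return self.matches / self.aln_len


def _extend_ungapped(
    q: str, s: str, i: int, j: int, k: int, match: int, mismatch: int, xdrop: int
) -> tuple[int, int, int]:
    """Extend an exact k-mer seed at read offset i / ref offset j in both
    directions; return (read_start0, read_end0, score) of the best-scoring
    segment containing the seed."""
    # leftwards
    best_l, run, best_steps_l = 0, 0, 0
    bi, bj, steps = i - 1, j - 1, 0
    while bi >= 0 and bj >= 0:
        a, b = q[bi], s[bj]
        run += match if (a == b and a != "N") else mismatch
        steps += 1
        if run > best_l:
            best_l, best_steps_l = run, steps
        elif best_l - run > xdrop:
            break
        bi -= 1
        bj -= 1
    # rightwards
    best_r, run, best_steps_r = 0, 0, 0
    fi, fj, steps = i + k, j + k, 0
    lq, ls = len(q), len(s)
    while fi < lq and fj < ls:
        a, b = q[fi], s[fj]
        run += match if (a == b and a != "N") else mismatch
        steps += 1
        if run > best_r:
            best_r, best_steps_r = run, steps
        elif best_r - run > xdrop:
            break
        fi += 1
        fj += 1
    read_start0 = i - best_steps_l
    read_end0 = i + k - 1 + best_steps_r
    return read_start0, read_end0, k * match + best_l + best_r


def align_read(
    read: str | FSTRecord,
    index: ReferenceIndex,
    genome: ReferenceGenome,
    config: PipelineConfig | None = None,
    fst_id: str | None = None,
) -> list[AlignmentHit]:
    """Seed-and-extend both orientations of a read against the reference.

    Returns hits passing the identity and E-value thresholds, deduplicated
    by (chrom, ref interval, strand) keeping the best score.
    """
    config = config or PipelineConfig()
    if isinstance(read, FSTRecord):
        fst_id = fst_id or read.fst_id
        read = read.sequence
    fst_id = fst_id or "read"
    read = read.upper()
    L = len(read)
    k = index.k
    if L < k:
        raise ValueError(f"read {fst_id} shorter than seed length k={k}")
    match, mismatch = config.match_score, config.mismatch_score
    genome_len = genome.total_length
    kept: dict[tuple[str, int, int, str], AlignmentHit] = {}
    for strand, q in (("+", read), ("-", reverse_complement(read))):
        covered: dict[tuple[str, int], int] = {}  # (chrom, diagonal) -> max read_end0 seen
        for i in range(L - k + 1):
            kmer = q[i : i + k]
            if "N" in kmer:
                continue
            for chrom, j in index.positions.get(kmer, ()):
                diag = j - i
                if covered.get((chrom, diag), -1) >= i + k - 1:
                    continue  # this seed lies inside an already-extended segment
                s = genome.sequences[chrom]
                rs0, re0, score = _extend_ungapped(q, s, i, j, k, match, mismatch, config.xdrop)
                covered[(chrom, diag)] = max(covered.get((chrom, diag), -1), re0)
                aln_len = re0 - rs0 + 1
                n_match = sum(
                    1
                    for x in range(rs0, re0 + 1)
                    if q[x] == s[x + diag] and q[x] != "N"
                )
                identity = n_match / aln_len
                if config.identity_strict:
                    if identity <= config.min_identity:
                        continue
                elif identity + 1e-12 < config.min_identity:
                    continue
                evalue = score_to_evalue(score, L, genome_len, config)
                if evalue > config.max_evalue:
                    continue
                ref_start, ref_end = rs0 + diag + 1, re0 + diag + 1
                if strand == "+":
                    r1, r2 = rs0 + 1, re0 + 1
                else:
                    r1, r2 = L - re0, L - rs0
                key = (chrom, ref_start, ref_end, strand)
                prev = kept.get(key)
                if prev is None or score > prev.score:
                    kept[key] = AlignmentHit(
                        fst_id=fst_id,
                        chrom=chrom,
                        ref_start=ref_start,
                        ref_end=ref_end,
                        read_start=r1,
                        read_end=r2,
                        strand=strand,
                        matches=n_match,
                        aln_len=aln_len,
                        score=score,
                        evalue=evalue,
                    )
    return list(kept.values())


def best_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit | None:
    """Pick the best hit: max score, then lower E-value, longer alignment,
    lexicographically smaller chromosome, smaller ref_start."""
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.score, h.evalue, -h.aln_len, h.chrom, h.ref_start))


# ---------------------------------------------------------------------------
# insertion-site calling

@dataclass
class InsertionSite:
    """The 1-based genomic coordinate called for one mapped FST."""

    fst_id: str
    line_id: str
    chrom: str
    position: int
    strand: str
    hit: AlignmentHit | None = None


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def call_insertion_site(
    hit: AlignmentHit,
    qc_outcome: QCOutcome,
    genome: ReferenceGenome | None = None,
    line_id: str | None = None,
) -> InsertionSite:
    """Call the insertion coordinate from a best hit and its QC outcome.

    The junction base is the read base immediately adjacent to the signature
    motif (after it for head matches, before it for tail matches); its
    reference coordinate is obtained by projecting along the hit's diagonal,
    then clamping to the chromosome.  The site strand is the hit strand for
    head-signature reads and the opposite strand for tail-signature reads
    (a tail signature means the read was sequenced off the other Tnt1 end).
    """
    if hit.fst_id != qc_outcome.fst_id:
        raise ValueError(
            f"hit/QC mismatch: {hit.fst_id!r} vs {qc_outcome.fst_id!r}"
        )
    m = qc_outcome.best_match
    if m is None or m.which_end not in ("head", "tail"):
        raise ValueError(f"FST {hit.fst_id}: QC outcome carries no end-proximal signature")
    read_len = m.start_offset + len(m.motif) + m.end_distance
    if m.which_end == "head":
        junction = m.start_offset + len(m.motif) + 1  # first base after the motif
    else:
        junction = read_len - m.end_distance - len(m.motif)  # last base before the motif
    junction = min(max(junction, 1), read_len)
    if hit.strand == "+":
        pos = hit.ref_start + (junction - hit.read_start)
    else:
        pos = hit.ref_end - (junction - hit.read_start)
    pos = max(pos, 1)
    if genome is not None:
        pos = min(pos, genome.lengths[hit.chrom])
    strand = hit.strand if m.which_end == "head" else _flip(hit.strand)
    if line_id is None:
        line_id = hit.fst_id.split("_")[0] if "_" in hit.fst_id else hit.fst_id
    return InsertionSite(
        fst_id=hit.fst_id,
        line_id=line_id,
        chrom=hit.chrom,
        position=pos,
        strand=strand,
        hit=hit,
    )


# ---------------------------------------------------------------------------
# batch mapping

@dataclass
class MappingSummary:
    n_input: int
    n_mapped: int
    n_unmapped: int
    mapped_percent: int  # integer percent, round half up
    per_chrom: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_counts(
        cls, n_input: int, n_mapped: int, per_chrom: Mapping[str, int] | None = None
    ) -> "MappingSummary":
        if n_input == 0:
            logger.warning("mapping summary over zero input reads; percent reported as 0")
            pct = 0
        else:
            pct = int(round_half_up(n_mapped / n_input * 100.0, 0))
        return cls(
            n_input=n_input,
            n_mapped=n_mapped,
            n_unmapped=n_input - n_mapped,
            mapped_percent=pct,
            per_chrom=dict(per_chrom or {}),
        )


def map_batch(
    records: Iterable[FSTRecord],
    genome: ReferenceGenome,
    config: PipelineConfig | None = None,
    qc_outcomes: Mapping[str, QCOutcome] | None = None,
    index: ReferenceIndex | None = None,
) -> tuple[list[InsertionSite], MappingSummary]:
    """Map QC-passed FSTs and call one insertion site per mapped read.

    ``qc_outcomes`` must carry the signature match for every record (it is
    how the signature-bearing end is known); records without one are counted
    unmapped.
    """
    config = config or PipelineConfig()
    if index is None:
        index = build_index(genome, config.seed_k)
    records = list(records)
    sites: list[InsertionSite] = []
    n_unmapped = 0
    per_chrom: dict[str, int] = {}
    for rec in records:
        qc = (qc_outcomes or {}).get(rec.fst_id)
        if qc is None or qc.best_match is None or len(rec.sequence) < index.k:
            n_unmapped += 1
            continue
        hits = align_read(rec, index, genome, config)
        bh = best_hit(hits)
        if bh is None:
            n_unmapped += 1
            continue
        site = call_insertion_site(bh, qc, genome, line_id=rec.line_id)
        sites.append(site)
        per_chrom[site.chrom] = per_chrom.get(site.chrom, 0) + 1
    summary = MappingSummary.from_counts(len(records), len(sites), per_chrom)
    logger.info(
        "insertion_mapper: %d in, %d mapped (%d%%), %d unmapped",
        summary.n_input,
        summary.n_mapped,
        summary.mapped_percent,
        summary.n_unmapped,
    )
    return sites, summary


def deduplicate_sites(sites: Sequence[InsertionSite]) -> list[InsertionSite]:
    """Collapse FST-level sites to unique (line_id, chrom, position) records."""
    seen: set[tuple[str, str, int]] = set()
    out: list[InsertionSite] = []
    for s in sites:
        key = (s.line_id, s.chrom, s.position)
        if key not in seen:
            seen.add(key)
            out.append(s)
    return out


def hits_to_dataframe(hits: Sequence[AlignmentHit]):
    """BLAST-tabular-like hits table."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "fst_id": h.fst_id,
                "chrom": h.chrom,
                "identity": round(h.identity, 4),
                "aln_len": h.aln_len,
                "matches": h.matches,
                "read_start": h.read_start,
                "read_end": h.read_end,
                "ref_start": h.ref_start,
                "ref_end": h.ref_end,
                "strand": h.strand,
                "score": h.score,
                "evalue": h.evalue,
            }
            for h in hits
        ]
    )
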