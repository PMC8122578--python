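"""Signature-based quality control of flanking sequence tags (FSTs).

An FST is a TAIL-PCR read spanning the junction between a Tnt1 end and the
host genome.  A read is kept only when (1) it is at least ``min_fst_length``
bp long and (2) one of the Tnt1 end motifs (CCCAACA, CATCATCA, TGATGATGTCC)
occurs within ``end_window`` bp of the read start or end.  Reads failing
either rule are contaminants — typically arbitrary-degenerate (AD) primer
products that never crossed a transposon junction.

Each rejected read receives exactly one reason, applied in the fixed
precedence TOO_SHORT > NO_SIGNATURE > SIGNATURE_INTERNAL, so the batch
summary is a clean funnel: total = passed + sum of reject reasons.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .config import PipelineConfig
from .io import reverse_complement

logger = logging.getLogger("tnt1map")


@dataclass
class FSTRecord:
    """One flanking-sequence-tag read.

    ``line_id`` is parsed from the id prefix before the first underscore
    when present (FST ids are conventionally ``<line>_<tag>``), otherwise it
    equals the full id.
    """

    fst_id: str
    sequence: str
    line_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"FST {self.fst_id}: empty sequence")
        self.sequence = self.sequence.upper()
        if not self.line_id:
            self.line_id = self.fst_id.split("_")[0] if "_" in self.fst_id else self.fst_id

    def __len__(self) -> int:
        return len(self.sequence)


class RejectReason(str, Enum):
    PASS = "PASS"
    TOO_SHORT = "TOO_SHORT"
    NO_SIGNATURE = "NO_SIGNATURE"
    SIGNATURE_INTERNAL = "SIGNATURE_INTERNAL"


@dataclass
class SignatureMatch:
    """An exact occurrence of a Tnt1 end motif (or its reverse complement)."""

    motif: str
    strand_of_motif: str  # "forward" | "revcomp"
    start_offset: int  # 0-based offset of the first motif base in the read
    end_distance: int  # bp from the last motif base to the last read base
    which_end: str  # "head" | "tail" | "internal"

    @property
    def end_proximity(self) -> int:
        """Distance to the read end the match is assigned to."""
        return self.start_offset if self.which_end == "head" else self.end_distance


@dataclass
class QCOutcome:
    fst_id: str
    passed: bool
    reason: RejectReason
    best_match: SignatureMatch | None = None


def _classify_end(start_offset: int, end_distance: int, end_window: int) -> str:
    # head wins when a short read puts the motif within both windows
    if start_offset <= end_window - 1:
        return "head"
    if end_distance <= end_window - 1:
        return "tail"
    return "internal"


def find_signature(
    sequence: str,
    motifs: Sequence[str] | None = None,
    search_reverse_complement: bool = True,
    end_window: int = 28,
) -> list[SignatureMatch]:
    """Report every exact occurrence of each motif in a read.

    When reverse-complement search is on, occurrences of the motif's reverse
    complement are reported too (TAIL-PCR read orientation is arbitrary).
    N never matches, which exact string search gives for free since motifs
    are N-free.  Matches are sorted by start offset.
    """
    if motifs is None:
        motifs = PipelineConfig().signature_motifs
    seq = sequence.upper()
    patterns: list[tuple[str, str, str]] = [(m.upper(), m.upper(), "forward") for m in motifs]
    if search_reverse_complement:
        for m in motifs:
            rc = reverse_complement(m.upper())
            patterns.append((rc, m.upper(), "revcomp"))
    matches: list[SignatureMatch] = []
    seen: set[tuple[int, str, str]] = set()
    for pattern, motif, strand in patterns:
        start = seq.find(pattern)
        while start != -1:
            key = (start, motif, strand)
            if key not in seen:
                seen.add(key)
                end_distance = len(seq) - (start + len(pattern))
                matches.append(
                    SignatureMatch(
                        motif=motif,
                        strand_of_motif=strand,
                        start_offset=start,
                        end_distance=end_distance,
                        which_end=_classify_end(start, end_distance, end_window),
                    )
                )
            start = seq.find(pattern, start + 1)
    matches.sort(key=lambda m: (m.start_offset, m.motif, m.strand_of_motif))
    return matches


def classify_fst(record: FSTRecord, config: PipelineConfig | None = None) -> QCOutcome:
    """Apply the three reject rules in fixed precedence and pick a best match.

    The best match among end-proximal ones is the match closest to its read
    end; ties prefer the longer motif (the motifs nest: TGATGATGTCC starts
    with the reverse complement of CATCATCA, and the junction must be called
    after the most specific match), then head over tail, then the smaller
    start offset.
    """
    config = config or PipelineConfig()
    if not record.sequence:
        raise ValueError(f"FST {record.fst_id}: empty sequence")
    if len(record.sequence) < config.min_fst_length:
        return QCOutcome(record.fst_id, False, RejectReason.TOO_SHORT)
    matches = find_signature(
        record.sequence,
        config.signature_motifs,
        config.search_reverse_complement,
        config.end_window,
    )
    if not matches:
        return QCOutcome(record.fst_id, False, RejectReason.NO_SIGNATURE)
    end_proximal = [m for m in matches if m.which_end in ("head", "tail")]
    if not end_proximal:
        return QCOutcome(record.fst_id, False, RejectReason.SIGNATURE_INTERNAL)
    best = min(
        end_proximal,
        key=lambda m: (
            m.end_proximity,
            -len(m.motif),
            0 if m.which_end == "head" else 1,
            m.start_offset,
        ),
    )
    return QCOutcome(record.fst_id, True, RejectReason.PASS, best)


@dataclass
class FunnelSummary:
    """Counts for one filtering stage: total in, passed, and reject reasons."""

    total: int
    n_pass: int
    reject_reasons: dict[str, int] = field(default_factory=dict)

    @property
    def n_rejected(self) -> int:
        return self.total - self.n_pass

    def validate(self) -> None:
        if self.n_pass + sum(self.reject_reasons.values()) != self.total:
            raise ValueError("funnel counts do not sum to total")


def filter_batch(
    records: Iterable[FSTRecord], config: PipelineConfig | None = None
) -> tuple[list[FSTRecord], list[FSTRecord], FunnelSummary, dict[str, QCOutcome]]:
    """Classify a batch; returns (pass, fail, funnel summary, outcome by id)."""
    config = config or PipelineConfig()
    records = list(records)
    ids = [r.fst_id for r in records]
    if len(set(ids)) != len(ids):
        dup = next(i for i, c in Counter(ids).items() if c > 1)
        raise ValueError(f"duplicate fst_id {dup!r} in batch")
    passed: list[FSTRecord] = []
    failed: list[FSTRecord] = []
    reasons: Counter[str] = Counter()
    outcomes: dict[str, QCOutcome] = {}
    for rec in records:
        out = classify_fst(rec, config)
        outcomes[rec.fst_id] = out
        if out.passed:
            passed.append(rec)
        else:
            failed.append(rec)
            reasons[out.reason.value] += 1
    summary = FunnelSummary(total=len(records), n_pass=len(passed), reject_reasons=dict(reasons))
    summary.validate()
    logger.info(
        "fst_qc: %d in, %d pass, %d rejected %s",
        summary.total,
        summary.n_pass,
        summary.n_rejected,
        dict(reasons),
    )
    return passed, failed, summary, outcomes
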