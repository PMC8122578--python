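"""Pipeline configuration.

A single dataclass carries every tunable of the FST pipeline: the quality
filters (minimum read length, signature motifs, end-proximity window), the
alignment thresholds (identity, E-value), the aligner's scoring scheme, and
the landscape bin width.  Defaults follow the published Tnt1 FST protocol:
reads shorter than 50 bp are discarded, a signature motif must start within
28 bp of a read end, hits need >= 90% identity and E <= 1e-5, and the
insertion landscape is binned in 500 kb windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Sequence

#: Tnt1 LTR end motifs whose presence near a read end certifies a genuine
#: transposon-genome junction.
DEFAULT_SIGNATURE_MOTIFS = ("CCCAACA", "CATCATCA", "TGATGATGTCC")

_MOTIF_ALPHABET = set("ACGT")


@dataclass
class PipelineConfig:
    """Tunable parameters of the FST filtering / mapping / landscape pipeline."""

    min_fst_length: int = 50
    end_window: int = 28
    signature_motifs: Sequence[str] = DEFAULT_SIGNATURE_MOTIFS
    search_reverse_complement: bool = True
    min_identity: float = 0.90
    identity_strict: bool = False  # if True, require identity > min_identity
    max_evalue: float = 1.00e-5
    bin_width: int = 500_000
    seed_k: int = 15
    match_score: int = 1
    mismatch_score: int = -2
    xdrop: int = 20
    evalue_k: float = 0.3  # Karlin-Altschul K; lambda is solved numerically
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.min_fst_length <= 0:
            raise ValueError("min_fst_length must be > 0")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.end_window <= 0:
            raise ValueError("end_window must be > 0")
        if self.seed_k < 8:
            raise ValueError("seed_k must be >= 8")
        if self.match_score <= 0 or self.mismatch_score >= 0:
            raise ValueError("match_score must be positive and mismatch_score negative")
        motifs = tuple(m.upper() for m in self.signature_motifs)
        if not motifs:
            raise ValueError("signature_motifs must be non-empty")
        for m in motifs:
            if not m or not set(m) <= _MOTIF_ALPHABET:
                raise ValueError(f"signature motif {m!r} must be non-empty over A,C,G,T")
        self.signature_motifs = motifs

    def replace(self, **kwargs) -> "PipelineConfig":
        """Return a copy with the given fields overridden."""
        current = {f.name: getattr(self, f.name) for f in fields(self)}
        current.update(kwargs)
        return PipelineConfig(**current)


def config_from_mapping(mapping: dict) -> PipelineConfig:
    """Build a config from a flat key->value mapping (e.g. parsed YAML).

    Unknown keys raise, so typos in config files fail loudly.
    """
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(mapping) - known
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**mapping)
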