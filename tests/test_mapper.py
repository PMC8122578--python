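from math import exp

import numpy as np
import pytest

from tnt1map import (
    AlignmentHit,
    PipelineConfig,
    QCOutcome,
    ReferenceGenome,
    RejectReason,
    align_read,
    best_hit,
    build_index,
    call_insertion_site,
    filter_batch,
    karlin_lambda,
    map_batch,
    score_to_evalue,
)
from tnt1map.io import reverse_complement
from tnt1map.qc import FSTRecord, SignatureMatch


def _random_genome(n=2000, seed=7, name="c1"):
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=n))
    return ReferenceGenome({name: seq})


@pytest.fixture(scope="module")
def genome():
    return _random_genome()


@pytest.fixture(scope="module")
def index(genome):
    return build_index(genome, 15)


class TestBuildIndex:
    def test_enumerated_small_genome(self):
        idx = build_index(ReferenceGenome({"c1": "ACGTACGT"}), k=4)
        assert idx.n_positions == 5
        assert sorted(off for _, off in idx.positions["ACGT"]) == [0, 4]

    def test_windows_overlapping_n_are_excluded(self):
        idx = build_index(ReferenceGenome({"c1": "AANAA"}), k=2)
        assert idx.n_positions == 2
        assert sorted(idx.positions) == ["AA"]

    def test_k_equal_to_chromosome_length(self):
        idx = build_index(ReferenceGenome({"c1": "ACGTACGT"}), k=8)
        assert idx.n_positions == 1

    def test_k_longer_than_every_chromosome_is_an_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            build_index(ReferenceGenome({"c1": "ACGT"}), k=10)


class TestAlignRead:
    def test_perfect_substring(self, genome, index):
        read = genome["c1"][500:600]
        hits = align_read(read, index, genome)
        best = best_hit(hits)
        assert best.identity == 1.0
        assert best.aln_len == 100
        assert (best.ref_start, best.ref_end, best.strand) == (501, 600, "+")

    def test_reverse_complement_maps_to_same_interval(self, genome, index):
        read = genome["c1"][500:600]
        fwd = best_hit(align_read(read, index, genome))
        rev = best_hit(align_read(reverse_complement(read), index, genome))
        assert (rev.ref_start, rev.ref_end) == (fwd.ref_start, fwd.ref_end)
        assert rev.strand == "-" and rev.score == fwd.score

    def test_five_substitutions_match_brute_force(self, genome, index, alignment_oracle):
        read = list(genome["c1"][500:600])
        for pos in (10, 30, 50, 70, 90):
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        read = "".join(read)
        best = best_hit(align_read(read, index, genome))
        assert best.identity == pytest.approx(0.95)
        assert best.score == alignment_oracle(read, genome["c1"])

    def test_read_shorter_than_k_is_an_error(self, genome, index):
        with pytest.raises(ValueError, match="shorter"):
            align_read("ACGTACGT", index, genome)

    def test_threshold_soundness(self, genome, index):
        cfg = PipelineConfig()
        rng = np.random.default_rng(11)
        for _ in range(20):
            start = int(rng.integers(0, 1800))
            read = list(genome["c1"][start : start + 120])
            for pos in rng.integers(0, 120, size=int(rng.integers(0, 12))):
                read[pos] = "ACGT"[int(rng.integers(4))]
            for h in align_read("".join(read), index, genome, cfg):
                assert h.identity + 1e-12 >= cfg.min_identity
                assert h.evalue <= cfg.max_evalue


class TestEvalue:
    def test_lambda_matches_independent_bisection(self):
        # independent oracle: plain interval bisection on the defining equation
        p_match, p_mis = 0.25, 0.75

        def f(lam):
            return p_match * exp(lam * 1) + p_mis * exp(lam * -2) - 1.0

        lo, hi = 1e-9, 4.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) < 0:
                lo = mid
            else:
                hi = mid
        assert karlin_lambda(1, -2) == pytest.approx((lo + hi) / 2, abs=1e-6)

    def test_evalue_linear_in_genome_length(self):
        e1 = score_to_evalue(100, 300, 10**6)
        e2 = score_to_evalue(100, 300, 2 * 10**6)
        assert e2 == pytest.approx(2 * e1)

    def test_evalue_strictly_decreasing_in_score(self):
        assert score_to_evalue(101, 300, 10**6) < score_to_evalue(100, 300, 10**6)

    def test_non_negative_expected_score_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            karlin_lambda(1, 0)


def _hit(**kw):
    base = dict(
        fst_id="f1",
        chrom="c1",
        ref_start=1001,
        ref_end=1100,
        read_start=1,
        read_end=100,
        strand="+",
        matches=100,
        aln_len=100,
        score=100,
        evalue=1e-50,
    )
    base.update(kw)
    return AlignmentHit(**base)


class TestBestHit:
    def test_argmax_score(self):
        assert best_hit([_hit(score=90), _hit(score=100)]).score == 100

    def test_chromosome_tie_break(self):
        assert best_hit([_hit(chrom="chr2"), _hit(chrom="chr1")]).chrom == "chr1"

    def test_empty_input_gives_none(self):
        assert best_hit([]) is None


def _qc(which_end, motif="CCCAACA", start_offset=0, end_distance=0, fst_id="f1"):
    return QCOutcome(
        fst_id=fst_id,
        passed=True,
        reason=RejectReason.PASS,
        best_match=SignatureMatch(
            motif=motif,
            strand_of_motif="forward",
            start_offset=start_offset,
            end_distance=end_distance,
            which_end=which_end,
        ),
    )


class TestCallInsertionSite:
    def test_head_signature_plus_strand(self):
        # 7-bp motif at offset 0: junction is read base 8 = aligned read_start
        hit = _hit(read_start=8, read_end=107)
        qc = _qc("head", end_distance=100)
        assert call_insertion_site(hit, qc).position == 1001

    def test_head_signature_minus_strand(self):
        hit = _hit(read_start=8, read_end=107, strand="-")
        qc = _qc("head", end_distance=100)
        assert call_insertion_site(hit, qc).position == 1100

    def test_junction_projected_through_trimmed_alignment(self):
        # alignment starts 3 bp after the junction (e.g. substitutions at the
        # junction); the call must still land on the junction's diagonal
        hit = _hit(read_start=11, read_end=107, ref_start=1004, aln_len=97, matches=97)
        qc = _qc("head", end_distance=100)
        assert call_insertion_site(hit, qc).position == 1001

    def test_id_mismatch_is_an_error(self):
        with pytest.raises(ValueError, match="mismatch"):
            call_insertion_site(_hit(fst_id="a"), _qc("head", fst_id="b"))


class TestMapBatch:
    def test_perfect_reads_all_map(self, genome):
        cfg = PipelineConfig()
        reads = [
            FSTRecord(fst_id=f"L1_r{i}", sequence="CCCAACA" + genome["c1"][i * 150 : i * 150 + 100])
            for i in range(10)
        ]
        _, _, _, outcomes = filter_batch(reads, cfg)
        sites, summary = map_batch(reads, genome, cfg, outcomes)
        assert summary.n_mapped == 10 and summary.mapped_percent == 100
        # zero-noise reads must recover their source coordinate exactly
        assert [s.position for s in sites] == [i * 150 + 1 for i in range(10)]

    def test_empty_input(self, genome):
        sites, summary = map_batch([], genome, PipelineConfig(), {})
        assert (summary.n_input, summary.n_mapped, summary.mapped_percent) == (0, 0, 0)

    def test_mapped_percent_rounds_half_up_like_published_funnel(self):
        from tnt1map import MappingSummary

        assert MappingSummary.from_counts(221_275, 202_788).mapped_percent == 92
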