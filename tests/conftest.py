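import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tnt1map import PipelineConfig, filter_batch
from tnt1map.io import reverse_complement
from tnt1map.simulate import SimulationConfig, simulate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def pipeline_config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """A 100 kb / ~150-read simulation shared across tests."""
    cfg = SimulationConfig(
        n_chroms=2,
        chrom_length=50_000,
        n_genes=15,
        gene_length=(500, 1500),
        n_lines=20,
        insertions_per_line=(5, 10),
        rng_seed=1,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_qc(small_dataset, pipeline_config):
    passed, failed, funnel, outcomes = filter_batch(small_dataset.reads, pipeline_config)
    return {"passed": passed, "failed": failed, "funnel": funnel, "outcomes": outcomes}


def brute_force_best_score(read: str, ref: str, match: int = 1, mismatch: int = -2) -> int:
    """Independent alignment oracle: exhaustive max-subarray score over every
    ungapped placement (all diagonals) and both read orientations."""

    def arr(s: str) -> np.ndarray:
        return np.frombuffer(s.encode(), dtype=np.uint8)

    best = 0
    b = arr(ref)
    for q in (read, reverse_complement(read)):
        a = arr(q)
        for d in range(-(len(a) - 1), len(b)):
            i0 = max(0, -d)
            j0 = i0 + d
            span = min(len(a) - i0, len(b) - j0)
            if span <= 0:
                continue
            qa, rb = a[i0 : i0 + span], b[j0 : j0 + span]
            col = np.where((qa == rb) & (qa != ord("N")), match, mismatch).astype(np.int64)
            c = np.concatenate(([0], np.cumsum(col)))
            max_sub = int(np.max(c[1:] - np.minimum.accumulate(c[:-1])))
            best = max(best, max_sub)
    return best


@pytest.fixture(scope="session")
def alignment_oracle():
    return brute_force_best_score
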