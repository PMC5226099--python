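import numpy as np
import pytest

from enhancerstack.benchmarks import REDUCED_SVM, strong_signal_run, strong_signal_spec
from enhancerstack.genomic_io import GenomicInterval, PeakRecord

strong_spec = strong_signal_spec  # convenience alias for tests


def random_peaks(rng, chrom_sizes, n, max_width=800):
    """Random valid PeakRecords over the given chromosomes."""
    peaks = []
    chroms = list(chrom_sizes)
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        size = chrom_sizes[chrom]
        start = int(rng.integers(0, size - 1))
        end = int(min(size, start + rng.integers(1, max_width)))
        peaks.append(
            PeakRecord(
                GenomicInterval(chrom, start, end),
                name=f"p{i}",
                score=int(rng.integers(0, 1001)),
                signal_value=float(np.round(rng.uniform(0, 20), 3)),
            )
        )
    return peaks


@pytest.fixture(scope="session")
def strong_run(tmp_path_factory):
    """One full train/predict/evaluate pass on the strong-signal study,
    shared by pipeline and acceptance tests."""
    return strong_signal_run(tmp_path_factory.mktemp("strong_study"), seed=7)
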