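import numpy as np
import pytest

from tailprofiler import pipeline, read_preprocess, synthetic_data
from tailprofiler.refprep import HairpinReference


@pytest.fixture(scope="session")
def toy_refs():
    """Three synthetic hairpins with G/C-only 3' regions (identifiable tails)."""
    return synthetic_data.make_test_references(n_hairpins=3, seed=7)


@pytest.fixture(scope="session")
def library_run(toy_refs):
    """One full sequencing-arm run on the default synthetic library.

    Generated once per session: 10,000 reads at the default generating
    conditions (mono-U fraction 0.362, trimmed fraction 0.3), preprocessed,
    aligned and tail-called.
    """
    truth = synthetic_data.LibraryTruth(n_reads=10_000)
    reads, truth_table = synthetic_data.simulate_library(toy_refs, truth, seed=7)
    processed = [
        read_preprocess.preprocess_read(
            seq, synthetic_data.DEFAULT_ADAPTER, read_id=rid
        )
        for rid, seq in reads
    ]
    calls = pipeline.call_processed_reads(processed, toy_refs)
    return {
        "refs": toy_refs,
        "truth": truth,
        "truth_table": truth_table,
        "reads": reads,
        "processed": processed,
        "calls": calls,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def plain_ref():
    """A bare 30-nt reference with no flanks, for hand-built alignments."""
    return HairpinReference("toy", "ACGGTTCAGACCGGAATGTCCGCTGCAGGC", 0, 30, extension_nt=0)
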