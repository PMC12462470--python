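import warnings

import numpy as np
import pytest

from sskit import generate_bundle, run_pipeline
from sskit.core import GenomicInterval, RegulatoryElement

# bin-shortfall redistribution warnings are expected on the default bundle
warnings.filterwarnings("ignore", message=".*redistributed.*")


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic bundle, shared across the suite."""
    return generate_bundle(seed=7)


@pytest.fixture(scope="session")
def recovered(bundle):
    """Pipeline summary quantities for the shared bundle."""
    return run_pipeline(bundle, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_elements(starts, lengths=1000, chrom="chr1", signal=1.0, mark="H3K27me3", prefix="e"):
    """Small helper used throughout: elements at given starts."""
    if np.isscalar(lengths):
        lengths = [lengths] * len(starts)
    if np.isscalar(signal):
        signal = [signal] * len(starts)
    return [
        RegulatoryElement(
            f"{prefix}{i}",
            GenomicInterval(chrom, int(s), int(s) + int(l)),
            "silencer",
            {mark: float(v)},
        )
        for i, (s, l, v) in enumerate(zip(starts, lengths, signal))
    ]
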