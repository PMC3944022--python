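import numpy as np
import pytest

from clonalpair.io_formats import MutationRecord, SegmentRecord

EFFECTS = [
    "nonsynonymous",
    "synonymous",
    "stopgain",
    "stoploss",
    "frameshift_indel",
    "nonframeshift_indel",
    "splicing",
]

BASES = "ACGT"


def random_mutation(rng: np.random.Generator, sample_id: str = "S1") -> MutationRecord:
    ref = BASES[rng.integers(4)]
    alt = ref
    while alt == ref:
        alt = BASES[rng.integers(4)]
    return MutationRecord(
        sample_id=sample_id,
        chromosome=f"chr{rng.integers(1, 23)}",
        position=int(rng.integers(1, 10**8)),
        ref_allele=ref,
        alt_allele=alt,
        gene=f"G{rng.integers(1, 500):03d}",
        effect=EFFECTS[rng.integers(len(EFFECTS))],
    )


def random_segment(rng: np.random.Generator, sample_id: str = "S1") -> SegmentRecord:
    start = int(rng.integers(1, 10**6))
    return SegmentRecord(
        sample_id=sample_id,
        chromosome=f"chr{rng.integers(1, 23)}",
        start=start,
        end=start + int(rng.integers(0, 10**5)),
        copy_number=int(rng.integers(0, 7)),
        loh=bool(rng.integers(2)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
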