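import numpy as np
import pytest

from mbcorrect import MutationDataset, MutationRecord


@pytest.fixture
def tiny_records():
    """Three complete hand-built mutation records."""
    return [
        MutationRecord(
            record_id="r1", structure_id="1ABC", chain="A", position=1,
            wt_aa="A", mut_aa="V", ddg_exp=1.0, score_delta=0.4,
        ),
        MutationRecord(
            record_id="r2", structure_id="1ABC", chain="A", position=5,
            wt_aa="L", mut_aa="P", ddg_exp=-2.0, score_delta=-1.1,
        ),
        MutationRecord(
            record_id="r3", structure_id="2XYZ", chain="B", position=7,
            wt_aa="G", mut_aa="W", ddg_exp=0.5, score_delta=0.2,
        ),
    ]


@pytest.fixture
def tiny_dataset(tiny_records):
    return MutationDataset(records=list(tiny_records), meta={"method": "toy"})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
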