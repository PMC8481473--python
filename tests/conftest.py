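import pytest

from fibronet.curation import Manipulation, ManipulationRecord, Outcome


def make_record(gene="Gene1", study="S1", manip=Manipulation.OVEREXPRESSION,
                outcome=Outcome.REDUCED_FIBROSIS, model="bleomycin"):
    return ManipulationRecord(
        gene_id=gene, study_id=study, manipulation=manip, outcome=outcome, model=model
    )


@pytest.fixture
def record():
    return make_record
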