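import numpy as np
import pytest

from tcrdiag.io import ClonotypeRecord, Cohort, Repertoire
from tcrdiag.simulate import SimulationConfig, generate_cohort


def make_repertoire(sample_id, triples):
    """Repertoire from (cdr3, v, j, count) tuples."""
    recs = [
        ClonotypeRecord(cdr3_aa=c, v_gene=v, j_gene=j, count=n)
        for c, v, j, n in triples
    ]
    return Repertoire(sample_id=sample_id, records=recs).finalize()


def make_cohort(spec):
    """Cohort from {sample_id: (label, [(cdr3, v, j, count), ...])}."""
    reps, labels = [], []
    for sid, (label, triples) in spec.items():
        reps.append(make_repertoire(sid, triples))
        labels.append(label)
    return Cohort(repertoires=reps, labels=labels, batch_ids=["b0"] * len(reps))


@pytest.fixture
def tiny_repertoire():
    return make_repertoire(
        "S1",
        [
            ("CASSLGF", "TRBV9", "TRBJ2-3", 6),
            ("CASRTEAF", "TRBV28", "TRBJ1-1", 3),
            ("CAWSVGF", "TRBV30", "TRBJ2-7", 1),
        ],
    )


@pytest.fixture(scope="session")
def small_cohort_and_truth():
    """A 20/20 spiked cohort shared by slower tests (session scope)."""
    config = SimulationConfig(n_cases=20, n_controls=20, seed=11)
    return generate_cohort(config)


@pytest.fixture(scope="session")
def default_cohort_and_truth():
    """The default study-scale spiked cohort (100/100) at a fixed seed."""
    config = SimulationConfig(seed=2024)
    return generate_cohort(config)
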