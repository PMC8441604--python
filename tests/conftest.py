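import numpy as np
import pytest

from icdcoder.synthetic_corpus import SyntheticSpec, generate_corpus
from icdcoder.text_pipeline import LabeledNote, LabelSpace, Vocabulary


@pytest.fixture
def tiny_vocab():
    return Vocabulary(["a", "b", "c"])


@pytest.fixture
def tiny_space():
    return LabelSpace({f"C{i}": f"definition of C{i}" for i in range(5)})


@pytest.fixture
def tiny_notes():
    return [
        LabeledNote("n1", ["a", "b", "a"], {"C0"}),
        LabeledNote("n2", ["b", "c"], {"C1", "C2"}),
        LabeledNote("n3", ["c", "a", "b", "c"], {"C3"}),
    ]


@pytest.fixture(scope="session")
def small_corpus():
    """A small certified planted-signal corpus shared across tests."""
    spec = SyntheticSpec(n_codes=10, n_notes=120, note_len=(10, 25), seed=5)
    records, notes, ontology = generate_corpus(spec)
    return spec, records, notes, ontology


# heavy study-scale runs, computed once per session and shared by the
# acceptance tests

@pytest.fixture(scope="session")
def planted_result():
    from icdcoder.experiments import planted_signal_run

    return planted_signal_run(seed=0)


@pytest.fixture(scope="session")
def direction_result():
    from icdcoder.experiments import architecture_direction_run

    return architecture_direction_run(seed=0)


@pytest.fixture(scope="session")
def matcher_result():
    from icdcoder.experiments import matcher_run

    return matcher_run(seed=0)
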