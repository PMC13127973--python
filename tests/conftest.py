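import numpy as np
import pytest

from textmarkers import SyntheticConfig, generate_corpus

CONLLU_TWO_DOCS = """\
# newdoc id = a
# sent_id = a-1
1\tIl\til\tDET\t_\t_\t2\tdet\t_\t_
2\tgoverno\tgoverno\tNOUN\t_\t_\t3\tnsubj\t_\t_
3\tnasconde\tnascondere\tVERB\t_\t_\t0\troot\t_\t_
4\t?\t?\tPUNCT\t_\t_\t3\tpunct\t_\t_

# sent_id = a-2
1\tsito\tsito\tNOUN\t_\t_\t0\troot\t_\t_
2\tweb\tweb\tNOUN\t_\t_\t1\tcompound\t_\t_
3\t5\t5\tNUM\t_\t_\t1\tnummod\t_\t_

# newdoc id = b
# sent_id = b-1
1-2\tdel\t_\t_\t_\t_\t_\t_\t_\t_
1\tdi\tdi\tADP\t_\t_\t3\tcase\t_\t_
2\til\til\tDET\t_\t_\t3\tdet\t_\t_
3\tsegreto\tsegreto\tNOUN\t_\t_\t0\troot\t_\t_
3.1\tnodo\tnodo\tNOUN\t_\t_\t_\t_\t_\t_
"""


@pytest.fixture
def conllu_file(tmp_path):
    path = tmp_path / "fixture.conllu"
    path.write_text(CONLLU_TWO_DOCS, encoding="utf-8")
    return path


@pytest.fixture(scope="session")
def small_corpus():
    """A 40-participant synthetic study used across module tests."""
    return generate_corpus(SyntheticConfig(n_participants=40, seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
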