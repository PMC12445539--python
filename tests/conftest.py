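import numpy as np
import pytest

from flcnn.corpus import EntityMention, LabeledSentence
from flcnn.lattice import build_lexicon
from flcnn.synth import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A small deterministic synthetic corpus + trie lexicon."""
    corpus, lex = generate_corpus(SynthConfig(seed=11, n_sentences=50))
    return corpus, build_lexicon(lex)


@pytest.fixture(scope="session")
def tiny_labeled():
    return [
        LabeledSentence("发烧三天了", [EntityMention("SYM", 0, 1)]),
        LabeledSentence("间歇夜间发热", [EntityMention("SYM", 0, 5)]),
        LabeledSentence("无症状", []),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
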