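import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from motifcurate import Document, load_stopwords

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def stoplist():
    return load_stopwords()


@pytest.fixture()
def rng():
    return np.random.default_rng(20100616)


def random_documents(rng, n_docs, vocab, mean_len=12, label="unknown", start=1):
    """Small random documents over an explicit vocabulary (test helper)."""
    docs = []
    for i in range(n_docs):
        length = max(1, int(rng.poisson(mean_len)))
        words = rng.choice(vocab, size=length)
        docs.append(
            Document(
                pmid=str(start + i),
                title=" ".join(words[:2]),
                abstract=" ".join(words[2:]),
                label=label,
            )
        )
    return docs
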