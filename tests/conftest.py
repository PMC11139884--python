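import warnings

import pytest

from ptsdlang.corpus_io import Transcript, tokenize
from ptsdlang.features import extract_all
from ptsdlang.synthetic import (
    SyntheticConfig,
    generate_corpus,
    generate_lexicons,
)

warnings.filterwarnings("ignore", message=".*ConvergenceWarning.*")


def small_config(**overrides) -> SyntheticConfig:
    """A desk-scale cohort: 40 documents, short narratives."""
    defaults = dict(
        n_docs=40, exposure_split=(30, 10), diagnosis_split=(18, 12, 10),
        length_mean=300.0, length_sd=150.0, length_bounds=(80, 900), seed=42,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle():
    """(corpus, metadata, ground truth) for a 40-document null cohort."""
    return generate_corpus(small_config())


@pytest.fixture(scope="session")
def lexicons():
    return generate_lexicons(42)


@pytest.fixture(scope="session")
def small_docs(small_bundle):
    corpus, _meta, _gt = small_bundle
    return [tokenize(t) for t in corpus]


@pytest.fixture(scope="session")
def small_table(small_docs, lexicons):
    return extract_all(small_docs, lexicons)


def doc(text: str):
    """Tokenize a one-off snippet."""
    return tokenize(Transcript("snippet", text))
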