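import pytest

from burnout_ensemble.corpus import Corpus, TextSample
from burnout_ensemble.pipeline import RunConfig, run_experiment
from burnout_ensemble.synthetic import generate_scenario


def make_corpus(labels, texts=None, groups=None, prefix="s"):
    """Small labeled corpus from parallel lists."""
    n = len(labels)
    texts = texts if texts is not None else [f"doc {i}" for i in range(n)]
    groups = groups if groups is not None else [None] * n
    return Corpus(
        [
            TextSample(id=f"{prefix}{i}", text=texts[i], label=labels[i], group=groups[i])
            for i in range(n)
        ]
    )


@pytest.fixture
def tiny_corpus():
    return make_corpus(
        [1, 0, 0],
        texts=["I am burnt out and tired", "a quiet day of writing", "short"],
        groups=[None, "books", "books"],
    )


@pytest.fixture(scope="session")
def paper_shape_run():
    """One full-size random-batching ensemble run, shared across tests.

    Generates the reference-shape corpus (352 positives / 13,216 grouped
    controls) and runs the complete pipeline with the default protocol
    settings (500-token vocabulary, 70/30 split, 20 batches, 10-fold CV,
    threshold sweep 0.4-0.9).
    """
    corpus, _ = generate_scenario("paper_shape", seed=11)
    return run_experiment(corpus, RunConfig(seed=11), "ensemble_random")
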