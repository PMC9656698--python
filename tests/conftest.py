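import pytest

from ppmadl import PPMActivityModel, worked_example


@pytest.fixture(scope="session")
def example():
    return worked_example()


@pytest.fixture()
def example_model(example):
    """PPM model trained on the five hand-checkable triplets."""
    return PPMActivityModel().fit(example.training)
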