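import pytest

from mobscan.panels import ReferencePanels
from mobscan.pipeline import PipelineConfig, annotate_sequence
from mobscan.synthetic import default_landscape_config, generate_landscape


@pytest.fixture(scope="session")
def panels():
    return ReferencePanels.default()


@pytest.fixture(scope="session")
def landscape1(panels):
    """The standard 100 kb study landscape at seed 1, mutation-free."""
    return generate_landscape(default_landscape_config(1), panels)


@pytest.fixture(scope="session")
def report1(landscape1, panels):
    seq, _ = landscape1
    return annotate_sequence(seq, panels, PipelineConfig())
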