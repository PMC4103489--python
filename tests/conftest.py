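import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

from enrichmap.model import BuildParameters
from enrichmap.synth import micro_dataset, write_micro_files


@pytest.fixture
def micro_ds():
    return micro_dataset()


@pytest.fixture
def micro_network(micro_ds):
    from enrichmap.build import build_map

    network, report = build_map(micro_ds, BuildParameters())
    return network


@pytest.fixture
def micro_files(tmp_path):
    return write_micro_files(tmp_path)
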