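import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from oxilink import SyntheticPanelConfig, generate_panel  # noqa: E402


@pytest.fixture(scope="session")
def small_panel():
    """Four-genus panel with tiny genomes, annotations materialised."""
    config = SyntheticPanelConfig(
        n_genera=4, n_categories=5, genes_range=(60, 150), seed=42
    )
    return generate_panel(config)


@pytest.fixture(scope="session")
def medium_panel():
    """Default-condition panel (in-memory path only)."""
    return generate_panel(SyntheticPanelConfig(seed=7), with_annotations=False)
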