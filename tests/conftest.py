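from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def demo_study(tmp_path_factory):
    """One synthetic five-cohort study at the design's stage sizes, with the
    full pipeline run on it. Shared across tests that inspect the end-to-end
    behaviour."""
    from enhscreen.pipeline import run_pipeline
    from enhscreen.study import StudyDesign, build_study

    root = tmp_path_factory.mktemp("demo_study")
    config = build_study(root, StudyDesign(seed=1))
    result = run_pipeline(config)
    return config, result
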