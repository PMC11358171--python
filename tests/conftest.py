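import numpy as np
import pytest

from gazesal import synth

# Small-scale fixture geometry used across the suite: 64x64 px clips at
# 10 fps with 16-px patch windows keep the full pipeline fast while
# exercising every stage.


@pytest.fixture(scope="session")
def tiny_spec() -> synth.ClipSpec:
    return synth.ClipSpec(
        clip_id="fight-01",
        category="fight",
        duration_s=1.0,
        fps=10.0,
        width=64,
        height=64,
        n_agents=2,
        n_distractors=2,
    )

@pytest.fixture(scope="session")
def tiny_clip(tiny_spec) -> synth.VideoClip:
    return synth.generate_clip(tiny_spec, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort() -> synth.CohortSpec:
    return synth.CohortSpec(
        n_group_a=3, n_group_b=3, strategy_gap=0.6, gaze_noise_px=15.0, seed=11
    )


@pytest.fixture(scope="session")
def tiny_traces(tiny_clip, tiny_cohort) -> list[synth.GazeTrace]:
    return synth.generate_cohort_gaze([tiny_clip], tiny_cohort)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240125)
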