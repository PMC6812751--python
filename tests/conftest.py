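import numpy as np
import pytest

from derplab.montage import builtin_rois, standard_montage_32
from derplab.pipeline import PipelineConfig, run_pipeline
from derplab.synth import (CohortSpec, ComponentTemplate, TrialCountSpec,
                           paper_fixture)


@pytest.fixture(scope="session")
def montage():
    return standard_montage_32()


@pytest.fixture(scope="session")
def rois():
    return {r.name: r for r in builtin_rois()}


def small_cohort_spec(seed=0, **overrides) -> CohortSpec:
    """A scaled-down cohort (4+4 subjects, ~24 trials) for fast tests."""
    base = paper_fixture(seed=seed)
    kwargs = dict(
        n_meditators=4, n_non_meditators=4,
        trial_counts={(g, e): TrialCountSpec(24.0, 4.0, 10)
                      for g in ("meditator", "non_meditator")
                      for e in ("passive", "hold")},
        components=base.components,
        white_sd_uv=4.0, pink_sd_uv=2.0,
        latency_jitter_sd_ms=4.0, amplitude_jitter_rel_sd=0.1,
        artifact_rate=0.0,
        channel_noise_scale={"TP9": 0.3, "TP10": 0.3},
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


def noiseless_spec(templates, seed=0, n_med=2, n_non=2, n_trials=5):
    return CohortSpec(
        n_meditators=n_med, n_non_meditators=n_non,
        trial_counts={(g, e): TrialCountSpec(float(n_trials), 0.0, 1)
                      for g in ("meditator", "non_meditator")
                      for e in ("passive", "hold")},
        components=templates,
        white_sd_uv=0.0, pink_sd_uv=0.0,
        latency_jitter_sd_ms=0.0, amplitude_jitter_rel_sd=0.0,
        artifact_rate=0.0, seed=seed,
    )


def single_fn_templates(amplitude=-5.0, latency=160.0, electrode="Fz"):
    tpl = ComponentTemplate(name="FN", latency_ms=latency, width_ms=25.0,
                            amplitude_uv=amplitude,
                            topography={electrode: 1.0})
    return {"meditator": (tpl,), "non_meditator": (tpl,)}


@pytest.fixture(scope="session")
def fixture_bundle():
    """One full pipeline run on the shipped cohort (shared across tests)."""
    return run_pipeline(PipelineConfig.fixture(seed=777))
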