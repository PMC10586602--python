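import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

import musselpatch as mp  # noqa: E402


@pytest.fixture(scope="session")
def default_config():
    return mp.SimConfig().validate()


@pytest.fixture(scope="session")
def env_default(default_config):
    return mp.gen_environment(default_config, seed=11)


@pytest.fixture(scope="session")
def cages_default(default_config, env_default):
    return mp.gen_cage_experiment(default_config, env_default, seed=12)


#: run-window means (value, 3 x 95% CI) of the study year, used as the
#: plausibility envelope for the default environment generator
STUDY_WINDOWS = {
    "run1": {"temp_C": (8.89, 1.65), "chl_ug_l": (1.73, 0.27), "turb_FTU": (3.57, 2.16)},
    "run2": {"temp_C": (11.63, 0.93), "chl_ug_l": (2.96, 1.65), "turb_FTU": (1.63, 0.96)},
    "run3": {"temp_C": (19.08, 1.32), "chl_ug_l": (1.79, 0.42), "turb_FTU": (2.57, 2.10)},
    "run4": {"temp_C": (19.56, 0.30), "chl_ug_l": (2.46, 0.36), "turb_FTU": (3.43, 0.60)},
    "run5": {"temp_C": (15.51, 0.78), "chl_ug_l": (1.70, 0.33), "turb_FTU": (1.97, 0.51)},
    "run6": {"temp_C": (8.59, 1.77), "chl_ug_l": (1.08, 0.15), "turb_FTU": (3.64, 2.61)},
    "run7": {"temp_C": (2.30, 1.38), "chl_ug_l": (2.15, 1.38), "turb_FTU": (7.64, 7.83)},
}
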