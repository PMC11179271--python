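import pytest

import cropcarbon as cc


@pytest.fixture(scope="session")
def noiseless_study():
    """Full 30-system / 720-run study with zero noise (closed forms)."""
    return cc.generate_study(seed=1, noise_cv_yield=0.0, noise_cv_soc=0.0)


@pytest.fixture(scope="session")
def harmonized(noiseless_study):
    return cc.harmonize_study(noiseless_study)


@pytest.fixture(scope="session")
def presets():
    return cc.scenario_presets()


@pytest.fixture(scope="session")
def ref_result(harmonized, presets):
    return cc.run_scenario(presets["REF"], harmonized)


@pytest.fixture(scope="session")
def ccpl_result(harmonized, presets):
    return cc.run_scenario(presets["CCPL"], harmonized)


@pytest.fixture(scope="session")
def small_study():
    """One-system noiseless study: 24 trajectories, fast unit checks."""
    design = [cc.BasinCropSystem("B01", "wheat", 50.0)]
    return cc.generate_study(design=design, seed=7, noise_cv_yield=0.0,
                             noise_cv_soc=0.0)
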