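import numpy as np
import pytest

from quantpd import (
    BaselineParams,
    EffectParams,
    KineticParams,
    QuadratureFitter,
    SimulationDesign,
    TimeCourse,
    default_schedule,
    model_signal,
)


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def kin():
    return KineticParams(t_half=41.0, t_shift=0.5, hill=1.0)


@pytest.fixture(scope="session")
def baseline():
    return BaselineParams(a0=1000.0, a1=0.05, a2=0.0)


@pytest.fixture(scope="session")
def times():
    return SimulationDesign().times


@pytest.fixture(scope="session")
def default_fitter(times, schedule):
    """One quadrature engine shared by the whole session (it is stateless
    across curves apart from a per-fit cache)."""
    return QuadratureFitter(times, schedule)


@pytest.fixture(scope="session")
def make_curve(times, schedule, kin, baseline):
    """Factory for study-like noisy curves with a dedicated seeded RNG."""

    def _make(ec50: float | None, noise_sd: float, seed: int = 0) -> TimeCourse:
        eff = EffectParams(0.0, 0.0) if ec50 is None else EffectParams.from_ec50(10.0, ec50)
        clean = np.asarray(model_signal(times, schedule, kin, eff, baseline))
        rng = np.random.default_rng(seed)
        noisy = clean if noise_sd == 0 else clean + rng.normal(0, noise_sd, times.size)
        return TimeCourse(times=times, values=noisy,
                          meta={"ec50": ec50, "noise_sd": noise_sd, "seed": seed})

    return _make
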