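import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import polku as pk

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def ku_scenario() -> pk.KineticScenario:
    """Condition with Ku pre-loaded (faster binding, slower dissociation)."""
    return pk.load_condition("pol_lambda_ku")


@pytest.fixture(scope="session")
def alone_scenario() -> pk.KineticScenario:
    """Polymerase-alone condition."""
    return pk.load_condition("pol_lambda")


@pytest.fixture(scope="session")
def true_factors(ku_scenario) -> pk.CorrectionFactors:
    return pk.CorrectionFactors(ku_scenario.leakage,
                                ku_scenario.direct_excitation,
                                ku_scenario.gamma)


def make_trajectory(f_aa, frame_interval=0.2, molecule_id=0):
    """Trajectory with a given partner-channel series and flat other channels."""
    f_aa = np.asarray(f_aa, dtype=float)
    n = f_aa.size
    return pk.Trajectory(
        molecule_id=molecule_id,
        time_s=np.arange(n) * frame_interval,
        f_dd=np.full(n, 500.0),
        f_da=np.full(n, 10.0),
        f_aa=f_aa,
        frame_interval=frame_interval,
    )


@pytest.fixture(scope="session")
def fret_events_for(true_factors):
    """Run the correction + FRET event calling chain for one scenario."""

    def _run(scenario, **call_kwargs):
        trajset, truth = pk.simulate_fret(scenario)
        events = []
        for traj in trajset:
            trace = pk.compute_efret(traj, true_factors,
                                     background=scenario.background)
            events.extend(pk.call_fret_events(trace, **call_kwargs))
        return events, truth

    return _run
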