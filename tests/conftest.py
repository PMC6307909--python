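import numpy as np
import pytest

from szdiary.diary import DAY_S, HOUR_S, AnimalDiary, Cohort, SeizureEvent
from szdiary.simulate import SimulatorConfig, simulate_cohort


def make_diary(onsets_days, durations_s=None, animal_id="a1", epoch="injection",
               recording_days=30.0, clock_offset_h=7.0, semiology=None,
               recording_start_days=0.0, injection_s=None):
    onsets = np.asarray(onsets_days, dtype=float) * DAY_S
    if durations_s is None:
        durations_s = np.full(len(onsets), 60.0)
    events = [
        SeizureEvent(float(o), float(d),
                     semiology if isinstance(semiology, (str, type(None)))
                     else semiology[i])
        for i, (o, d) in enumerate(zip(onsets, durations_s))
    ]
    return AnimalDiary(
        animal_id=animal_id,
        events=events,
        epoch=epoch,
        recording_start_s=recording_start_days * DAY_S,
        recording_end_s=recording_days * DAY_S,
        clock_offset_h=clock_offset_h,
        injection_s=injection_s,
    )


@pytest.fixture(scope="session")
def default_cohort50():
    """One 50-animal cohort at the generator's default study conditions."""
    return simulate_cohort(SimulatorConfig(n_animals=50, seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-animal cohort small enough for fast end-to-end stages."""
    return simulate_cohort(SimulatorConfig(n_animals=12, seed=7))
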