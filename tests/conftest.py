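import numpy as np
import pytest

from ahre.episodes import EpisodeRecord, Label, N_SAMPLES
from ahre.simulate import CenterSpec, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small five-center cohort shared across read-only tests."""
    cfg = SimulationConfig(
        seed=123,
        centers=[
            CenterSpec("C1", 10),
            CenterSpec("C2", 8),
            CenterSpec("C3", 6),
            CenterSpec("C4", 4),
            CenterSpec("EXT", 5),
        ],
    )
    cohort, events = simulate_cohort(cfg)
    return cohort, events


def make_episode(
    episode_id="e0",
    patient_id="p0",
    center_id="c0",
    label=Label.ATAF,
    seed=0,
    nowhere_zero=False,
):
    """Hand-built episode with controllable, nonzero content."""
    rng = np.random.default_rng(seed)
    atrial = rng.uniform(-1.0, 1.0, N_SAMPLES).astype(np.float32)
    ventricular = rng.uniform(-1.0, 1.0, N_SAMPLES).astype(np.float32)
    if nowhere_zero:
        atrial = np.sign(atrial) * np.maximum(np.abs(atrial), 0.05)
        ventricular = np.sign(ventricular) * np.maximum(np.abs(ventricular), 0.05)
    markers = np.zeros(N_SAMPLES, dtype=np.uint8)
    markers[[10, 500, 1200]] = 1
    return EpisodeRecord(
        episode_id=episode_id,
        patient_id=patient_id,
        center_id=center_id,
        label=label,
        atrial=atrial / np.max(np.abs(atrial)),
        ventricular=ventricular / np.max(np.abs(ventricular)),
        has_ventricular=True,
        markers=markers,
    )
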