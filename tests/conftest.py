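import numpy as np
import pytest

from mbnet import (
    Recording,
    SimulationConfig,
    calibrate_coupling,
    connection_matrix,
    preprocess_group,
    simulate_group,
)

#: study conditions used by the recovery / null checks
RECOVERY_DURATION = 600.0
RECOVERY_TARGET_R = 0.7
N_NULL_SEEDS = 100


def make_recording(
    participant_id="p1",
    instrument_id="inst",
    sampling_rate=10.0,
    clock_offset=0.0,
    duration=10.0,
    channels=("prefrontal_1", "prefrontal_2"),
    rois=None,
    fill=None,
    events=(),
):
    """Small uniform recording; ``fill`` maps channel -> callable(t) or const."""
    # inclusive endpoint: a "duration" of 100 s truly spans [0, 100]
    t = np.arange(int(round(duration * sampling_rate)) + 1) / sampling_rate
    cols = []
    for c in channels:
        spec = (fill or {}).get(c, 0.0)
        cols.append(spec(t) if callable(spec) else np.full_like(t, float(spec)))
    roi_map = rois or {c: c.rsplit("_", 1)[0] for c in channels}
    return Recording(
        participant_id=participant_id,
        instrument_id=instrument_id,
        sampling_rate=sampling_rate,
        clock_offset=clock_offset,
        timestamps=t,
        channels=list(channels),
        roi_map=roi_map,
        hbo=np.column_stack(cols),
        events=list(events),
    )


@pytest.fixture(scope="session")
def short_group():
    """One short synthetic two-instrument group session (shared, read-only)."""
    recordings, truth = simulate_group(SimulationConfig(duration=120.0, seed=42))
    return recordings, truth


@pytest.fixture(scope="session")
def calibrated_beta():
    cfg = SimulationConfig(duration=RECOVERY_DURATION, seed=0)
    return calibrate_coupling(cfg, RECOVERY_TARGET_R)


@pytest.fixture(scope="session")
def null_connection_matrices():
    """Pearson matrices of uncoupled (beta = 0) groups at the recovery
    study conditions, one per seed; shared between the null-correlation
    and empty-graph checks."""
    out = []
    for seed in range(N_NULL_SEEDS):
        recs, _ = simulate_group(
            SimulationConfig(
                duration=RECOVERY_DURATION, seed=seed, coupling=0.0
            )
        )
        out.append(connection_matrix(preprocess_group(recs)))
    return out
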