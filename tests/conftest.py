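import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import multikin as mk

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def benchmark_gt() -> mk.GroundTruthKinetics:
    """Reference kinetics: k_on = 1e5 M^-1 s^-1, k_off = 1e-3 s^-1 (K_D = 10 nM)."""
    return mk.GroundTruthKinetics(k_on=1e5, k_off=1e-3)


@pytest.fixture
def assay_setup() -> mk.CompetitionSetup:
    """Displacement assay conditions: 20 nM target, 10 nM tracer, 25 nM tracer K_D."""
    return mk.CompetitionSetup(T_t=20e-9, C_t=10e-9, K_D_tracer=25e-9)


def referenced_traces(gt, concs, noise_sd=0.0, drift=0.0, seed=0, **kw):
    """Simulate channel sets and return double-referenced traces per conc."""
    out = []
    for j, c in enumerate(concs):
        ch = mk.simulate_fps_trace(
            gt, c, noise_sd=noise_sd, drift=drift, seed=seed * 1000 + j, **kw
        )
        out.append(
            mk.double_reference(
                ch["measurement"],
                ch["reference"],
                ch["blank_measurement"],
                ch["blank_reference"],
            )
        )
    return out


@pytest.fixture(scope="session")
def planted_table() -> pd.DataFrame:
    """Default library with planted ground-truth kinetics as a response table."""
    lib = mk.default_library(seed=0)
    rows = []
    for arch in lib:
        gt = mk.plant_kinetics(arch, seed=1)
        rows.append(
            {
                "id": arch.id,
                "valency": arch.valency,
                "epitope_seq": arch.epitope_seq,
                "tokens": arch.token_string,
                "kd_M": gt.K_D,
                "k_on": gt.k_on,
                "k_off": gt.k_off,
            }
        )
    return pd.DataFrame(rows)


def make_trace(signal_by_phase: dict[str, np.ndarray], dt: float = 1.0, **kw):
    """Assemble a SensorTrace from per-phase signal arrays."""
    sig = np.concatenate([np.asarray(v, float) for v in signal_by_phase.values()])
    phase = np.concatenate(
        [np.repeat(k, len(v)) for k, v in signal_by_phase.items()]
    ).astype(object)
    t = np.arange(sig.size, dtype=float) * dt
    return mk.SensorTrace(time=t, signal=sig, phase=phase, **kw)
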